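# Methods

This document describes the models and conventions the package
implements, the parameters it exposes, and where its guarantees end.
Every empirical number quoted in the README or emitted by
`scripts/acceptance.py` is computed at run time by the test suite or
the script itself; nothing here asserts a measured result.

## Header model

NIfTI-1 and Analyze 7.5 share a 348-byte binary header. The codec is
hand-written over `struct` rather than delegated to an imaging library
because the de-identification guarantees are stated at the byte level
and must be auditable at the byte level (the test suite uses nibabel as
an independent oracle to cross-check decoding).

- **Format trichotomy.** The 4 bytes at offset 344 decide: `n+1\0`
  means single-file NIfTI (`.nii`), `ni1\0` means a NIfTI `.hdr`/`.img`
  pair, anything else means Analyze 7.5. Endianness is resolved by
  trial-decoding `sizeof_hdr` at offset 0 in both byte orders and
  requiring the value 348; headers satisfying neither are rejected as
  malformed rather than guessed at.
- **Field roster.** Every field is carried with its name, byte span,
  struct code and an `editable` flag. Editable fields are exactly the
  free-text history fields: for NIfTI `descrip`, `aux_file`,
  `db_name`; for Analyze additionally `originator`, `generated`,
  `scannum`, `patient_id`, `exp_date`, `exp_time`. Everything that
  affects interpretation of the voxel data — dimensions, datatype,
  bitpix, pixdim, `vox_offset`, scaling, orientation — is protected
  and can only change through an explicit conversion, never through an
  edit.
- **Locality by construction.** A decoded record keeps the original
  raw bytes plus the set of *dirty* fields; re-encoding patches only
  the dirty byte spans into the original buffer. Consequently
  `encode(decode(x)) == x` for any well-formed header, and an edit can
  only ever change bytes inside the edited field's span. These are
  structural properties, not tested approximations; the fuzz tests
  confirm the implementation realizes them.
- **Scrubbing** zero-fills every editable field (NUL bytes), which
  makes it idempotent.
- **Conversion.** `.nii` → pair rewrites the magic, zeroes
  `vox_offset`, and splits the voxel block out at its recorded offset;
  header extensions cannot be represented in a pair and are dropped
  with a logged warning. Pair → `.nii` sets `vox_offset = 352` (348 +
  the 4-byte extender). Analyze pairs are promoted to NIfTI by
  building a fresh NIfTI header from the geometry and copying the
  fields the two formats share. Voxel payloads are moved verbatim, so
  round trips are voxel-exact; supported datatypes are uint8, int16,
  int32 and float32.

## Associative matching

The table's first column is taken as the subject-ID column. For each
ID, candidate files are sought in four precedence tiers, stopping at
the first tier that yields any candidate:

1. exact filename stem,
2. a user pattern containing `{id}` (glob semantics, e.g.
   `{id}_run*`),
3. bounded substring — the ID must appear in the stem *not* flanked by
   alphanumerics, so `S01` matches `x_S01_y.nii` but not `S012.nii`,
4. a full path component equal to the ID (subject-per-directory
   layouts), enabled by an option.

IDs are resolved in descending length groups so a short ID can never
claim a file that a longer ID also claims (`S1` vs `S10`): longer IDs
bind first and remove their files from the pool. Within a length
group, ties cannot be broken by length, so two same-length IDs
claiming one file is an ambiguity error, not a silent choice. A
subject with several candidates is an error unless multi-image
subjects are explicitly allowed; a subject with none is reported as a
`MISMATCH` rather than dropped. `.hdr`/`.img` pairs count as one
logical image, and a lone `.img` is an error. Inverting a pattern
(`infer_id`) lets unmatched files generate placeholder table rows.

## Pseudonymization and the key file

New IDs are `prefix + zero-padded integer` (default `SUB` + 4 digits),
drawn from `random.Random(seed)` with rejection: a draw colliding with
an original ID or an already-assigned new ID is redrawn, and the digit
width grows automatically when the label space nears exhaustion, so
generation terminates for any input size. The invariants — new IDs
internally unique and disjoint from the originals — are enforced again
by the `IdMap` constructor, so no code path can produce a violating
map. The original↔new key is written outside the shareable directory
by default, and packaging refuses outright if a key file is found
inside it.

Validation (`validate_round_trip`) repeats, for repetition *r* with
its own RNG seeded `seed + r`: sample a random non-empty row subset,
pseudonymize it, and compare every non-ID cell of the relabeled table
against the source. Any mismatch or duplicate-ID occurrence is a
counted failure with the first discrepancy recorded. The package's
reference protocol — used by the acceptance script and the test suite
— is a 581-row table and 1000 repetitions, with a fault-injection
control (`corrupt_cells=1`) to confirm the comparator actually detects
corruption. Validation covers the tabular relabeling only; image
integrity is covered separately by byte-identity checks on packaged
members.

## Defacing

The built-in backend is intensity-based skull-stripping: with `p2` and
`p98` the 2nd/98th percentiles over nonzero voxels, the threshold is

    t = p2 + f · (p98 − p2),   f ∈ [0, 1]

followed by largest 6-connected component extraction and a
radius-1 binary closing. Because the mask is a thresholded superlevel
set intersected with deterministic morphology, masks are nested
(monotonically shrinking) in `f`. The backend is a deliberate
stand-in: when FSL `bet` is on `PATH` it is preferred (invoked with
`FSLOUTPUTTYPE=NIFTI`), and the builtin exists so the pipeline,
its QC and its tests run without external tools. It is adequate for
the high-contrast synthetic phantom; on real heads with intensity
inhomogeneity or low face/brain contrast a validated tool such as
`bet` should be used. QC compares pre/post volumes against caller-
supplied regions and reports per-region retention fractions; the
montage renderer loads one volume pair at a time so memory stays
bounded in the number of subjects.

## Synthetic fixtures

The head phantom is a 64×64×40 int16 volume: a brain ellipsoid at
intensity 1000, an adjacent 2-voxel skull shell at 450, a face wedge
at 300 placed strictly beyond the anterior skull boundary, and
additive Gaussian noise (σ = 20), all from a seeded generator with
ground-truth brain and face masks returned alongside. The intensity
triplet is chosen so the builtin threshold at `f = 0.5` falls between
skull and brain — i.e. the phantom is constructed to have a correct
answer, and region overlap or out-of-grid placement is rejected at
construction. The demographic generator produces ID, name, date and
measurement columns with controllable missingness, plus a planted
extreme value (AGE 96) that exercises range-band generalization.

These fixtures are deliberately idealized: piecewise-constant
intensities, no bias field, no partial-volume effects, no anatomical
variability, and filenames that follow the ID conventions exactly.
They validate the machinery — thresholding, connectivity, matching,
relabeling, leak scanning — not clinical-grade defacing performance,
which must be assessed on real data with a real stripping tool.

## Tabular conventions and numerics

- Missing cells are a dedicated `MISSING` sentinel (never a string),
  recognized on input from `"", NA, NaN, N/A, .` case-insensitively
  and written back as a configurable code (default `NA`), so
  load→write round trips are lossless.
- Identifier detection flags column 0 (the ID column) always, columns
  whose names contain identifier substrings (name, dob, date, address,
  phone, ssn, mrn, email, zip), and columns where ≥ 80% of non-missing
  cells parse as dates — a threshold chosen to tolerate stray
  malformed entries without flagging numeric columns that merely
  contain a date-like value.
- Generalization: bin-rounding uses half-away-from-zero rounding
  (`floor(x/w + 0.5)·w`) rather than banker's rounding so equal-width
  bins behave as users expect at bin edges; significant-figure
  rounding and `[lo, hi)` range bands are also provided. `MISSING`
  passes through every rule unchanged.
- Percentiles in the defacer are computed over nonzero voxels only, so
  large zero backgrounds cannot drag the robust range down; an
  all-zero volume is returned unchanged with an explicit
  removed-fraction of 0 rather than an error.
- All randomized procedures take explicit integer seeds and use
  private generator instances (`random.Random` / numpy `Generator`),
  never global state, so identical inputs and seeds reproduce byte-
  identical outputs end to end.

## Leak scanning and packaging

The scan is a case-sensitive substring search for every original ID
and every dropped identifier value over: output filenames, every table
cell, every editable header field of every readable image, and the
manifest text. Substring matching over-triggers by design (a short ID
inside an unrelated token is still a finding) — false positives cost a
review, false negatives cost a disclosure. An unreadable header stops
only the header-field scan for that file; its filename is still
scanned. Packaging requires an attested manifest and a clean report;
an override must be explicit and is recorded in the shipped log.
Archive members are added in sorted path order, so the layout is a
deterministic function of the content.

## Limitations

- The leak scan is exact-substring only: transformations of an ID
  (re-encodings, checksums, embedded dates) are not detected.
- Defacing guarantees are demonstrated on the synthetic phantom; the
  builtin stripper is not validated for clinical data.
- Only the NIfTI-1/Analyze 7.5 single-volume formats and four
  datatypes are handled; DICOM, NIfTI-2 and compressed `.nii.gz` are
  out of scope.
- Generalization reduces, but does not quantify, re-identification
  risk; the package implements mechanisms, not a formal privacy model
  such as k-anonymity or differential privacy.
- Identifier-column detection is heuristic (names and date fraction);
  it is a reviewing aid, and the operator's attestation remains the
  final gate.
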