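# deid

Headless de-identification of linked neuroimaging datasets: structural
brain volumes (NIfTI-1 `.nii` or `.hdr`/`.img`, Analyze 7.5
`.hdr`/`.img`) together with the demographic/behavioral table that keys
them by subject ID.

Sharing human-subject imaging data requires more than deleting a name
column. The image headers themselves carry free-text fields (patient
ID, scan number, experiment date) that can re-identify a subject; the
voxels representing the face can be surface-rendered and matched to a
photograph; quasi-identifiers like an extreme age can single a subject
out of a released table; and the link between the old subject labels
and the new ones must be severed so the shared IDs cannot be tracked
back. `deid` automates that whole workflow for researchers preparing a
limited dataset, with every step audited and every unsafe step refused.

## What it does

1. **Format detection & header auditing** — both formats share a
   348-byte binary header; NIfTI is identified by the 4 magic bytes at
   offset 344 (`n+1\0` single-file, `ni1\0` pair), Analyze by their
   absence. Every field is decoded with its byte offset and an
   *editable* flag: free-text history fields can be edited or
   zero-filled (scrubbed), geometry/codec fields (dimensions, datatype,
   transforms) are protected. Re-encoding an untouched header is
   byte-identical; an edit changes only its own field's byte span.
2. **Associative matching** — each subject ID from the table's first
   column is linked to the image file(s) carrying that ID in the
   filename (exact stem, `{id}` wildcard pattern, bounded substring, or
   path component). IDs are matched longest-first so `S1` can never
   steal `S10.nii`; unresolvable claims are an error, missing images
   are reported as `MISMATCH`.
3. **Table auditing & generalization** — missing cells are located,
   likely identifier columns (names, dates of birth, test dates) are
   auto-flagged and dropped, and continuous quasi-identifiers can be
   generalized by bin-rounding, significant figures, or range bands
   (a 96-year-old becomes `[90, 100)`).
4. **Anonymization** — new random IDs (`SUB` + zero-padded integer) are
   drawn from a seeded RNG and redrawn until there is no duplication
   with the original IDs; images are copied under the new stems and the
   table's ID column is rewritten. The original↔new key file is written
   *outside* the shareable directory and can never enter the package.
   A validation mode re-runs anonymize-and-compare over random row
   subsets (the reference protocol: 1000 repetitions) and reports any
   cell mismatch or duplicate-ID violation.
5. **Defacing & QC** — voxels representing the face are removed by
   skull-stripping, via FSL `bet` when installed or a built-in
   fractional-intensity stripper otherwise (threshold
   `t = p2 + f·(p98 − p2)` over the robust intensity range, largest
   6-connected component, morphological closing; `f = 0.5` default,
   raise `f` to remove more). QC reports removed fractions and a
   side-by-side montage, loading one volume pair at a time.
6. **Leak scanning & packaging** — after attestation, every output
   filename, table cell, editable header field and the manifest are
   substring-searched for every original ID and every dropped
   identifier value; findings block packaging. The clean set is
   packaged as a deterministic `tar.gz` with a log of who prepared the
   data, where, when, and under which sharing level (open access, data
   enclave, or recipient-only).

A `synthdata` module generates deterministic head phantoms (with
ground-truth brain/face masks) and demographic tables (with planted
identifiers and missing cells) so the whole pipeline is testable
without any external data.

## Worked example

```sh
$ deid synth --subjects 3 --out data --seed 4
wrote 3 subjects to data

$ deid table audit data/demographics.tsv
3 rows x 10 columns
missing cells: 0
identifier: ID (id_label) subject-ID column
identifier: NAME (name_pattern) column name contains 'name'
identifier: DOB (name_pattern) column name contains 'dob'
identifier: TESTDATE (name_pattern) column name contains 'date'

$ deid run --table data/demographics.tsv --images data --out shared \
      --seed 9 --contributor "Jean Doe" --institution "Example U" --attest
package: shared/deid_package.tar.gz
shared table: shared/table.tsv
audit log: shared/audit_log.json
```

The shared table now carries random IDs and none of the flagged
columns:

```
ID       SEX  AGE  HEIGHT  WEIGHT  SCORE1  SCORE2
SUB7585  F    35   163.8   76.8    38      25.88
SUB6116  F    78   192.5   52      99      66.53
SUB4376  F    23   184.8   53      13      49.95
```

The archive holds the defaced, header-scrubbed images under their new
names plus the table and the sharing log — and nothing else:

```
images/SUB4376.nii  images/SUB6116.nii  images/SUB7585.nii
table.tsv  deid_share.log
```

The self-test confirms the relabeling never touches a data cell:

```sh
$ deid validate --table data/demographics.tsv --reps 100 --seed 2
repetitions: 100
failures: 0
duplicate_id_violations: 0
```

Omitting `--attest`, or any original ID surviving into a filename,
table cell or header field, aborts the run with a non-zero exit before
anything is packaged.

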