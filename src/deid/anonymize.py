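"""Collision-free subject relabeling and its automated validation.

New subject IDs are random labels (prefix + zero-padded integer) drawn
from a seeded RNG; any candidate that collides with an original ID or a
previously drawn label is rejected and redrawn, so the new-ID set is
always disjoint from the originals.  The link between original and new
IDs is written to a key file kept OUTSIDE the shareable output — the
shared package never contains it.

Validation mirrors an anonymize-and-compare protocol: repeatedly sample
a random row subset, relabel it, and verify every non-ID cell survives
unchanged and no new ID duplicates an original.
"""

from __future__ import annotations

import os
import random
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .errors import DeidError, MatchError
from .matching import MatchStatus, MatchTable
from .tabular import CellRef, DatasetTable, write_table


@dataclass(frozen=True)
class IdScheme:
    prefix: str = "SUB"
    digits: int = 4


@dataclass(frozen=True)
class IdMap:
    pairs: dict[str, str]
    scheme: IdScheme
    seed: int

    def __post_init__(self):
        new = list(self.pairs.values())
        if len(set(new)) != len(new):
            raise DeidError("new IDs are not unique")
        if set(new) & set(self.pairs):
            raise DeidError("a new ID collides with an original ID")

    def __getitem__(self, original: str) -> str:
        return self.pairs[original]


def generate_id_map(
    original_ids: Sequence[str],
    scheme: IdScheme = IdScheme(),
    seed: int = 0,
) -> IdMap:
    """Draw a collision-free random relabeling of the original IDs.

    Candidates colliding with an original ID (or an earlier draw) are
    rejected and redrawn; the digit width widens automatically when a
    width's label space is exhausted.  Deterministic for a fixed seed.
    """
    originals = list(original_ids)
    if not originals:
        raise DeidError("no original IDs supplied")
    if len(set(originals)) != len(originals):
        raise DeidError("original IDs are not unique")
    rng = random.Random(seed)
    forbidden = set(originals)
    pairs: dict[str, str] = {}
    digits = scheme.digits
    tried: set[int] = set()
    for orig in originals:
        while True:
            space = 10 ** digits
            if len(tried) >= space:
                digits += 1
                tried = set()
                continue
            n = rng.randrange(space)
            if n in tried:
                continue
            tried.add(n)
            label = f"{scheme.prefix}{n:0{digits}d}"
            if label in forbidden:
                continue
            pairs[orig] = label
            forbidden.add(label)
            break
    return IdMap(pairs=pairs, scheme=IdScheme(scheme.prefix, digits), seed=seed)


def relabel_table(table: DatasetTable, id_map: IdMap) -> DatasetTable:
    """Rewrite column 0 with the new IDs; every other cell is untouched."""
    rows = []
    for r in table.rows:
        orig = str(r[0])
        if orig not in id_map.pairs:
            raise DeidError(f"subject {orig!r} has no entry in the ID map")
        rows.append((id_map.pairs[orig], *r[1:]))
    return DatasetTable(
        column_names=table.column_names, rows=tuple(rows), missing_code=table.missing_code
    )


@dataclass(frozen=True)
class AnonymizedDataset:
    table: DatasetTable
    out_dir: Path
    image_map: dict[str, tuple[Path, ...]]  # new_id -> copied image paths
    key_path: Path


def _copy_logical_image(src: Path, dest_stem: Path) -> tuple[Path, ...]:
    if src.suffix.lower() == ".nii":
        dest = dest_stem.with_suffix(".nii")
        shutil.copyfile(src, dest)
        return (dest,)
    hdr = dest_stem.with_suffix(".hdr")
    img = dest_stem.with_suffix(".img")
    shutil.copyfile(src, hdr)
    shutil.copyfile(src.with_suffix(".img"), img)
    return (hdr, img)


def apply_id_map(
    match_table: MatchTable,
    table: DatasetTable,
    id_map: IdMap,
    out_dir: str | os.PathLike,
    key_path: str | os.PathLike | None = None,
) -> AnonymizedDataset:
    """Materialize the anonymized dataset in ``out_dir``.

    Matched images are copied under their new-ID stems (multi-image
    subjects get ``newid_1``, ``newid_2``, ... in sorted source order);
    column 0 of the table is rewritten; the original↔new key file is
    written OUTSIDE ``out_dir`` (default: sibling ``<name>_idmap_key.tsv``)
    and must never enter the shared package.  Source files are untouched.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    new_table = relabel_table(table, id_map)

    image_map: dict[str, tuple[Path, ...]] = {}
    for entry in match_table.entries:
        if entry.status is not MatchStatus.MATCHED:
            continue
        new_id = id_map[entry.subject_id]
        copied: list[Path] = []
        if len(entry.paths) == 1:
            dest = out / new_id
            if any(d.exists() for d in (dest.with_suffix(".nii"), dest.with_suffix(".hdr"))):
                raise MatchError(f"output collision at {dest}")
            copied.extend(_copy_logical_image(entry.paths[0], dest))
        else:
            for k, src in enumerate(sorted(entry.paths), start=1):
                copied.extend(_copy_logical_image(src, out / f"{new_id}_{k}"))
        image_map[new_id] = tuple(copied)

    if key_path is None:
        key_path = out.parent / f"{out.name}_idmap_key.tsv"
    key_path = Path(key_path)
    with open(key_path, "w", encoding="utf-8") as fh:
        fh.write("original_id\tnew_id\n")
        for orig, new in id_map.pairs.items():
            fh.write(f"{orig}\t{new}\n")

    return AnonymizedDataset(
        table=new_table, out_dir=out, image_map=image_map, key_path=key_path
    )


@dataclass(frozen=True)
class ValidationReport:
    repetitions: int
    failures: int
    duplicate_id_violations: int
    first_failure: tuple[int, CellRef] | None = None

    def __post_init__(self):
        assert self.failures <= self.repetitions


def validate_round_trip(
    original_table: DatasetTable,
    repetitions: int = 1000,
    seed: int = 0,
    corrupt_cells: int = 0,
) -> ValidationReport:
    """Anonymize-and-compare self-test over random row subsets.

    Each repetition draws a uniformly random non-empty subset of rows
    (without replacement), relabels it with a fresh seeded ID map, then
    compares every non-ID cell of the relabeled table against the source
    under the map.  ``corrupt_cells`` > 0 injects that many cell
    corruptions per repetition (fault-injection mode, used to prove the
    comparison actually catches errors).
    """
    original_table.validate_ids()
    n = original_table.n_rows
    all_ids = set(original_table.ids)
    failures = 0
    dup_violations = 0
    first_failure: tuple[int, CellRef] | None = None
    for rep in range(repetitions):
        rng = random.Random(seed + rep)
        k = rng.randint(1, n)
        idx = sorted(rng.sample(range(n), k))
        sub = DatasetTable(
            column_names=original_table.column_names,
            rows=tuple(original_table.rows[i] for i in idx),
            missing_code=original_table.missing_code,
        )
        id_map = generate_id_map(sub.ids, seed=seed + rep)
        out = relabel_table(sub, id_map)
        if set(id_map.pairs.values()) & all_ids:
            dup_violations += 1
        rows = [list(r) for r in out.rows]
        for _ in range(corrupt_cells):
            i = rng.randrange(len(rows))
            j = rng.randrange(1, len(out.column_names))
            rows[i][j] = "__CORRUPTED__"
        rep_failed = False
        for i, (got, want) in enumerate(zip(rows, sub.rows)):
            if str(got[0]) != id_map[str(want[0])]:
                rep_failed = True
                if first_failure is None:
                    first_failure = (rep, CellRef(i, 0))
                break
            for j in range(1, len(want)):
                if got[j] != want[j]:
                    rep_failed = True
                    if first_failure is None:
                        first_failure = (rep, CellRef(i, j))
                    break
            if rep_failed:
                break
        if rep_failed:
            failures += 1
    return ValidationReport(
        repetitions=repetitions,
        failures=failures,
        duplicate_id_violations=dup_violations,
        first_failure=first_failure,
    )
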