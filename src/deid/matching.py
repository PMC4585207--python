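"""Associative matching of image files to subject IDs.

Each subject ID from the table's first column is linked to the image
file(s) whose name (or path) carries that ID.  A .hdr/.img pair is one
logical image keyed by its shared stem.  Matching is greedy
longest-ID-first so that "S1" can never steal "S10.nii"; a file
claimable by two same-length IDs is an ambiguity error rather than a
silent first-match.
"""

from __future__ import annotations

import fnmatch
import os
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .errors import AmbiguousMatchError, MatchError, TableError
from .tabular import MISSING, DatasetTable

IMAGE_SUFFIXES = {".nii", ".hdr", ".img"}


class MatchStatus(Enum):
    MATCHED = "MATCHED"
    MISMATCH = "MISMATCH"


@dataclass(frozen=True)
class MatchOptions:
    search_full_path: bool = False
    allow_multiple_per_subject: bool = False
    pattern: str | None = None  # glob template containing "{id}" exactly once
    fill_missing_code: bool = False
    ignore_case: bool = False

    def __post_init__(self):
        if self.pattern is not None and self.pattern.count("{id}") != 1:
            raise MatchError("pattern must contain the {id} placeholder exactly once")


@dataclass(frozen=True)
class MatchEntry:
    subject_id: str
    paths: tuple[Path, ...]
    status: MatchStatus


@dataclass(frozen=True)
class MatchTable:
    entries: tuple[MatchEntry, ...]
    unmatched_files: tuple[Path, ...]

    def entry(self, subject_id: str) -> MatchEntry:
        for e in self.entries:
            if e.subject_id == subject_id:
                return e
        raise KeyError(subject_id)

    @property
    def matched(self) -> tuple[MatchEntry, ...]:
        return tuple(e for e in self.entries if e.status is MatchStatus.MATCHED)

    @property
    def mismatches(self) -> tuple[MatchEntry, ...]:
        return tuple(e for e in self.entries if e.status is MatchStatus.MISMATCH)


def logical_images(paths: Iterable[str | os.PathLike]) -> list[Path]:
    """Collapse .hdr/.img pairs to one logical image (the .hdr path).

    A lone .img without its .hdr is an error; .nii files pass through.
    """
    paths = [Path(p) for p in paths]
    out: list[Path] = []
    stems = {p.with_suffix(""): p for p in paths if p.suffix.lower() == ".hdr"}
    for p in sorted(paths):
        suf = p.suffix.lower()
        if suf == ".nii" or suf == ".hdr":
            out.append(p)
        elif suf == ".img":
            if p.with_suffix("") not in stems:
                raise MatchError(f"{p}: voxel file without a .hdr sibling")
        else:
            raise MatchError(f"{p}: unsupported image suffix")
    return out


def _norm(s: str, opts: MatchOptions) -> str:
    return s.lower() if opts.ignore_case else s


def _bounded_contains(haystack: str, needle: str) -> bool:
    """needle appears in haystack bounded by non-alphanumerics or edges."""
    return re.search(
        rf"(?<![A-Za-z0-9]){re.escape(needle)}(?![A-Za-z0-9])", haystack
    ) is not None


def _candidate_tier(path: Path, sid: str, opts: MatchOptions) -> int | None:
    """Best (lowest) matching tier for this file/ID, or None."""
    base = _norm(path.stem, opts)
    sid_n = _norm(sid, opts)
    if base == sid_n:
        return 1
    if opts.pattern is not None:
        pat = _norm(opts.pattern.replace("{id}", sid), opts)
        name = _norm(path.name, opts)
        if fnmatch.fnmatchcase(base, pat) or fnmatch.fnmatchcase(name, pat):
            return 2
    if _bounded_contains(base, sid_n):
        return 3
    if opts.search_full_path:
        if any(_norm(part, opts) == sid_n for part in path.parent.parts):
            return 4
    return None


def match_images(
    table: DatasetTable,
    image_paths: Sequence[str | os.PathLike],
    options: MatchOptions = MatchOptions(),
) -> MatchTable:
    """Associate each table ID with its image file(s).

    IDs are processed longest-first; within a length group a file wanted
    by two IDs raises :class:`AmbiguousMatchError`.  Subjects with no
    candidate file get MISMATCH status; files claimed by no subject are
    reported as unmatched.
    """
    table.validate_ids()
    files = logical_images(image_paths)
    ids = list(table.ids)
    claimed: dict[Path, str] = {}
    assignment: dict[str, list[Path]] = {sid: [] for sid in ids}

    by_length: dict[int, list[str]] = {}
    for sid in ids:
        by_length.setdefault(len(sid), []).append(sid)

    for length in sorted(by_length, reverse=True):
        group = sorted(by_length[length])
        # candidate sets at each ID's best tier, over still-unclaimed files
        cand: dict[str, list[Path]] = {}
        for sid in group:
            tiers: dict[int, list[Path]] = {}
            for p in files:
                if p in claimed:
                    continue
                t = _candidate_tier(p, sid, options)
                if t is not None:
                    tiers.setdefault(t, []).append(p)
            if tiers:
                cand[sid] = tiers[min(tiers)]
        seen: dict[Path, str] = {}
        for sid, paths in cand.items():
            for p in paths:
                if p in seen:
                    raise AmbiguousMatchError(
                        f"{p} is claimable by both {seen[p]!r} and {sid!r}"
                    )
                seen[p] = sid
        for sid, paths in cand.items():
            if len(paths) > 1 and not options.allow_multiple_per_subject:
                raise MatchError(
                    f"subject {sid!r} matches {len(paths)} images; "
                    "enable multiple-images-per-subject to accept this"
                )
            for p in paths:
                claimed[p] = sid
                assignment[sid].append(p)

    entries = tuple(
        MatchEntry(
            sid,
            tuple(sorted(assignment[sid])),
            MatchStatus.MATCHED if assignment[sid] else MatchStatus.MISMATCH,
        )
        for sid in ids
    )
    unmatched = tuple(p for p in files if p not in claimed)
    return MatchTable(entries=entries, unmatched_files=unmatched)


def infer_id(path: str | os.PathLike, options: MatchOptions = MatchOptions()) -> str:
    """Infer the subject ID carried by an image filename.

    With an ``{id}`` pattern the placeholder's text is extracted; without
    one the basename-without-extension is the ID.
    """
    p = Path(path)
    if options.pattern is not None:
        token = "xIDxPLACEHOLDERx"  # alphanumeric: survives fnmatch.translate verbatim
        glob_re = fnmatch.translate(options.pattern.replace("{id}", token))
        glob_re = glob_re.replace(token, "(?P<id>.+?)")
        for target in (p.stem, p.name):
            m = re.match(glob_re, target)
            if m:
                return m.group("id")
    return p.stem


def fill_missing_rows(
    table: DatasetTable, match_table: MatchTable, options: MatchOptions = MatchOptions()
) -> DatasetTable:
    """Append an all-MISSING row for each unmatched file's inferred ID.

    Mirrors the missing-data-code option: an image present for a case
    absent from the data file gains a placeholder row so the association
    survives de-identification.
    """
    existing = set(table.ids)
    new_ids: list[str] = []
    for p in match_table.unmatched_files:
        sid = infer_id(p, options)
        if sid in existing:
            raise TableError(
                f"inferred ID {sid!r} for {p} collides with an existing row"
            )
        if sid not in new_ids:
            new_ids.append(sid)
    if not new_ids:
        return table
    blank = (MISSING,) * (len(table.column_names) - 1)
    rows = table.rows + tuple((sid, *blank) for sid in new_ids)
    return DatasetTable(
        column_names=table.column_names, rows=rows, missing_code=table.missing_code
    )
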