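"""Audited packaging of the de-identified dataset.

Before anything leaves the machine the operator must attest that the
data were inspected, and an automatic leak scan searches every output
filename, table cell, editable header field and the manifest itself for
any original subject ID or dropped identifier value.  A clean scan (or
an explicit, logged override) gates the tar.gz build; the ID key file
can never enter the archive.
"""

from __future__ import annotations

import datetime as _dt
import os
import tarfile
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

from . import __version__
from .errors import AttestationError, DeidError, LeakError
from .formats import read_header
from .tabular import MISSING, DatasetTable


class SharingLevel(Enum):
    OPEN = "open"                    # open access
    ENCLAVE = "enclave"              # data enclave / secure computing environment
    RECIPIENT_ONLY = "recipient"     # only the named recipient investigators


@dataclass(frozen=True)
class ShareManifest:
    contributor: str
    institution: str
    sharing_level: SharingLevel
    attestation: bool
    timestamp: str
    tool_version: str

    def serialize(self) -> str:
        return (
            f"contributor: {self.contributor}\n"
            f"institution: {self.institution}\n"
            f"sharing_level: {self.sharing_level.value}\n"
            f"attestation: {str(self.attestation).lower()}\n"
            f"timestamp: {self.timestamp}\n"
            f"tool_version: {self.tool_version}\n"
        )


def build_manifest(
    contributor: str,
    institution: str,
    sharing_level: str | SharingLevel,
    attestation: bool,
) -> ShareManifest:
    """Build the sharing log entry: who prepared the data, where, when.

    ``attestation`` must be true — the operator's statement that the
    data were inspected and contain no personal health identifiers is a
    required step, not a formality.
    """
    if not contributor.strip():
        raise DeidError("contributor name must be non-empty")
    if not institution.strip():
        raise DeidError("institution must be non-empty")
    if not attestation:
        raise AttestationError(
            "packaging requires attestation that the data has been inspected"
        )
    level = sharing_level if isinstance(sharing_level, SharingLevel) else SharingLevel(sharing_level)
    return ShareManifest(
        contributor=contributor.strip(),
        institution=institution.strip(),
        sharing_level=level,
        attestation=True,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        tool_version=__version__,
    )


class LeakKind(Enum):
    FILENAME = "filename"
    TABLE_CELL = "table_cell"
    HEADER_FIELD = "header_field"
    MANIFEST = "manifest"


@dataclass(frozen=True)
class LeakFinding:
    kind: LeakKind
    location: str
    matched: str


@dataclass(frozen=True)
class LeakReport:
    findings: tuple[LeakFinding, ...]

    @property
    def clean(self) -> bool:
        return not self.findings


def scan_for_leaks(
    dataset_dir: str | os.PathLike,
    table: DatasetTable,
    original_ids: Iterable[str],
    dropped_values: Iterable[str] = (),
    manifest: ShareManifest | None = None,
) -> LeakReport:
    """Search the shareable set for any original ID or dropped identifier.

    Case-sensitive substring search over output filenames, every table
    cell, every editable header field of every image, and the manifest
    text.  Every hit is a finding; an empty report means clean.
    """
    needles = sorted({str(s) for s in original_ids if str(s)})
    needles += sorted({str(v) for v in dropped_values if v is not MISSING and str(v)})
    findings: list[LeakFinding] = []
    root = Path(dataset_dir)

    def hits(text: str) -> list[str]:
        return [n for n in needles if n in text]

    for p in sorted(root.rglob("*")):
        if not p.is_file():
            continue
        for n in hits(p.name):
            findings.append(LeakFinding(LeakKind.FILENAME, str(p), n))
        if p.suffix.lower() in (".hdr", ".nii"):
            try:
                hdr = read_header(p)
            except DeidError:
                continue  # unreadable header: the filename scan still applies
            for fname in hdr.editable_fields:
                for n in hits(str(hdr[fname])):
                    findings.append(
                        LeakFinding(LeakKind.HEADER_FIELD, f"{p}:{fname}", n)
                    )

    for i, row in enumerate(table.rows):
        for j, cell in enumerate(row):
            if cell is MISSING:
                continue
            for n in hits(str(cell)):
                findings.append(
                    LeakFinding(
                        LeakKind.TABLE_CELL,
                        f"row {i}, column {table.column_names[j]}",
                        n,
                    )
                )

    if manifest is not None:
        for n in hits(manifest.serialize()):
            findings.append(LeakFinding(LeakKind.MANIFEST, "manifest", n))

    return LeakReport(findings=tuple(findings))


def package_dataset(
    dataset_dir: str | os.PathLike,
    table_path: str | os.PathLike,
    manifest: ShareManifest,
    out_path: str | os.PathLike,
    leak_report: LeakReport | None = None,
    force: bool = False,
) -> Path:
    """Build the shareable tar.gz: images/, the table, and the log file.

    Refuses when the manifest is unattested, when the leak report has
    findings (unless ``force`` overrides, which is noted in the log
    member), or when an ID key file sits inside ``dataset_dir``.
    Members are added in sorted path order so the archive layout is
    deterministic for fixed inputs; extraction reproduces every member
    byte-identically.
    """
    if not manifest.attestation:
        raise AttestationError("manifest is not attested; refusing to package")
    if leak_report is not None and not leak_report.clean and not force:
        raise LeakError(
            f"leak scan found {len(leak_report.findings)} finding(s); "
            "refusing to package (use force to override)"
        )
    root = Path(dataset_dir)
    key_files = sorted(root.rglob("*idmap_key*"))
    if key_files:
        raise LeakError(f"ID key file inside dataset dir: {key_files[0]}")

    log_text = manifest.serialize()
    if force and leak_report is not None and not leak_report.clean:
        log_text += f"leak_override: true ({len(leak_report.findings)} findings)\n"

    out_path = Path(out_path)
    log_path = out_path.with_suffix(".log")
    log_path.write_text(log_text, encoding="utf-8")
    with tarfile.open(out_path, "w:gz") as tar:
        for p in sorted(root.rglob("*")):
            if p.is_file():
                tar.add(p, arcname=f"images/{p.relative_to(root)}")
        tp = Path(table_path)
        tar.add(tp, arcname=tp.name)
        tar.add(log_path, arcname="deid_share.log")
    return out_path
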