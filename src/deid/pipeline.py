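"""End-to-end de-identification pipeline.

Stage order follows the data flow of the underlying architecture:
match -> variable audit/drop -> generalization -> anonymization (new
IDs, file renaming) -> defacing -> header scrubbing -> leak scan ->
packaging.  The scrub runs before the leak scan so the scan verifies
it; any gate failure stops the run with the failing stage's name.

Every stage is appended to an audit log (stage, parameters, UTC
timestamp) so a de-identification error can later be traced to who ran
what, when.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import anonymize, deface, formats, matching, packaging, tabular
from .errors import DeidError, PipelineError
from .tabular import MISSING


@dataclass
class RunConfig:
    """Everything a full run needs; loadable from TOML/YAML with CLI override."""

    table: str = ""
    images: str = ""                 # directory holding the source images
    out: str = ""                    # working/output directory
    seed: int = 0
    # matching
    pattern: str | None = None
    multiple: bool = False
    search_path: bool = False
    fill_missing: bool = False
    # tabular
    auto_drop: bool = True
    generalize: list[dict] = field(default_factory=list)  # {column, kind, parameter}
    # anonymization
    prefix: str = "SUB"
    digits: int = 4
    # defacing
    f: float = 0.5
    backend: str = "auto"
    no_strip: bool = False
    # packaging
    contributor: str = ""
    institution: str = ""
    level: str = "open"
    attest: bool = False

    def merged(self, **overrides) -> "RunConfig":
        """CLI flags take precedence over file values; None means unset."""
        vals = dataclasses.asdict(self)
        for k, v in overrides.items():
            if v is not None:
                vals[k] = v
        return RunConfig(**vals)


@dataclass
class PipelineResult:
    archive: Path
    shared_table: Path
    out_dir: Path
    id_map: anonymize.IdMap
    audit_log: list[dict]


def collect_images(images_dir: str | os.PathLike) -> list[Path]:
    root = Path(images_dir)
    return sorted(
        p for p in root.rglob("*") if p.suffix.lower() in matching.IMAGE_SUFFIXES
    )


def _scrub_file_header(path: Path) -> None:
    hdr = formats.read_header(path)
    blob = formats.encode_header(formats.scrub_header(hdr))
    with open(path, "r+b") as fh:
        fh.write(blob)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline; raises :class:`PipelineError` on the
    first failing stage (the CLI turns that into a non-zero exit)."""
    log: list[dict] = []

    def stage(name: str, fn, **params):
        log.append({
            "stage": name,
            "params": {k: str(v) for k, v in params.items()},
            "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        })
        try:
            return fn()
        except DeidError as e:
            raise PipelineError(name, e) from e
        except OSError as e:
            raise PipelineError(name, e) from e

    out_root = Path(config.out)
    out_root.mkdir(parents=True, exist_ok=True)
    shared = out_root / "shared_images"

    table = stage("load_table", lambda: tabular.load_table(config.table),
                  table=config.table)
    original_ids = list(table.ids)

    opts = matching.MatchOptions(
        search_full_path=config.search_path,
        allow_multiple_per_subject=config.multiple,
        pattern=config.pattern,
        fill_missing_code=config.fill_missing,
    )
    images = collect_images(config.images)
    match = stage("match", lambda: matching.match_images(table, images, opts),
                  images=len(images))
    if config.fill_missing:
        table = stage("fill_missing_rows",
                      lambda: matching.fill_missing_rows(table, match, opts))
        original_ids = list(table.ids)
        match = stage("rematch", lambda: matching.match_images(table, images, opts))

    dropped_values: list[str] = []
    if config.auto_drop:
        findings = tabular.detect_identifier_columns(table)
        to_drop = [f.column for f in findings
                   if f.reason is not tabular.FindingReason.ID_LABEL]
        for col in to_drop:
            dropped_values += [str(v) for v in table.column(col)
                               if v is not MISSING]
        table = stage("drop_identifiers",
                      lambda: tabular.drop_columns(table, to_drop),
                      columns=",".join(to_drop))

    for spec in config.generalize:
        rule = tabular.GeneralizationRule(
            column=spec["column"],
            kind=tabular.GeneralizationKind(spec.get("kind", "bin_round")),
            parameter=float(spec["parameter"]),
        )
        table = stage("generalize",
                      lambda t=table, r=rule: tabular.generalize_column(t, r),
                      column=rule.column, kind=rule.kind.value,
                      parameter=rule.parameter)

    id_map = stage(
        "generate_id_map",
        lambda: anonymize.generate_id_map(
            table.ids,
            anonymize.IdScheme(config.prefix, config.digits),
            seed=config.seed,
        ),
        seed=config.seed,
    )
    dataset = stage(
        "apply_id_map",
        lambda: anonymize.apply_id_map(
            match, table, id_map, shared, key_path=out_root / "idmap_key.tsv"
        ),
    )

    if not config.no_strip:
        def deface_all():
            for p in matching.logical_images(
                q for q in sorted(shared.iterdir()) if q.is_file()
            ):
                vol = formats.read_volume(p)
                result = deface.skull_strip(vol, f=config.f, backend=config.backend)
                formats.write_volume(result.stripped, p)
        stage("deface", deface_all, f=config.f, backend=config.backend)

    def scrub_all():
        for p in sorted(shared.iterdir()):
            if p.suffix.lower() in (".hdr", ".nii"):
                _scrub_file_header(p)
    stage("scrub_headers", scrub_all)

    shared_table = out_root / "table.tsv"
    stage("write_table", lambda: tabular.write_table(dataset.table, shared_table))

    manifest = stage(
        "manifest",
        lambda: packaging.build_manifest(
            config.contributor, config.institution, config.level, config.attest
        ),
        level=config.level, attest=config.attest,
    )
    leaks = stage(
        "leak_scan",
        lambda: packaging.scan_for_leaks(
            shared, dataset.table, original_ids, dropped_values, manifest
        ),
    )
    archive = stage(
        "package",
        lambda: packaging.package_dataset(
            shared, shared_table, manifest, out_root / "deid_package.tar.gz", leaks
        ),
    )

    (out_root / "audit_log.json").write_text(
        json.dumps(log, indent=2), encoding="utf-8"
    )
    return PipelineResult(
        archive=archive,
        shared_table=shared_table,
        out_dir=out_root,
        id_map=id_map,
        audit_log=log,
    )
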