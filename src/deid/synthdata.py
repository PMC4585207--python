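"""Synthetic head volumes and demographic tables for testing.

Nothing here resembles real anatomy: the "head" is a bright brain
ellipsoid wrapped in a medium-intensity skull shell with a dim wedge
protruding from the anterior surface standing in for the face, over a
noisy zero background.  What matters is the contract: the generator
records ground-truth brain/face masks and planted identifiers/missing
cells, so every other module can be tested against known truth without
downloading data.  Intensities are calibrated so the builtin stripper
at f = 0.5 keeps the brain and removes the face wedge.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DeidError
from .formats import FormatKind, Volume, edit_header_field, make_header, write_volume
from .tabular import MISSING, CellRef, DatasetTable


@dataclass(frozen=True)
class FixtureSpec:
    """Geometry and intensities of the synthetic head phantom."""

    dims: tuple[int, int, int] = (64, 64, 40)
    brain_center: tuple[float, float, float] = (32.0, 30.0, 21.0)
    brain_axes: tuple[float, float, float] = (20.0, 22.0, 13.0)
    brain_intensity: float = 1000.0
    skull_thickness: float = 2.0
    skull_intensity: float = 450.0
    face_intensity: float = 300.0
    noise_sd: float = 20.0
    seed: int = 0


@dataclass(frozen=True)
class HeadFixture:
    volume: Volume
    brain_mask: np.ndarray
    face_mask: np.ndarray
    path: Path | None = None  # header-bearing file when written to disk


def _ellipsoid(coords, center, axes) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = axes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def make_head_volume(
    spec: FixtureSpec = FixtureSpec(),
    kind: FormatKind = FormatKind.NIFTI_SINGLE,
    out_dir: str | os.PathLike | None = None,
    stem: str = "head",
    patient_id: str | None = None,
) -> HeadFixture:
    """Build the phantom, optionally writing it in any supported format.

    ``patient_id`` plants an identifier in the header's free-text fields
    (patient_id for Analyze, descrip otherwise) for scrub/leak tests.
    Deterministic for a fixed spec seed.
    """
    nx, ny, nz = spec.dims
    coords = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    brain = _ellipsoid(coords, spec.brain_center, spec.brain_axes)
    outer_axes = tuple(a + spec.skull_thickness for a in spec.brain_axes)
    skull = _ellipsoid(coords, spec.brain_center, outer_axes) & ~brain

    # Face wedge: a dim box just beyond the anterior (+y) skull surface,
    # adjacent to it so low thresholds merge it into the head component.
    cx, cy, cz = spec.brain_center
    y0 = int(np.floor(cy + outer_axes[1])) + 1  # first plane beyond the skull
    x, y, z = coords
    face = (
        (np.abs(x - cx) <= 8)
        & (y >= y0)
        & (y < min(y0 + 6, ny))
        & (z >= cz - 10)
        & (z <= cz + 2)
    )
    if (brain & skull).any() or (brain & face).any() or (skull & face).any():
        raise DeidError("fixture regions overlap; adjust the spec geometry")
    if not face.any():
        raise DeidError("face wedge fell outside the grid; adjust the spec")

    rng = np.random.default_rng(spec.seed)
    base = np.zeros(spec.dims, dtype=np.float64)
    base[brain] = spec.brain_intensity
    base[skull] = spec.skull_intensity
    base[face] = spec.face_intensity
    data = np.rint(base + rng.normal(0.0, spec.noise_sd, size=spec.dims))
    data = np.clip(data, np.iinfo(np.int16).min, np.iinfo(np.int16).max).astype(np.int16)

    header = make_header(spec.dims, 4, kind)
    if patient_id is not None:
        target = "patient_id" if kind is FormatKind.ANALYZE75 else "descrip"
        header = edit_header_field(header, target, patient_id)
    volume = Volume.from_array(data, header)

    path: Path | None = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        suffix = ".nii" if kind is FormatKind.NIFTI_SINGLE else ".hdr"
        path = write_volume(volume, out_dir / f"{stem}{suffix}", kind)
    return HeadFixture(volume=volume, brain_mask=brain, face_mask=face, path=path)


_GIVEN = ("Alice", "Bruno", "Chloe", "Dmitri", "Elena", "Farid", "Grace", "Hiro",
          "Ines", "Jonas", "Karim", "Lena", "Mateo", "Nadia", "Omar", "Priya")
_FAMILY = ("Abbott", "Bergmann", "Castillo", "Dubois", "Eriksen", "Fontana",
           "Gupta", "Horvat", "Ivanova", "Jensen", "Kovacs", "Larsson",
           "Moreau", "Novak", "Okafor", "Petrov")


@dataclass(frozen=True)
class DemographicsFixture:
    table: DatasetTable
    missing_cells: tuple[CellRef, ...]


def make_demographics(
    n: int, seed: int = 0, missing_rate: float = 0.0
) -> DemographicsFixture:
    """Generate an n-row demographic table with planted identifiers.

    Columns: ID, NAME, DOB, TESTDATE, SEX, AGE, HEIGHT, WEIGHT, SCORE1,
    SCORE2.  One extreme AGE=96 row is planted when n >= 10 (the classic
    re-identifiable outlier).  Missing cells are planted uniformly at
    ``missing_rate`` over non-ID columns with their positions recorded.
    """
    if n < 1:
        raise DeidError("need at least one subject")
    rng = np.random.default_rng(seed)
    columns = ("ID", "NAME", "DOB", "TESTDATE", "SEX", "AGE", "HEIGHT",
               "WEIGHT", "SCORE1", "SCORE2")
    rows: list[tuple[object, ...]] = []
    for i in range(n):
        sid = f"S{i + 1:03d}"
        name = f"{_GIVEN[rng.integers(len(_GIVEN))]} {_FAMILY[rng.integers(len(_FAMILY))]}"
        dob = f"{rng.integers(1950, 2000)}-{rng.integers(1, 13):02d}-{rng.integers(1, 29):02d}"
        test = f"{rng.integers(2010, 2015)}-{rng.integers(1, 13):02d}-{rng.integers(1, 29):02d}"
        sex = "M" if rng.random() < 0.5 else "F"
        age = int(rng.integers(18, 81))
        height = float(np.round(rng.normal(170, 10), 1))
        weight = float(np.round(rng.normal(75, 12), 1))
        s1 = int(rng.integers(0, 101))
        s2 = float(np.round(rng.normal(50, 15), 2))
        rows.append((sid, name, dob, test, sex, age, height, weight, s1, s2))
    if n >= 10:
        r = list(rows[3])
        r[5] = 96  # planted extreme age
        rows[3] = tuple(r)

    missing: list[CellRef] = []
    if missing_rate > 0:
        for i in range(n):
            for j in range(1, len(columns)):
                if rng.random() < missing_rate:
                    row = list(rows[i])
                    row[j] = MISSING
                    rows[i] = tuple(row)
                    missing.append(CellRef(i, j))

    table = DatasetTable(column_names=columns, rows=tuple(rows))
    table.validate_ids()
    return DemographicsFixture(table=table, missing_cells=tuple(missing))
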