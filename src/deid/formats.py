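"""Binary reading/writing of Analyze 7.5 and NIfTI-1 image headers.

Both formats share a 348-byte fixed-layout header.  NIfTI-1 is identified
by a 4-byte magic at offset 344 ("n+1\\0" for single-file .nii, "ni1\\0"
for a .hdr/.img pair); Analyze 7.5 is identified by the absence of either
magic.  Each header field is decoded with its byte offset, storage type
and an *editable* flag: free-text history fields (description, patient
ID, scan number, experiment date, ...) may be edited or scrubbed, while
geometry/codec fields (dimensions, datatype, voxel sizes, transforms) are
protected because changing them would corrupt the image.

Encoding starts from the original raw bytes and patches only the fields
that were actually edited, so an untouched header re-encodes
byte-for-byte and every edit is local to its field's byte span.
"""

from __future__ import annotations

import logging
import os
import struct
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    MalformedFileError,
    MalformedHeaderError,
    OversizeValueError,
    ProtectedFieldError,
    UnknownFieldError,
    UnrecognizedFormatError,
    UnsupportedDatatypeError,
)

log = logging.getLogger(__name__)

HEADER_SIZE = 348

MAGIC_PAIR = b"ni1\x00"
MAGIC_SINGLE = b"n+1\x00"


class FormatKind(Enum):
    NIFTI_SINGLE = "nifti_single"
    NIFTI_PAIR = "nifti_pair"
    ANALYZE75 = "analyze75"


# Supported voxel datatype codes (shared by Analyze 7.5 and NIfTI-1).
DATATYPE_CODES = {
    2: ("uint8", 8),
    4: ("int16", 16),
    8: ("int32", 32),
    16: ("float32", 32),
}


# ---------------------------------------------------------------------------
# Field layouts
# ---------------------------------------------------------------------------

# (name, offset, struct code, count, editable); code "s" means char[count].
_NIFTI_LAYOUT: list[tuple[str, int, str, int, bool]] = [
    ("sizeof_hdr", 0, "i", 1, False),
    ("data_type", 4, "s", 10, False),
    ("db_name", 14, "s", 18, True),
    ("extents", 32, "i", 1, False),
    ("session_error", 36, "h", 1, False),
    ("regular", 38, "s", 1, False),
    ("dim_info", 39, "B", 1, False),
    ("dim", 40, "h", 8, False),
    ("intent_p1", 56, "f", 1, False),
    ("intent_p2", 60, "f", 1, False),
    ("intent_p3", 64, "f", 1, False),
    ("intent_code", 68, "h", 1, False),
    ("datatype", 70, "h", 1, False),
    ("bitpix", 72, "h", 1, False),
    ("slice_start", 74, "h", 1, False),
    ("pixdim", 76, "f", 8, False),
    ("vox_offset", 108, "f", 1, False),
    ("scl_slope", 112, "f", 1, False),
    ("scl_inter", 116, "f", 1, False),
    ("slice_end", 120, "h", 1, False),
    ("slice_code", 122, "B", 1, False),
    ("xyzt_units", 123, "B", 1, False),
    ("cal_max", 124, "f", 1, False),
    ("cal_min", 128, "f", 1, False),
    ("slice_duration", 132, "f", 1, False),
    ("toffset", 136, "f", 1, False),
    ("glmax", 140, "i", 1, False),
    ("glmin", 144, "i", 1, False),
    ("descrip", 148, "s", 80, True),
    ("aux_file", 228, "s", 24, True),
    ("qform_code", 252, "h", 1, False),
    ("sform_code", 254, "h", 1, False),
    ("quatern_b", 256, "f", 1, False),
    ("quatern_c", 260, "f", 1, False),
    ("quatern_d", 264, "f", 1, False),
    ("qoffset_x", 268, "f", 1, False),
    ("qoffset_y", 272, "f", 1, False),
    ("qoffset_z", 276, "f", 1, False),
    ("srow_x", 280, "f", 4, False),
    ("srow_y", 296, "f", 4, False),
    ("srow_z", 312, "f", 4, False),
    ("intent_name", 328, "s", 16, False),
    ("magic", 344, "s", 4, False),
]

_ANALYZE_LAYOUT: list[tuple[str, int, str, int, bool]] = [
    ("sizeof_hdr", 0, "i", 1, False),
    ("data_type", 4, "s", 10, False),
    ("db_name", 14, "s", 18, True),
    ("extents", 32, "i", 1, False),
    ("session_error", 36, "h", 1, False),
    ("regular", 38, "s", 1, False),
    ("hkey_un0", 39, "s", 1, False),
    ("dim", 40, "h", 8, False),
    ("unused8", 56, "h", 1, False),
    ("unused9", 58, "h", 1, False),
    ("unused10", 60, "h", 1, False),
    ("unused11", 62, "h", 1, False),
    ("unused12", 64, "h", 1, False),
    ("unused13", 66, "h", 1, False),
    ("unused14", 68, "h", 1, False),
    ("datatype", 70, "h", 1, False),
    ("bitpix", 72, "h", 1, False),
    ("dim_un0", 74, "h", 1, False),
    ("pixdim", 76, "f", 8, False),
    ("vox_offset", 108, "f", 1, False),
    ("funused1", 112, "f", 1, False),
    ("funused2", 116, "f", 1, False),
    ("funused3", 120, "f", 1, False),
    ("cal_max", 124, "f", 1, False),
    ("cal_min", 128, "f", 1, False),
    ("compressed", 132, "f", 1, False),
    ("verified", 136, "f", 1, False),
    ("glmax", 140, "i", 1, False),
    ("glmin", 144, "i", 1, False),
    ("descrip", 148, "s", 80, True),
    ("aux_file", 228, "s", 24, True),
    ("orient", 252, "B", 1, False),
    ("originator", 253, "s", 10, True),
    ("generated", 263, "s", 10, True),
    ("scannum", 273, "s", 10, True),
    ("patient_id", 283, "s", 10, True),
    ("exp_date", 293, "s", 10, True),
    ("exp_time", 303, "s", 10, True),
    ("hist_un0", 313, "s", 3, False),
    ("views", 316, "i", 1, False),
    ("vols_added", 320, "i", 1, False),
    ("start_field", 324, "i", 1, False),
    ("field_skip", 328, "i", 1, False),
    ("omax", 332, "i", 1, False),
    ("omin", 336, "i", 1, False),
    ("smax", 340, "i", 1, False),
    ("smin", 344, "i", 1, False),
]

_STORAGE_NAMES = {"b": "int8", "B": "uint8", "h": "int16", "i": "int32", "f": "float32"}
_STRUCT_SIZES = {"b": 1, "B": 1, "h": 2, "i": 4, "f": 4}


def _layout_for(kind: FormatKind) -> list[tuple[str, int, str, int, bool]]:
    if kind is FormatKind.ANALYZE75:
        return _ANALYZE_LAYOUT
    return _NIFTI_LAYOUT


# ---------------------------------------------------------------------------
# Header records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeaderField:
    """One decoded header field with its position in the 348-byte block."""

    name: str
    offset: int
    storage: str  # "int8" | "int16" | "int32" | "float32" | "char[n]"
    value: object  # str for char fields, int/float scalar, or tuple for arrays
    editable: bool
    size: int  # byte width of the field's span

    @property
    def span(self) -> tuple[int, int]:
        return self.offset, self.offset + self.size


@dataclass(frozen=True)
class HeaderRecord:
    """A decoded header plus its original raw bytes.

    ``dirty`` lists the field names whose values no longer match ``raw``;
    :func:`encode_header` patches exactly those byte spans.
    """

    format: FormatKind
    endianness: str  # "little" | "big"
    fields: tuple[HeaderField, ...]
    raw: bytes
    dirty: frozenset[str] = field(default_factory=frozenset)

    def field_map(self) -> dict[str, HeaderField]:
        return {f.name: f for f in self.fields}

    def __getitem__(self, name: str) -> object:
        for f in self.fields:
            if f.name == name:
                return f.value
        raise UnknownFieldError(f"no header field named {name!r}")

    def get_field(self, name: str) -> HeaderField:
        for f in self.fields:
            if f.name == name:
                return f
        raise UnknownFieldError(f"no header field named {name!r}")

    @property
    def editable_fields(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fields if f.editable)

    @property
    def dims(self) -> tuple[int, ...]:
        d = self["dim"]
        ndim = max(int(d[0]), 1)
        return tuple(int(x) for x in d[1 : 1 + max(ndim, 3)])


def _byte_order(endianness: str) -> str:
    return "<" if endianness == "little" else ">"


def _decode_field(raw: bytes, spec: tuple[str, int, str, int, bool], bo: str) -> HeaderField:
    name, offset, code, count, editable = spec
    if code == "s":
        chunk = raw[offset : offset + count]
        value = chunk.split(b"\x00", 1)[0].decode("latin-1")
        storage = f"char[{count}]"
        size = count
    else:
        size = _STRUCT_SIZES[code] * count
        vals = struct.unpack_from(f"{bo}{count}{code}", raw, offset)
        value = vals[0] if count == 1 else tuple(vals)
        storage = _STORAGE_NAMES[code]
    return HeaderField(name, offset, storage, value, editable, size)


def _encode_field(spec: tuple[str, int, str, int, bool], value: object, bo: str) -> bytes:
    name, _offset, code, count, _editable = spec
    if code == "s":
        data = str(value).encode("latin-1")
        if len(data) > count:
            raise OversizeValueError(
                f"value for {name!r} is {len(data)} bytes; field holds {count}"
            )
        return data.ljust(count, b"\x00")
    vals = value if isinstance(value, (tuple, list)) else (value,)
    if len(vals) != count:
        raise OversizeValueError(f"{name!r} expects {count} values, got {len(vals)}")
    return struct.pack(f"{bo}{count}{code}", *vals)


# ---------------------------------------------------------------------------
# Detection and decode/encode
# ---------------------------------------------------------------------------

def detect_format(header_bytes: bytes) -> FormatKind:
    """Classify a header blob by the 4 magic bytes at offset 344.

    "ni1\\0" -> NIfTI hdr/img pair, "n+1\\0" -> single-file .nii, and the
    absence of either magic -> Analyze 7.5 (provided sizeof_hdr decodes to
    348 under one byte order).
    """
    if len(header_bytes) < HEADER_SIZE:
        raise MalformedHeaderError(
            f"need at least {HEADER_SIZE} header bytes, got {len(header_bytes)}"
        )
    magic = header_bytes[344:348]
    if magic == MAGIC_PAIR:
        return FormatKind.NIFTI_PAIR
    if magic == MAGIC_SINGLE:
        return FormatKind.NIFTI_SINGLE
    if _detect_endianness(header_bytes) is None:
        raise UnrecognizedFormatError(
            "sizeof_hdr != 348 under both byte orders; not Analyze 7.5 or NIfTI-1"
        )
    return FormatKind.ANALYZE75


def _detect_endianness(header_bytes: bytes) -> str | None:
    (le,) = struct.unpack_from("<i", header_bytes, 0)
    if le == HEADER_SIZE:
        return "little"
    (be,) = struct.unpack_from(">i", header_bytes, 0)
    if be == HEADER_SIZE:
        return "big"
    return None


def decode_header(header_bytes: bytes) -> HeaderRecord:
    """Decode 348 header bytes into a :class:`HeaderRecord`."""
    kind = detect_format(header_bytes)
    endianness = _detect_endianness(header_bytes)
    if endianness is None:
        raise UnrecognizedFormatError("sizeof_hdr != 348 under both byte orders")
    bo = _byte_order(endianness)
    raw = bytes(header_bytes[:HEADER_SIZE])
    fields = tuple(_decode_field(raw, spec, bo) for spec in _layout_for(kind))
    return HeaderRecord(format=kind, endianness=endianness, fields=fields, raw=raw)


def encode_header(header: HeaderRecord) -> bytes:
    """Re-encode a header: original bytes with dirty field spans patched."""
    out = bytearray(header.raw)
    bo = _byte_order(header.endianness)
    specs = {s[0]: s for s in _layout_for(header.format)}
    for f in header.fields:
        if f.name in header.dirty:
            out[f.offset : f.offset + f.size] = _encode_field(specs[f.name], f.value, bo)
    return bytes(out)


def read_header(path: str | os.PathLike) -> HeaderRecord:
    """Read and decode the header of a .hdr or .nii file."""
    p = Path(path)
    if p.suffix.lower() == ".img":
        raise MalformedHeaderError(
            f"{p} is a voxel file; pass its .hdr sibling instead"
        )
    with open(p, "rb") as fh:
        blob = fh.read(HEADER_SIZE)
    if len(blob) < HEADER_SIZE:
        raise MalformedHeaderError(f"{p}: file shorter than {HEADER_SIZE} bytes")
    return decode_header(blob)


def edit_header_field(header: HeaderRecord, name: str, value: object) -> HeaderRecord:
    """Return a new record with one editable field changed.

    Protected fields (geometry, datatype, transforms) raise
    :class:`ProtectedFieldError`; oversize strings are rejected rather
    than truncated so the audit trail is never silently corrupted.
    """
    target = header.get_field(name)
    if not target.editable:
        raise ProtectedFieldError(f"field {name!r} cannot be edited")
    specs = {s[0]: s for s in _layout_for(header.format)}
    # Validate encoding (length, type) before committing the edit.
    bo = _byte_order(header.endianness)
    _encode_field(specs[name], value, bo)
    new_fields = tuple(
        replace(f, value=value) if f.name == name else f for f in header.fields
    )
    return replace(header, fields=new_fields, dirty=header.dirty | {name})


def scrub_header(header: HeaderRecord, policy: Iterable[str] | None = None) -> HeaderRecord:
    """Zero-fill identifying free-text fields.

    ``policy`` defaults to every editable field of the format (for Analyze
    that includes patient ID, scan number and experiment date/time).  The
    policy may only narrow the editable roster; naming a protected field
    is an error.
    """
    names = tuple(policy) if policy is not None else header.editable_fields
    out = header
    for name in names:
        f = out.get_field(name)
        if not f.editable:
            raise ProtectedFieldError(f"refusing to scrub protected field {name!r}")
        if f.value != "":
            out = edit_header_field(out, name, "")
    return out


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A 3-D image: header plus lazily-loaded voxel array.

    The voxel array is read from disk on first access to :attr:`data`
    (T1-weighted volumes are large; header audits must not pay for them).
    """

    header: HeaderRecord
    _loader: object = None  # zero-arg callable -> np.ndarray
    _data: np.ndarray | None = None

    @property
    def dims(self) -> tuple[int, ...]:
        return self.header.dims[:3]

    @property
    def datatype(self) -> int:
        return int(self.header["datatype"])

    @property
    def bitpix(self) -> int:
        return int(self.header["bitpix"])

    @property
    def loaded(self) -> bool:
        return self._data is not None

    @property
    def data(self) -> np.ndarray:
        if self._data is None:
            if self._loader is None:
                raise MalformedFileError("volume has neither data nor a loader")
            self._data = self._loader()
        return self._data

    @classmethod
    def from_array(cls, data: np.ndarray, header: HeaderRecord) -> "Volume":
        return cls(header=header, _data=np.asarray(data))


def _np_dtype(datatype: int, endianness: str) -> np.dtype:
    if datatype not in DATATYPE_CODES:
        raise UnsupportedDatatypeError(f"datatype code {datatype} not supported")
    name, _bits = DATATYPE_CODES[datatype]
    return np.dtype(name).newbyteorder("<" if endianness == "little" else ">")


def _data_paths(path: Path, kind: FormatKind) -> tuple[Path, int]:
    """Locate the voxel byte stream and its start offset for a header path."""
    hdr = read_header(path)
    if kind is FormatKind.NIFTI_SINGLE:
        return path, int(round(float(hdr["vox_offset"])))
    img = path.with_suffix(".img")
    if not img.exists():
        raise MalformedFileError(f"missing voxel file {img}")
    return img, 0


def read_volume(path: str | os.PathLike) -> Volume:
    """Open an image in any supported format; voxels load lazily."""
    p = Path(path)
    header = read_header(p)
    dtype = _np_dtype(int(header["datatype"]), header.endianness)
    dims = header.dims[:3]
    n = int(np.prod(dims))
    src, offset = _data_paths(p, header.format)
    expected = offset + n * dtype.itemsize
    if src.stat().st_size < expected:
        raise MalformedFileError(
            f"{src}: {src.stat().st_size} bytes < expected {expected} "
            f"for dims {dims} at {dtype.itemsize * 8} bits/voxel"
        )

    def loader(src=src, offset=offset, dtype=dtype, n=n, dims=dims):
        flat = np.fromfile(src, dtype=dtype, count=n, offset=offset)
        return flat.reshape(dims, order="F")

    return Volume(header=header, _loader=loader)


def _reverse_dtype(data: np.ndarray) -> tuple[int, int]:
    for code, (name, bits) in DATATYPE_CODES.items():
        if np.dtype(name) == data.dtype.newbyteorder("="):
            return code, bits
    raise UnsupportedDatatypeError(f"array dtype {data.dtype} not supported")


def make_header(
    dims: Sequence[int],
    datatype: int,
    kind: FormatKind,
    *,
    pixdim: Sequence[float] = (1.0, 1.0, 1.0),
    endianness: str = "little",
) -> HeaderRecord:
    """Build a fresh minimal header for a new volume."""
    if datatype not in DATATYPE_CODES:
        raise UnsupportedDatatypeError(f"datatype code {datatype} not supported")
    bo = _byte_order(endianness)
    raw = bytearray(HEADER_SIZE)
    struct.pack_into(f"{bo}i", raw, 0, HEADER_SIZE)
    raw[38:39] = b"r"  # "regular": all volumes the same size
    ndim = len(dims)
    dim8 = [ndim, *[int(d) for d in dims]] + [1] * (7 - ndim)
    struct.pack_into(f"{bo}8h", raw, 40, *dim8)
    struct.pack_into(f"{bo}h", raw, 70, datatype)
    struct.pack_into(f"{bo}h", raw, 72, DATATYPE_CODES[datatype][1])
    pix8 = [1.0, *[float(x) for x in pixdim]] + [1.0] * (7 - len(pixdim))
    struct.pack_into(f"{bo}8f", raw, 76, *pix8[:8])
    if kind is FormatKind.NIFTI_SINGLE:
        struct.pack_into(f"{bo}f", raw, 108, 352.0)
        raw[344:348] = MAGIC_SINGLE
    elif kind is FormatKind.NIFTI_PAIR:
        raw[344:348] = MAGIC_PAIR
    return decode_header(bytes(raw))


def write_volume(
    volume: Volume, path: str | os.PathLike, kind: FormatKind | None = None
) -> Path:
    """Write a volume to disk as .nii (NIFTI_SINGLE) or .hdr/.img pair.

    Integer voxel data round-trips bit-exactly; the path's suffix must
    agree with the requested format.  Returns the header-bearing path.
    """
    p = Path(path)
    kind = kind or volume.header.format
    data = volume.data
    code, _bits = _reverse_dtype(data)
    hdr = volume.header
    if hdr.format is not kind or int(hdr["datatype"]) != code or hdr.dims[:3] != tuple(data.shape):
        hdr = _retarget_header(hdr, data.shape, code, kind)
    bo = "<" if hdr.endianness == "little" else ">"
    blob = encode_header(hdr)
    payload = np.ascontiguousarray(data.astype(data.dtype.newbyteorder(bo)), dtype=data.dtype.newbyteorder(bo))
    raw_bytes = payload.tobytes(order="F")
    if kind is FormatKind.NIFTI_SINGLE:
        if p.suffix.lower() != ".nii":
            raise MalformedFileError(f"single-file NIfTI must end in .nii: {p}")
        with open(p, "wb") as fh:
            fh.write(blob)
            fh.write(b"\x00" * 4)  # no extensions
            fh.write(raw_bytes)
        return p
    if p.suffix.lower() != ".hdr":
        raise MalformedFileError(f"hdr/img output must be named by its .hdr: {p}")
    with open(p, "wb") as fh:
        fh.write(blob)
    with open(p.with_suffix(".img"), "wb") as fh:
        fh.write(raw_bytes)
    return p


def _retarget_header(
    hdr: HeaderRecord, shape: Sequence[int], datatype: int, kind: FormatKind
) -> HeaderRecord:
    """Rebuild a header for a new format/shape, carrying over free text."""
    out = make_header(shape, datatype, kind, endianness=hdr.endianness)
    for name in ("descrip", "aux_file", "db_name"):
        try:
            out = edit_header_field(out, name, hdr[name])
        except UnknownFieldError:
            pass
    return out


# ---------------------------------------------------------------------------
# Conversion between .nii and .hdr/.img
# ---------------------------------------------------------------------------

def convert_nii_to_pair(path: str | os.PathLike, out_dir: str | os.PathLike) -> tuple[Path, Path]:
    """Split a single-file .nii into a .hdr/.img pair.

    The pair's magic becomes "ni1\\0", vox_offset 0, and the .img holds
    exactly the voxel bytes that began at the source's vox_offset.  Any
    NIfTI extension bytes are dropped (a common hiding place for
    identifiers) with a logged warning.
    """
    p = Path(path)
    hdr = read_header(p)
    if hdr.format is not FormatKind.NIFTI_SINGLE:
        raise MalformedFileError(f"{p} is not a single-file NIfTI")
    vox_offset = int(round(float(hdr["vox_offset"])))
    if vox_offset < 352:
        raise MalformedFileError(f"{p}: vox_offset {vox_offset} < 352")
    if vox_offset > 352:
        log.warning("%s: dropping %d bytes of NIfTI extension data", p, vox_offset - 352)
    dtype = _np_dtype(int(hdr["datatype"]), hdr.endianness)
    n = int(np.prod(hdr.dims[:3])) * int(np.prod(hdr.dims[3:]) or 1)
    nbytes = n * dtype.itemsize
    with open(p, "rb") as fh:
        fh.seek(vox_offset)
        voxels = fh.read(nbytes)
    if len(voxels) < nbytes:
        raise MalformedFileError(f"{p}: truncated voxel data")

    raw = bytearray(hdr.raw)
    bo = _byte_order(hdr.endianness)
    raw[344:348] = MAGIC_PAIR
    struct.pack_into(f"{bo}f", raw, 108, 0.0)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hdr_path = out_dir / (p.stem + ".hdr")
    img_path = out_dir / (p.stem + ".img")
    with open(hdr_path, "wb") as fh:
        fh.write(bytes(raw))
        fh.write(b"\x00" * 4)  # extension flag cleared
    with open(img_path, "wb") as fh:
        fh.write(voxels)
    return hdr_path, img_path


def convert_pair_to_nii(
    hdr_path: str | os.PathLike,
    img_path: str | os.PathLike | None = None,
    out_dir: str | os.PathLike | None = None,
) -> Path:
    """Merge a .hdr/.img pair (NIfTI pair or Analyze 7.5) into one .nii.

    Analyze inputs are promoted to NIfTI-1: geometry and free-text fields
    carry over; NIfTI-only transform fields get identity-compatible
    defaults (qform/sform codes 0).
    """
    hp = Path(hdr_path)
    ip = Path(img_path) if img_path is not None else hp.with_suffix(".img")
    out_dir = Path(out_dir) if out_dir is not None else hp.parent
    hdr = read_header(hp)
    if hdr.format is FormatKind.NIFTI_SINGLE:
        raise MalformedFileError(f"{hp} is already a single-file NIfTI")
    dtype = _np_dtype(int(hdr["datatype"]), hdr.endianness)
    n = int(np.prod(hdr.dims[:3])) * int(np.prod(hdr.dims[3:]) or 1)
    nbytes = n * dtype.itemsize
    if ip.stat().st_size != nbytes:
        raise MalformedFileError(
            f"{ip}: {ip.stat().st_size} bytes != dims x bitpix/8 = {nbytes}"
        )

    bo = _byte_order(hdr.endianness)
    if hdr.format is FormatKind.NIFTI_PAIR:
        raw = bytearray(hdr.raw)
    else:
        # Promote Analyze 7.5: start from a clean NIfTI header, copy over
        # the fields the two layouts share.
        base = make_header(
            hdr.dims[: max(int(hdr["dim"][0]), 3)],
            int(hdr["datatype"]),
            FormatKind.NIFTI_SINGLE,
            pixdim=tuple(float(x) for x in hdr["pixdim"][1:4]),
            endianness=hdr.endianness,
        )
        for name in ("db_name", "descrip", "aux_file"):
            base = edit_header_field(base, name, hdr[name])
        raw = bytearray(encode_header(base))
        struct.pack_into(f"{bo}i", raw, 140, int(hdr["glmax"]))
        struct.pack_into(f"{bo}i", raw, 144, int(hdr["glmin"]))
        struct.pack_into(f"{bo}f", raw, 124, float(hdr["cal_max"]))
        struct.pack_into(f"{bo}f", raw, 128, float(hdr["cal_min"]))
    raw[344:348] = MAGIC_SINGLE
    struct.pack_into(f"{bo}f", raw, 108, 352.0)

    out_dir.mkdir(parents=True, exist_ok=True)
    out = out_dir / (hp.stem + ".nii")
    with open(out, "wb") as fh:
        fh.write(bytes(raw[:HEADER_SIZE]))
        fh.write(b"\x00" * 4)
        fh.write(ip.read_bytes())
    return out
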