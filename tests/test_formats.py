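"""Binary header layer: detection, decode/encode identity, edit locality,
scrubbing, format conversion, and voxel round trips.

nibabel serves as the independent oracle for decoding and voxel layout;
the implementation under test never calls it.
"""

import struct

import numpy as np
import pytest

import deid.formats as F
from deid.errors import (
    MalformedFileError,
    MalformedHeaderError,
    OversizeValueError,
    ProtectedFieldError,
    UnknownFieldError,
    UnrecognizedFormatError,
)
from deid.formats import FormatKind
from deid.synthdata import FixtureSpec, make_head_volume


def _blank_header(magic: bytes, endian: str = "<") -> bytes:
    raw = bytearray(348)
    struct.pack_into(f"{endian}i", raw, 0, 348)
    raw[344:348] = magic
    return bytes(raw)


class TestDetectFormat:
    @pytest.mark.parametrize("endian", ["<", ">"])
    @pytest.mark.parametrize(
        "magic,expected",
        [
            (b"ni1\x00", FormatKind.NIFTI_PAIR),
            (b"n+1\x00", FormatKind.NIFTI_SINGLE),
            (b"\x00\x00\x00\x00", FormatKind.ANALYZE75),
        ],
    )
    def test_trichotomy(self, magic, expected, endian):
        assert F.detect_format(_blank_header(magic, endian)) is expected

    def test_short_input_is_malformed(self):
        with pytest.raises(MalformedHeaderError):
            F.detect_format(b"\x00" * 100)

    def test_bad_sizeof_hdr_is_unrecognized(self):
        raw = bytearray(348)
        struct.pack_into("<i", raw, 0, 999)
        with pytest.raises(UnrecognizedFormatError):
            F.detect_format(bytes(raw))

    def test_magic_wins_over_analyze(self):
        # Analyze's smin occupies the magic offset; an smin spelling "ni1\0"
        # is classified NIfTI by the last-four-bytes rule.
        assert F.detect_format(_blank_header(b"ni1\x00")) is FormatKind.NIFTI_PAIR


class TestReadHeader:
    def test_planted_patient_id_decodes(self, analyze_pair):
        hdr = F.read_header(analyze_pair)
        fld = hdr.get_field("patient_id")
        assert fld.value == "PT007"
        assert fld.editable
        assert fld.offset == 283 and fld.size == 10

    def test_dim_decodes_protected(self, nii_file):
        hdr = F.read_header(nii_file)
        fld = hdr.get_field("dim")
        assert fld.value == (3, 64, 64, 40, 1, 1, 1, 1)
        assert not fld.editable

    def test_byte_swapped_header_same_values(self):
        little = F.make_header((64, 64, 40), 4, FormatKind.NIFTI_SINGLE)
        big = F.make_header(
            (64, 64, 40), 4, FormatKind.NIFTI_SINGLE, endianness="big"
        )
        assert big.endianness == "big"
        assert big.raw != little.raw
        for lf, bf in zip(little.fields, big.fields):
            assert lf.name == bf.name and lf.value == bf.value

    def test_img_path_rejected(self, analyze_pair):
        with pytest.raises(MalformedHeaderError):
            F.read_header(analyze_pair.with_suffix(".img"))


class TestEditAndScrub:
    def test_edit_descrip_is_local(self, nii_file):
        hdr = F.read_header(nii_file)
        edited = F.edit_header_field(hdr, "descrip", "deidentified")
        assert edited["descrip"] == "deidentified"
        out = F.encode_header(edited)
        changed = {i for i in range(348) if out[i] != hdr.raw[i]}
        lo, hi = hdr.get_field("descrip").span
        assert changed and changed <= set(range(lo, hi))

    def test_identity_edit_reproduces_raw(self, nii_file):
        hdr = F.read_header(nii_file)
        same = F.edit_header_field(hdr, "descrip", hdr["descrip"])
        assert F.encode_header(same) == hdr.raw

    def test_protected_field_rejected(self, nii_file):
        hdr = F.read_header(nii_file)
        with pytest.raises(ProtectedFieldError):
            F.edit_header_field(hdr, "dim", (3, 1, 1, 1, 1, 1, 1, 1))

    def test_unknown_field_rejected(self, nii_file):
        with pytest.raises(UnknownFieldError):
            F.edit_header_field(F.read_header(nii_file), "no_such_field", "x")

    def test_oversize_string_rejected_not_truncated(self, analyze_pair):
        hdr = F.read_header(analyze_pair)
        with pytest.raises(OversizeValueError):
            F.edit_header_field(hdr, "patient_id", "X" * 11)

    def test_scrub_blanks_identifiers(self, analyze_pair):
        hdr = F.read_header(analyze_pair)
        scrubbed = F.scrub_header(hdr)
        blob = F.encode_header(scrubbed)
        for name in hdr.editable_fields:
            fld = hdr.get_field(name)
            assert blob[fld.offset : fld.offset + fld.size] == b"\x00" * fld.size
        # geometry untouched
        dim = hdr.get_field("dim")
        assert blob[dim.offset : dim.offset + dim.size] == hdr.raw[dim.offset : dim.offset + dim.size]

    def test_scrub_idempotent(self, analyze_pair):
        hdr = F.read_header(analyze_pair)
        once = F.encode_header(F.scrub_header(hdr))
        twice = F.encode_header(F.scrub_header(F.decode_header(once)))
        assert once == twice

    def test_scrub_round_trip_decodes_empty(self, analyze_pair):
        blob = F.encode_header(F.scrub_header(F.read_header(analyze_pair)))
        redecoded = F.decode_header(blob)
        assert all(redecoded[n] == "" for n in redecoded.editable_fields)

    def test_scrub_policy_refuses_protected(self, nii_file):
        with pytest.raises(ProtectedFieldError):
            F.scrub_header(F.read_header(nii_file), ["dim"])


class TestDecodeEncodeIdentity:
    @pytest.mark.parametrize("seed", range(25))
    def test_fuzzed_headers_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        raw = bytearray(rng.integers(0, 256, size=348, dtype=np.uint8).tobytes())
        struct.pack_into("<i", raw, 0, 348)
        raw[344:348] = [b"ni1\x00", b"n+1\x00", b"\x00" * 4][seed % 3]
        hdr = F.decode_header(bytes(raw))
        assert F.encode_header(hdr) == bytes(raw)


class TestConversion:
    def test_nii_to_pair_voxels_identical(self, nii_file, tmp_path):
        src = F.read_volume(nii_file)
        hdr_p, img_p = F.convert_nii_to_pair(nii_file, tmp_path / "pair")
        pair = F.read_volume(hdr_p)
        assert pair.header.format is FormatKind.NIFTI_PAIR
        assert pair.header["magic"] == "ni1"
        assert np.array_equal(pair.data, src.data)

    def test_pair_round_trip_preserves_protected_fields(self, nii_file, tmp_path):
        src_hdr = F.read_header(nii_file)
        hdr_p, _ = F.convert_nii_to_pair(nii_file, tmp_path / "pair")
        back = F.convert_pair_to_nii(hdr_p, out_dir=tmp_path / "back")
        back_hdr = F.read_header(back)
        assert np.array_equal(F.read_volume(back).data, F.read_volume(nii_file).data)
        for f in src_hdr.fields:
            if f.name in ("magic", "vox_offset"):
                continue  # set by the conversion itself
            assert back_hdr[f.name] == f.value, f.name

    def test_wrong_img_size_is_mismatch(self, analyze_pair, tmp_path):
        img = analyze_pair.with_suffix(".img")
        img.write_bytes(img.read_bytes()[:-10])
        with pytest.raises(MalformedFileError):
            F.convert_pair_to_nii(analyze_pair, out_dir=tmp_path / "o")

    def test_analyze_promoted_to_nifti(self, analyze_pair, tmp_path):
        src_hdr = F.read_header(analyze_pair)
        out = F.convert_pair_to_nii(analyze_pair, out_dir=tmp_path / "o")
        hdr = F.read_header(out)
        assert hdr.format is FormatKind.NIFTI_SINGLE
        assert hdr["dim"] == src_hdr["dim"]
        assert hdr["datatype"] == src_hdr["datatype"]
        assert np.array_equal(
            F.read_volume(out).data, F.read_volume(analyze_pair).data
        )

    def test_convert_requires_single_file_source(self, analyze_pair, tmp_path):
        with pytest.raises(MalformedFileError):
            F.convert_nii_to_pair(analyze_pair, tmp_path)


class TestVolumes:
    def test_voxel_count_matches_dims(self, nii_file):
        vol = F.read_volume(nii_file)
        assert vol.data.size == 64 * 64 * 40 == 163_840

    def test_lazy_loading(self, nii_file):
        vol = F.read_volume(nii_file)
        assert not vol.loaded
        _ = vol.data
        assert vol.loaded

    @pytest.mark.parametrize("dtype", [np.uint8, np.int16, np.int32, np.float32])
    def test_write_read_round_trip(self, tmp_path, dtype):
        rng = np.random.default_rng(0)
        if np.issubdtype(dtype, np.integer):
            info = np.iinfo(dtype)
            data = rng.integers(info.min, info.max, size=(8, 6, 4)).astype(dtype)
        else:
            data = rng.normal(size=(8, 6, 4)).astype(dtype)
        code = {np.uint8: 2, np.int16: 4, np.int32: 8, np.float32: 16}[dtype]
        hdr = F.make_header((8, 6, 4), code, FormatKind.NIFTI_SINGLE)
        path = F.write_volume(F.Volume.from_array(data, hdr), tmp_path / "v.nii")
        assert np.array_equal(F.read_volume(path).data, data)

    def test_unsupported_datatype_rejected(self, tmp_path):
        with pytest.raises(Exception):
            F.make_header((4, 4, 4), 64, FormatKind.NIFTI_SINGLE)  # float64 code

    def test_nibabel_agrees_on_voxels(self, nii_file):
        nib = pytest.importorskip("nibabel")
        ours = F.read_volume(nii_file).data
        theirs = np.asarray(nib.load(nii_file).dataobj)
        assert np.array_equal(ours, theirs)

    def test_nibabel_agrees_on_header_fields(self, nii_file):
        nib = pytest.importorskip("nibabel")
        hdr = F.read_header(nii_file)
        theirs = nib.load(nii_file).header
        assert tuple(int(x) for x in theirs["dim"]) == hdr["dim"]
        assert int(theirs["datatype"]) == hdr["datatype"]
        assert int(theirs["bitpix"]) == hdr["bitpix"]
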