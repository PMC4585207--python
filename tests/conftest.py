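import numpy as np
import pytest

from deid.formats import FormatKind
from deid.synthdata import FixtureSpec, make_demographics, make_head_volume
from deid.tabular import write_table


@pytest.fixture(scope="session")
def head_fixture():
    """Default synthetic head phantom (in-memory, deterministic)."""
    return make_head_volume(FixtureSpec(seed=7))


@pytest.fixture()
def nii_file(tmp_path):
    """A synthetic .nii on disk with a planted description identifier."""
    fx = make_head_volume(
        FixtureSpec(seed=7), FormatKind.NIFTI_SINGLE, tmp_path, stem="S01",
        patient_id="S01-visit1",
    )
    return fx.path


@pytest.fixture()
def analyze_pair(tmp_path):
    """A synthetic Analyze 7.5 .hdr/.img pair with a planted patient ID."""
    fx = make_head_volume(
        FixtureSpec(seed=7), FormatKind.ANALYZE75, tmp_path, stem="A01",
        patient_id="PT007",
    )
    return fx.path


@pytest.fixture()
def demo_table():
    return make_demographics(20, seed=3, missing_rate=0.05)


@pytest.fixture()
def demo_tsv(tmp_path, demo_table):
    return write_table(demo_table.table, tmp_path / "demo.tsv")


@pytest.fixture()
def subject_dataset(tmp_path):
    """5 subjects: table on disk + one .nii per subject named by its ID."""
    demo = make_demographics(5, seed=11)
    table_path = write_table(demo.table, tmp_path / "demo.tsv")
    img_dir = tmp_path / "imgs"
    for i, sid in enumerate(demo.table.ids):
        make_head_volume(
            FixtureSpec(seed=100 + i), FormatKind.NIFTI_SINGLE, img_dir,
            stem=sid, patient_id=sid,
        )
    return demo, table_path, img_dir
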