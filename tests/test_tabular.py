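"""Demographic table: typed loading, missing-value audit, identifier
detection, column dropping and quasi-identifier generalization."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import deid.tabular as T
from deid.errors import DuplicateIdError, TableError
from deid.tabular import (
    MISSING,
    CellRef,
    DatasetTable,
    FindingReason,
    GeneralizationKind,
    GeneralizationRule,
)


def make_table(columns, rows):
    return DatasetTable(column_names=tuple(columns), rows=tuple(map(tuple, rows)))


class TestLoadWrite:
    def test_typed_cells_and_missing(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("ID\tHEIGHT\tNOTE\nS01\t172.5\thello\nS02\t\tNA\nS03\t180\tok\n")
        t = T.load_table(p)
        assert t.rows[0] == ("S01", 172.5, "hello")
        assert t.rows[1][1] is MISSING and t.rows[1][2] is MISSING
        assert t.rows[2][1] == 180  # integer-valued stays int

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("ID\tX\nS01\t1\nS01\t2\n")
        with pytest.raises(DuplicateIdError):
            T.load_table(p)

    def test_ragged_row_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("ID\tX\nS01\t1\t9\n")
        with pytest.raises(TableError):
            T.load_table(p)

    def test_round_trip(self, tmp_path, demo_table):
        p = T.write_table(demo_table.table, tmp_path / "t.tsv")
        assert T.load_table(p) == demo_table.table

    def test_missing_written_as_code(self, tmp_path):
        t = make_table(["ID", "X"], [("S01", MISSING)])
        p = T.write_table(t, tmp_path / "t.tsv")
        assert p.read_text().splitlines()[1] == "S01\tNA"

    def test_header_only_file(self, tmp_path):
        t = make_table(["ID", "X"], [])
        p = T.write_table(t, tmp_path / "t.tsv")
        assert p.read_text() == "ID\tX\n"

    def test_csv_dialect_sniffed(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("ID,X\nS01,3\n")
        assert T.load_table(p).rows[0] == ("S01", 3)


class TestFindMissing:
    def test_fully_populated_is_empty(self):
        t = make_table(["ID", "X"], [("S01", 1), ("S02", 2)])
        assert T.find_missing(t) == []

    def test_planted_cell_found(self):
        t = make_table(["ID", "HEIGHT"], [("S01", 1), ("S02", 2), ("S03", MISSING)])
        assert T.find_missing(t) == [CellRef(2, 1)]

    def test_generator_planted_positions_recovered(self, demo_table):
        found = set(T.find_missing(demo_table.table))
        assert found == set(demo_table.missing_cells)
        assert len(found) > 0


class TestDetectIdentifiers:
    def test_name_patterns(self):
        t = make_table(
            ["ID", "NAME", "DOB", "SEX", "HEIGHT"],
            [("S01", "A B", "1990-01-02", "F", 170)],
        )
        findings = {f.column: f.reason for f in T.detect_identifier_columns(t)}
        assert findings == {
            "ID": FindingReason.ID_LABEL,
            "NAME": FindingReason.NAME_PATTERN,
            "DOB": FindingReason.NAME_PATTERN,
        }

    def test_date_values_flagged(self):
        rows = [(f"S{i}", f"2011-0{i + 1}-04", i) for i in range(5)]
        t = make_table(["ID", "VISIT", "SCORE"], rows)
        findings = {f.column: f.reason for f in T.detect_identifier_columns(t)}
        assert findings["VISIT"] is FindingReason.DATE_VALUES
        assert "SCORE" not in findings

    def test_numeric_columns_only_id_label(self):
        t = make_table(["SUBJ", "SEX", "SCORE"], [("S01", "F", 3), ("S02", "M", 4)])
        findings = T.detect_identifier_columns(t)
        assert [f.column for f in findings] == ["SUBJ"]

    def test_deterministic(self, demo_table):
        a = T.detect_identifier_columns(demo_table.table)
        b = T.detect_identifier_columns(demo_table.table)
        assert a == b


class TestDropColumns:
    def test_drop_two_of_five(self):
        t = make_table(
            ["ID", "NAME", "DOB", "SEX", "HEIGHT"],
            [("S01", "A", "d", "F", 170), ("S02", "B", "d", "M", 180)],
        )
        out = T.drop_columns(t, ["NAME", "DOB"])
        assert out.column_names == ("ID", "SEX", "HEIGHT")
        assert out.n_rows == 2
        # untouched cells identical, source table unchanged
        assert out.column("HEIGHT") == t.column("HEIGHT")
        assert t.column_names == ("ID", "NAME", "DOB", "SEX", "HEIGHT")

    def test_drop_nothing_is_identity(self, demo_table):
        assert T.drop_columns(demo_table.table, []) == demo_table.table

    def test_refuses_to_drop_id_column(self, demo_table):
        with pytest.raises(TableError):
            T.drop_columns(demo_table.table, ["ID"])


class TestGeneralize:
    def test_bin_round_height(self):
        t = make_table(["ID", "HEIGHT"], [("a", 172), ("b", 168), ("c", 181)])
        out = T.generalize_column(
            t, GeneralizationRule("HEIGHT", GeneralizationKind.BIN_ROUND, 5)
        )
        assert out.column("HEIGHT") == (170, 170, 180)

    def test_bin_width_one_is_identity_on_integers(self):
        t = make_table(["ID", "X"], [("a", 7), ("b", -3)])
        out = T.generalize_column(
            t, GeneralizationRule("X", GeneralizationKind.BIN_ROUND, 1)
        )
        assert out.column("X") == (7, -3)

    def test_range_band_extreme_age(self):
        t = make_table(["ID", "AGE"], [("a", 96)])
        out = T.generalize_column(
            t, GeneralizationRule("AGE", GeneralizationKind.RANGE_BAND, 10)
        )
        assert out.column("AGE") == ("[90, 100)",)

    def test_sig_figs(self):
        t = make_table(["ID", "X"], [("a", 1234.5), ("b", 0.04567)])
        out = T.generalize_column(
            t, GeneralizationRule("X", GeneralizationKind.SIG_FIGS, 2)
        )
        assert out.column("X") == (1200, pytest.approx(0.046))

    def test_missing_passes_through(self):
        t = make_table(["ID", "X"], [("a", MISSING)])
        out = T.generalize_column(
            t, GeneralizationRule("X", GeneralizationKind.BIN_ROUND, 5)
        )
        assert out.rows[0][1] is MISSING

    def test_non_numeric_cell_names_location(self):
        t = make_table(["ID", "X"], [("a", "tall")])
        with pytest.raises(TableError, match="X"):
            T.generalize_column(
                t, GeneralizationRule("X", GeneralizationKind.BIN_ROUND, 5)
            )

    def test_non_positive_parameter_rejected(self):
        with pytest.raises(TableError):
            GeneralizationRule("X", GeneralizationKind.BIN_ROUND, 0)

    @settings(deadline=None, max_examples=200)
    @given(
        x=st.floats(-1e6, 1e6, allow_nan=False),
        w=st.floats(0.5, 100, allow_nan=False),
    )
    def test_bin_round_error_bound_and_idempotence(self, x, w):
        t = make_table(["ID", "X"], [("a", x)])
        rule = GeneralizationRule("X", GeneralizationKind.BIN_ROUND, w)
        once = T.generalize_column(t, rule)
        v = once.rows[0][1]
        assert abs(v - x) <= w / 2 + 1e-6 * max(1.0, abs(x))
        twice = T.generalize_column(once, rule)
        assert twice.rows[0][1] == pytest.approx(v, rel=1e-12)
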