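from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gdistinct import FilterReport, filter_records, read_records, write_records
from gdistinct.records import RECORD_COLUMNS, SchemaError, ValidationError


def make_records(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS)).astype("string")


CLEAN_ROWS = [
    ("P1", "1965-07-21", "F", "ProvA", "CityA1", "DistA1a"),
    ("P2", "1980-12-31", "M", "ProvA", "CityA1", "DistA1b"),
    ("P3", "2001-02-03", "F", "ProvB", "CityB1", "DistB1a"),
]


class TestReadRecords:
    def test_well_formed_file_preserves_row_order(self, tmp_path):
        path = tmp_path / "r.csv"
        write_records(make_records(CLEAN_ROWS), path)
        df = read_records(path)
        assert list(df["record_id"]) == ["P1", "P2", "P3"]
        assert list(df["dob"]) == ["1965-07-21", "1980-12-31", "2001-02-03"]

    def test_non_iso_date_dialect_becomes_missing_with_warning(self, tmp_path, caplog):
        path = tmp_path / "r.csv"
        path.write_text(
            "record_id,dob,gender,province,city,district\n"
            "P1,31/12/1980,M,ProvA,CityA1,DistA1a\n"
        )
        with caplog.at_level(logging.WARNING, logger="gdistinct.records"):
            df = read_records(path)
        assert len(df) == 1  # record retained
        assert df["dob"].isna().all()
        assert any("ISO-8601" in r.message for r in caplog.records)

    def test_duplicate_record_id_names_the_offender(self, tmp_path):
        path = tmp_path / "r.csv"
        rows = [CLEAN_ROWS[0], ("P1", "1990-01-01", "M", "ProvA", "CityA1", "DistA1a")]
        write_records(make_records(rows), path)
        with pytest.raises(ValidationError, match="P1"):
            read_records(path)

    def test_missing_mapped_column_is_a_schema_error(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text("id,dob,gender,province,city,district\n")
        with pytest.raises(SchemaError, match="patient_no"):
            read_records(path, columns={"record_id": "patient_no"})

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(OSError):
            read_records(tmp_path / "nope.csv")

    def test_future_dob_relative_to_reference_date_becomes_missing(self, tmp_path):
        path = tmp_path / "r.csv"
        rows = [("P1", "2030-01-01", "F", "ProvA", "CityA1", "DistA1a")]
        write_records(make_records(rows), path)
        df = read_records(path, reference_date="2020-06-30")
        assert df["dob"].isna().all()

    def test_unknown_gender_value_becomes_missing(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "record_id,dob,gender,province,city,district\n"
            "P1,1980-01-02,X,ProvA,CityA1,DistA1a\n"
        )
        df = read_records(path)
        assert df["gender"].isna().all()


class TestRoundTrip:
    def test_empty_table_writes_header_only(self, tmp_path):
        path = tmp_path / "r.csv"
        write_records(make_records([]), path)
        assert path.read_text().strip() == ",".join(RECORD_COLUMNS)
        assert len(read_records(path)) == 0

    def test_write_then_read_is_identity_including_missingness(self, tmp_path):
        rows = [
            ("P1", "1965-07-21", "F", "ProvA", "CityA1", "DistA1a"),
            ("P2", pd.NA, pd.NA, "ProvA", pd.NA, "DistA1b"),
            ("P3", "2001-02-03", "M", pd.NA, pd.NA, pd.NA),
        ]
        original = make_records(rows)
        path = tmp_path / "r.csv"
        write_records(original, path)
        reread = read_records(path)
        pd.testing.assert_frame_equal(reread, original)

    def test_writing_same_records_twice_is_byte_identical(self, tmp_path):
        from gdistinct import PopulationConfig, generate_population

        records = generate_population(PopulationConfig(n_patients=10_000, seed=3)).records
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_records(records, p1)
        write_records(records, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_tab_delimiter_round_trips(self, tmp_path):
        path = tmp_path / "r.tsv"
        original = make_records(CLEAN_ROWS)
        write_records(original, path, delimiter="\t")
        pd.testing.assert_frame_equal(read_records(path, delimiter="\t"), original)


class TestFilterRecords:
    def test_attributes_each_exclusion_to_exactly_one_rule(self):
        rows = [
            ("P1", "1965-07-21", "F", "ProvA", "CityA1", "DistA1a"),
            ("P2", "1980-12-31", "M", pd.NA, "CityA1", "DistA1b"),  # missing address
            ("P3", "1900-01-01", "F", "ProvB", "CityB1", "DistB1a"),  # sentinel DOB
            ("P4", "1999-09-09", "M", "ProvB", "CityB1", "DistB1b"),
            ("P5", "1955-05-05", "F", "ProvB", "CityB2", "DistB2a"),
        ]
        retained, report = filter_records(make_records(rows))
        assert report == FilterReport(5, 1, 1, 3)
        assert list(retained["record_id"]) == ["P1", "P4", "P5"]

    def test_record_failing_both_rules_counted_under_missing_address(self):
        rows = [("P1", "1900-01-01", "F", pd.NA, pd.NA, pd.NA)]
        _, report = filter_records(make_records(rows))
        assert (report.n_missing_address, report.n_sentinel_dob) == (1, 0)

    def test_clean_input_passes_through_untouched(self):
        retained, report = filter_records(make_records(CLEAN_ROWS))
        assert report == FilterReport(3, 0, 0, 3)
        assert len(retained) == 3

    def test_empty_input_yields_empty_output_and_zero_counts(self):
        retained, report = filter_records(make_records([]))
        assert len(retained) == 0
        assert report == FilterReport(0, 0, 0, 0)

    def test_missing_gender_or_dob_is_not_an_exclusion(self):
        rows = [("P1", pd.NA, pd.NA, "ProvA", "CityA1", "DistA1a")]
        retained, report = filter_records(make_records(rows))
        assert len(retained) == 1 and report.n_retained == 1

    def test_empty_sentinel_set_rejected(self):
        with pytest.raises(ValueError):
            filter_records(make_records(CLEAN_ROWS), sentinel_dobs=set())

    def test_retained_count_matches_row_by_row_recount(self):
        from gdistinct import PopulationConfig, generate_population

        bundle = generate_population(
            PopulationConfig(
                n_patients=1_000, missing_address_rate=0.1, sentinel_dob_rate=0.05, seed=42
            )
        )
        retained, report = filter_records(bundle.records)
        expected = 0
        for _, row in bundle.records.iterrows():
            addr_ok = all(pd.notna(row[c]) for c in ("province", "city", "district"))
            expected += int(addr_ok and row["dob"] != "1900-01-01")
        assert report.n_retained == len(retained) == expected
        assert report.n_input == 1_000

    def test_filtering_is_idempotent(self):
        from gdistinct import PopulationConfig, generate_population

        bundle = generate_population(
            PopulationConfig(
                n_patients=500, missing_address_rate=0.2, sentinel_dob_rate=0.1, seed=9
            )
        )
        once, _ = filter_records(bundle.records)
        twice, report2 = filter_records(once)
        assert report2.n_retained == report2.n_input == len(once)
        pd.testing.assert_frame_equal(twice, once)


@given(
    flags=st.lists(
        st.tuples(st.booleans(), st.booleans()), min_size=0, max_size=60
    )
)
def test_filter_report_counts_always_sum_to_input(flags):
    """Every input row is accounted for under exactly one outcome."""
    rows = []
    for i, (miss, sent) in enumerate(flags):
        rows.append(
            (
                f"P{i}",
                "1900-01-01" if sent else "1970-06-15",
                "F",
                pd.NA if miss else "ProvA",
                "CityA1",
                "DistA1a",
            )
        )
    _, report = filter_records(make_records(rows))
    assert (
        report.n_missing_address + report.n_sentinel_dob + report.n_retained == report.n_input
    )
    assert report.n_input == len(flags)


def test_filter_report_rejects_irreconcilable_counts():
    with pytest.raises(ValidationError):
        FilterReport(n_input=5, n_missing_address=1, n_sentinel_dob=1, n_retained=4)
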