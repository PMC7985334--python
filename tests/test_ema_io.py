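"""Parsing, grid regularization, wear accounting and stress categories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tvcpar.ema_io import (
    CODE_ABSENT,
    CODE_ACTIVITY,
    CODE_INSUFFICIENT,
    CODE_MISSING,
    CODE_OBSERVED,
    categorize_stress,
    modeling_view,
    parse_stress_csv,
    regularize_grid,
    to_excel_serial,
    wear_report,
    write_stress_csv,
)

from conftest import make_series


def _write(tmp_path, rows, header="timestamp,stress"):
    p = tmp_path / "export.csv"
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    return p


class TestParse:
    def test_missing_codes_map_to_slot_status(self, tmp_path):
        p = _write(
            tmp_path,
            [
                "2020-01-06T00:00:00Z,40",
                "2020-01-06T00:03:00Z,-1",
                "2020-01-06T00:06:00Z,-2",
            ],
        )
        s = parse_stress_csv(p)
        assert list(s.codes) == [CODE_OBSERVED, CODE_INSUFFICIENT, CODE_ACTIVITY]
        assert s.values[0] == 40 and np.isnan(s.values[1]) and np.isnan(s.values[2])

    def test_unix_epoch_zero_is_1970(self, tmp_path):
        p = _write(tmp_path, ["0,30", "180,31"])
        s = parse_stress_csv(p, timezone_policy="utc")
        assert s.epoch_start == pd.Timestamp("1970-01-01T00:00:00Z")

    def test_rows_sorted_by_time(self, tmp_path):
        p = _write(
            tmp_path,
            ["2020-01-06T00:03:00Z,50", "2020-01-06T00:00:00Z,40"],
        )
        s = parse_stress_csv(p)
        assert list(s.values) == [40, 50]

    def test_duplicate_timestamp_rejected(self, tmp_path):
        p = _write(
            tmp_path,
            ["2020-01-06T00:00:00Z,40", "2020-01-06T00:00:00Z,41"],
        )
        with pytest.raises(ValueError, match="duplicate"):
            parse_stress_csv(p)

    def test_out_of_range_stress_rejected(self, tmp_path):
        p = _write(tmp_path, ["2020-01-06T00:00:00Z,101"])
        with pytest.raises(ValueError, match="outside"):
            parse_stress_csv(p)

    def test_unparseable_timestamp_names_row(self, tmp_path):
        p = _write(tmp_path, ["2020-01-06T00:00:00Z,40", "not-a-time,41"])
        with pytest.raises(ValueError, match="row 1"):
            parse_stress_csv(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("timestamp,stress\n")
        with pytest.raises(ValueError, match="no data"):
            parse_stress_csv(p)

    def test_column_map_for_vendor_headers(self, tmp_path):
        p = _write(tmp_path, ["0,55"], header="Zeit,Stresslevel")
        s = parse_stress_csv(
            p, column_map={"timestamp": "Zeit", "stress": "Stresslevel"}
        )
        assert s.values[0] == 55

    def test_misaligned_timestamp_rejected(self, tmp_path):
        p = _write(tmp_path, ["0,40", "200,41"])
        with pytest.raises(ValueError, match="not aligned"):
            parse_stress_csv(p)


class TestRegularize:
    def test_gap_becomes_absent_row(self, tmp_path):
        rows = [f"{180 * k},{30 + k}" for k in range(10) if k != 4]
        s = regularize_grid(parse_stress_csv(_write(tmp_path, rows)))
        assert len(s) == 10
        assert s.codes[4] == CODE_ABSENT and np.isnan(s.values[4])
        assert (s.codes != CODE_ABSENT).sum() == 9

    def test_idempotent_on_complete_grid(self):
        s = make_series([40, 41, 42, 43])
        assert regularize_grid(s) == s
        assert regularize_grid(regularize_grid(s)) == regularize_grid(s)

    def test_14_days_of_3min_rows_gives_6720_slots(self, tmp_path):
        n = 14 * 1440 // 3
        rows = [f"{180 * k},50" for k in range(n)]
        s = regularize_grid(parse_stress_csv(_write(tmp_path, rows)))
        assert len(s) == 6720

    def test_wear_counts_preserved_for_existing_slots(self, tmp_path):
        rows = ["0,40", "180,-1", "540,-2", "720,60"]
        raw = parse_stress_csv(_write(tmp_path, rows))
        reg = regularize_grid(raw)
        assert reg.codes[np.searchsorted(reg.slots, raw.slots)].tolist() == \
            raw.codes.tolist()


class TestWearReport:
    def test_two_thirds_worn_is_suitable(self):
        codes = np.array([CODE_OBSERVED] * 30 + [CODE_INSUFFICIENT] * 5
                         + [CODE_ACTIVITY] * 5 + [CODE_ABSENT] * 20, dtype=np.int8)
        values = np.where(codes == CODE_OBSERVED, 40.0, np.nan)
        r = wear_report(make_series(values, codes))
        assert r.n_slots == 60 and r.n_observed == 30
        assert r.wear_fraction == pytest.approx(40 / 60)
        assert r.suitable
        assert r.n_observed + r.n_insufficient + r.n_activity + r.n_absent == 60

    def test_exactly_half_is_not_suitable(self):
        codes = np.array([CODE_OBSERVED] * 30 + [CODE_ABSENT] * 30, dtype=np.int8)
        values = np.where(codes == CODE_OBSERVED, 40.0, np.nan)
        r = wear_report(make_series(values, codes))
        assert r.wear_fraction == 0.5 and not r.suitable

    def test_all_absent_is_zero_wear(self):
        r = wear_report(make_series([np.nan] * 10))
        assert r.wear_fraction == 0.0 and not r.suitable


class TestCategorize:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0, "rest"), (25, "rest"), (26, "low"), (50, "low"),
            (51, "medium"), (75, "medium"), (76, "high"), (100, "high"),
        ],
    )
    def test_band_edges(self, value, expected):
        assert categorize_stress(value) == expected

    @pytest.mark.parametrize("bad", [-1, 101, float("nan")])
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValueError):
            categorize_stress(bad)


class TestModelingView:
    def test_all_missing_categories_collapse(self):
        codes = np.array(
            [CODE_OBSERVED, CODE_INSUFFICIENT, CODE_ACTIVITY, CODE_ABSENT],
            dtype=np.int8,
        )
        values = np.array([40.0, np.nan, np.nan, np.nan])
        v = modeling_view(make_series(values, codes))
        assert list(v.codes) == [CODE_OBSERVED] + [CODE_MISSING] * 3

    def test_fully_observed_unchanged(self):
        s = make_series([40, 41, 42])
        assert modeling_view(s) == s

    def test_observed_count_bookkeeping(self):
        rng = np.random.default_rng(5)
        codes = np.zeros(6720, dtype=np.int8)
        codes[rng.choice(6720, size=700, replace=False)] = CODE_INSUFFICIENT
        values = np.where(codes == 0, 40.0, np.nan)
        v = modeling_view(make_series(values, codes))
        assert (v.codes == CODE_OBSERVED).sum() == 6020


def test_excel_serial_of_unix_epoch():
    assert to_excel_serial(pd.Timestamp("1970-01-01T00:00:00Z")) == 25569.0


@settings(max_examples=25, deadline=None)
@given(
    data=st.lists(
        st.one_of(st.integers(0, 100), st.sampled_from([-1, -2, None])),
        min_size=3,
        max_size=40,
    )
)
def test_write_parse_roundtrip(tmp_path_factory, data):
    """Writing a series and re-parsing (plus regularizing) recovers it."""
    if data[0] is None or data[-1] is None:
        data = [50] + data[1:-1] + [50]
    values, codes = [], []
    for d in data:
        if d is None:
            values.append(np.nan), codes.append(CODE_ABSENT)
        elif d == -1:
            values.append(np.nan), codes.append(CODE_INSUFFICIENT)
        elif d == -2:
            values.append(np.nan), codes.append(CODE_ACTIVITY)
        else:
            values.append(float(d)), codes.append(CODE_OBSERVED)
    s = make_series(values, np.array(codes, dtype=np.int8))
    p = tmp_path_factory.mktemp("rt") / "s.csv"
    write_stress_csv(s, p)
    back = regularize_grid(parse_stress_csv(p, patient_id="t"))
    assert back == s
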