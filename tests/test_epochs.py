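"""Epoch reading, reintegration, flagging and wear accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actitrend import (
    EpochSeries,
    detect_nonwear,
    flag_overnight,
    process_series,
    read_epoch_csv,
    reintegrate,
    wear_minutes,
)
from actitrend.errors import (
    FormatError,
    InvalidParameterError,
    InvalidTargetError,
    UnsupportedEpochError,
)

from _oracles import brute_force_nonwear
from conftest import make_series


# ---------------------------------------------------------------------------
# Reading


def write_csv(path, counts, start="2010-06-07 06:00:00", epoch=60, drop=None):
    ts = pd.date_range(start, periods=len(counts), freq=f"{epoch}s")
    df = pd.DataFrame({"timestamp": ts, "counts": counts})
    if drop is not None:
        df = df.drop(index=drop)
    df.to_csv(path, index=False)
    return path


class TestReadEpochCsv:
    def test_plain_csv(self, tmp_path):
        p = write_csv(tmp_path / "a.csv", [0, 150, 3000])
        s = read_epoch_csv(p)
        assert len(s) == 3
        assert s.epoch_length == 60
        assert list(s.counts) == [0, 150, 3000]
        assert s.wear_flag.all() and not s.excluded_flag.any()

    def test_15s_epochs_inferred(self, tmp_path):
        p = write_csv(tmp_path / "a.csv", range(8), epoch=15)
        s = read_epoch_csv(p)
        assert len(s) == 8 and s.epoch_length == 15

    def test_gap_default_error(self, tmp_path):
        p = write_csv(tmp_path / "a.csv", [1, 2, 3, 4, 5], drop=[2, 3])
        with pytest.raises(FormatError, match="gap"):
            read_epoch_csv(p)

    def test_gap_zero_fill(self, tmp_path):
        p = write_csv(tmp_path / "a.csv", [1, 2, 3, 4, 5], drop=[2, 3])
        s = read_epoch_csv(p, on_gap="zero_fill")
        assert list(s.counts) == [1, 2, 0, 0, 5]

    def test_missing_counts_column(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("timestamp,x\n2010-06-07 06:00:00,1\n")
        with pytest.raises(FormatError, match="counts"):
            read_epoch_csv(p)

    def test_non_monotone_timestamps(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text(
            "timestamp,counts\n2010-06-07 06:01:00,1\n2010-06-07 06:00:00,2\n"
        )
        with pytest.raises(FormatError, match="monotone"):
            read_epoch_csv(p)

    def test_unsupported_epoch_length(self, tmp_path):
        p = write_csv(tmp_path / "a.csv", [1, 2, 3], epoch=7)
        with pytest.raises(UnsupportedEpochError):
            read_epoch_csv(p)

    def test_actigraph_header_block(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text(
            "--- Data File Created By ActiGraph ---\n"
            "Serial Number: X123\n"
            "Start Time 06:00:00\n"
            "Start Date 6/7/2010\n"
            "Epoch Period (hh:mm:ss) 00:00:15\n"
            "---------------------------------\n"
            "10\n20\n30\n40\n"
        )
        s = read_epoch_csv(p)
        assert s.epoch_length == 15
        assert list(s.counts) == [10, 20, 30, 40]
        assert s.start_time == pd.Timestamp("2010-06-07 06:00:00")


# ---------------------------------------------------------------------------
# Reintegration


class TestReintegrate:
    @pytest.mark.parametrize(
        "epoch,counts,expected",
        [
            (15, [10, 20, 30, 40], [100]),
            (60, [5, 10], [5, 10]),
            (30, [5, 5, 5, 5, 5], [10, 10]),  # trailing partial window dropped
        ],
    )
    def test_windowing(self, epoch, counts, expected):
        out = reintegrate(make_series(counts, epoch_length=epoch))
        assert out.epoch_length == 60
        assert list(out.counts) == expected

    def test_invalid_target(self):
        with pytest.raises(InvalidTargetError):
            reintegrate(make_series([1, 2], epoch_length=60), target=30)

    @given(st.lists(st.integers(0, 5000), min_size=0, max_size=50))
    @settings(deadline=None)
    def test_conservation_over_retained_windows(self, counts):
        s = make_series(counts, epoch_length=15)
        out = reintegrate(s)
        retained = (len(counts) // 4) * 4
        assert out.counts.sum() == np.sum(np.asarray(counts)[:retained])


# ---------------------------------------------------------------------------
# Overnight exclusion


class TestFlagOvernight:
    @pytest.mark.parametrize(
        "start,excluded",
        [
            ("2010-06-07 23:00:00", True),
            ("2010-06-07 22:59:00", False),
            ("2010-06-08 05:59:00", True),
            ("2010-06-08 06:00:00", False),
            ("2010-06-07 12:00:00", False),
        ],
    )
    def test_half_open_boundary(self, start, excluded):
        out = flag_overnight(make_series([100], start=start))
        assert bool(out.excluded_flag[0]) is excluded

    def test_requires_60s_epochs(self):
        with pytest.raises(UnsupportedEpochError):
            flag_overnight(make_series([1, 2], epoch_length=30))


# ---------------------------------------------------------------------------
# Non-wear detection


class TestDetectNonwear:
    def test_60min_zeros_is_one_bout(self):
        s = make_series([500] * 5 + [0] * 60 + [500] * 5)
        bouts = detect_nonwear(s)
        assert [(b.start_index, b.end_index) for b in bouts] == [(5, 65)]
        assert not s.wear_flag[5:65].any()
        assert s.wear_flag[:5].all() and s.wear_flag[65:].all()

    def test_59min_zeros_is_no_bout(self):
        s = make_series([500] * 5 + [0] * 59 + [500] * 5)
        assert detect_nonwear(s) == []
        assert s.wear_flag.all()

    def test_two_minute_interruption_merges(self):
        s = make_series([500] * 3 + [0] * 30 + [150, 150] + [0] * 30 + [500] * 3)
        bouts = detect_nonwear(s)
        assert [(b.start_index, b.end_index) for b in bouts] == [(3, 65)]
        assert bouts[0].interruption_minutes == 2
        assert not s.wear_flag[3:65].any()  # interruption epochs included

    def test_three_minute_interruption_breaks(self):
        s = make_series([500] * 3 + [0] * 30 + [150] * 3 + [0] * 30 + [500] * 3)
        assert detect_nonwear(s) == []

    def test_per_bout_mode_caps_total_interruption(self):
        counts = [0] * 30 + [150, 150] + [0] * 30 + [150, 150] + [0] * 30
        per_interruption = detect_nonwear(make_series(counts))
        assert [(b.start_index, b.end_index) for b in per_interruption] == [(0, 94)]
        s = make_series(counts)
        per_bout = detect_nonwear(s, interruption_mode="per_bout")
        # total interruption capped at 2 min: no 60-min zero-bounded window
        # with <=2 interrupted minutes exists, so only the 62-min halves
        spans = [(b.start_index, b.end_index) for b in per_bout]
        assert spans == [(0, 62), (32, 94)]

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            detect_nonwear(make_series([0] * 10), min_bout=3, tolerance=2)

    def test_idempotent(self):
        s = make_series([500] * 3 + [0] * 70 + [500] * 3)
        detect_nonwear(s)
        flags = s.wear_flag.copy()
        detect_nonwear(s)
        assert np.array_equal(s.wear_flag, flags)

    def test_adding_interior_zeros_preserves_bout(self):
        base = [500] * 5 + [0] * 30 + [150, 150] + [0] * 30 + [500] * 5
        with_more = [500] * 5 + [0] * 40 + [150, 150] + [0] * 30 + [500] * 5
        b1 = detect_nonwear(make_series(base))
        b2 = detect_nonwear(make_series(with_more))
        assert len(b1) == 1 and len(b2) == 1
        assert b2[0].span >= b1[0].span

    @given(
        st.lists(
            st.sampled_from([0, 0, 0, 0, 0, 0, 1, 40, 500, 3000]),
            min_size=0,
            max_size=300,
        )
    )
    @settings(deadline=None, max_examples=200)
    def test_matches_brute_force_oracle(self, counts):
        s = make_series(counts)
        bouts = detect_nonwear(s)
        assert [(b.start_index, b.end_index) for b in bouts] == brute_force_nonwear(
            counts
        )

    @given(
        st.lists(st.sampled_from([0, 0, 0, 1, 200]), min_size=0, max_size=120),
        st.integers(5, 30),
        st.integers(0, 3),
    )
    @settings(deadline=None, max_examples=150)
    def test_matches_oracle_at_other_parameters(self, counts, min_bout, tol):
        if min_bout < tol + 2:
            return
        s = make_series(counts)
        bouts = detect_nonwear(s, min_bout=min_bout, tolerance=tol)
        assert [
            (b.start_index, b.end_index) for b in bouts
        ] == brute_force_nonwear(counts, min_bout, tol)


# ---------------------------------------------------------------------------
# Wear accounting


class TestWearMinutes:
    def test_full_day_worn(self):
        s = make_series([200] * 1440, start="2010-06-07 00:00:00")
        out = flag_overnight(s)
        assert wear_minutes(out).iloc[0] == 1020  # 06:00-23:00

    def test_fully_nonworn_day(self):
        s = make_series([0] * 1440, start="2010-06-07 00:00:00")
        detect_nonwear(s)
        out = flag_overnight(s)
        assert wear_minutes(out).iloc[0] == 0

    def test_nonwear_bout_subtracts(self):
        counts = [200] * 1440
        counts[8 * 60 : 10 * 60] = [0] * 120  # 08:00-10:00 non-wear
        s = make_series(counts, start="2010-06-07 00:00:00")
        detect_nonwear(s)
        out = flag_overnight(s)
        assert wear_minutes(out).iloc[0] == 900

    @given(
        st.lists(
            st.sampled_from([0, 0, 0, 0, 1, 500]), min_size=1440, max_size=1440
        )
    )
    @settings(deadline=None, max_examples=25)
    def test_wear_nonwear_excluded_partition_the_day(self, counts):
        s = make_series(counts, start="2010-06-07 00:00:00")
        detect_nonwear(s)
        out = flag_overnight(s)
        worn = (out.wear_flag & ~out.excluded_flag).sum()
        nonwear = (~out.wear_flag & ~out.excluded_flag).sum()
        excluded = out.excluded_flag.sum()
        assert worn + nonwear + excluded == 1440


def test_process_series_pipeline_end_to_end():
    counts = [3] * 4 * 1440  # 15-s epochs for one full day
    s = make_series(counts, start="2010-06-07 00:00:00", epoch_length=15)
    out = process_series(s)
    assert out.epoch_length == 60
    assert len(out) == 1440
    assert (out.counts == 12).all()
    assert wear_minutes(out).iloc[0] == 1020
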