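"""Nonwear detection, day scoring, imputation, and valid-day selection."""

import numpy as np
import pandas as pd
import pytest

from circare.exceptions import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidInputError,
)
from circare.preprocess import (
    detect_nonwear,
    impute,
    preprocess,
    score_days,
    select_valid,
)
from circare.synthetic import SyntheticSpec, generate_subject

from conftest import MIDNIGHT, make_series


def _active_days(n_days=3, level=50.0):
    """Flat positive record of whole days starting at midnight."""
    return np.full(n_days * 1440, level)


class TestDetectNonwear:
    @pytest.mark.parametrize(
        "start_minute, n_zero, expect_nonwear",
        [
            (10 * 60, 20, True),    # 20 min of zeros at 10:00 -> off-wrist
            (10 * 60, 10, False),   # 10 min: below the daytime threshold
            (1 * 60, 170, False),   # 2 h 50 min at night: below the 3-h rule
            (1 * 60, 180, True),    # exactly 3 h at night -> off-wrist
            (22 * 60 + 30, 60, False),  # 1-h run straddling 23:00: night rule
        ],
    )
    def test_zero_run_rules(self, start_minute, n_zero, expect_nonwear):
        counts = _active_days(2)
        counts[start_minute : start_minute + n_zero] = 0.0
        mask = detect_nonwear(make_series(counts))
        flagged = ~mask.wear[start_minute : start_minute + n_zero]
        assert flagged.all() == expect_nonwear
        assert mask.wear[: start_minute].all()

    def test_diary_intervals_are_nonwear(self):
        counts = _active_days(2)
        series = make_series(counts)
        diary = [(MIDNIGHT + pd.Timedelta(hours=9), MIDNIGHT + pd.Timedelta(hours=10))]
        mask = detect_nonwear(series, diary=diary)
        assert not mask.wear[9 * 60 : 10 * 60].any()
        assert mask.wear[10 * 60 :].all()

    def test_diary_outside_span_rejected(self):
        series = make_series(_active_days(2))
        bad = [(MIDNIGHT - pd.Timedelta(hours=1), MIDNIGHT + pd.Timedelta(hours=1))]
        with pytest.raises(InvalidInputError):
            detect_nonwear(series, diary=bad)

    def test_negative_counts_rejected(self):
        # mutate after construction to hit the operation's own check
        series = make_series(_active_days(2))
        series.counts[5] = -1.0
        with pytest.raises(InvalidInputError):
            detect_nonwear(series)

    def test_device_gaps_are_not_wear(self):
        counts = _active_days(2)
        counts[100:130] = np.nan
        mask = detect_nonwear(make_series(counts))
        assert not mask.wear[100:130].any()


class TestScoreDays:
    def _scored(self, counts):
        series = make_series(counts)
        return series, score_days(series, detect_nonwear(series))

    def test_wear_and_gap_boundaries(self):
        counts = _active_days(4)
        # day 0: 21 h wear, one 1-h gap -> valid
        counts[1440 * 0 + 600 : 1440 * 0 + 660] = np.nan
        counts[1440 * 0 + 700 : 1440 * 0 + 820] = np.nan  # another 2 h
        # day 1: 3.5-h gap -> invalid despite 20.5 h wear
        counts[1440 * 1 + 600 : 1440 * 1 + 810] = np.nan
        # day 2: exactly 20 h wear, max gap exactly 3 h -> valid (inclusive)
        counts[1440 * 2 + 540 : 1440 * 2 + 720] = np.nan   # 3 h
        counts[1440 * 2 + 800 : 1440 * 2 + 860] = np.nan   # 1 h more -> 20 h wear
        _, days = self._scored(counts)
        assert [d.valid for d in days] == [True, False, True, True]
        assert days[2].wear_hours == pytest.approx(20.0)
        assert days[2].longest_missing_run == pytest.approx(3.0)
        assert days[1].longest_missing_run == pytest.approx(3.5)

    def test_partial_edge_days_excluded(self):
        counts = np.full(3 * 1440 + 200, 50.0)
        series = make_series(counts, start=MIDNIGHT - pd.Timedelta(minutes=100))
        days = score_days(series, detect_nonwear(series))
        assert len(days) == 3
        assert all(d.valid for d in days)


class TestImpute:
    def test_stage1_uses_same_clock_time_on_other_days(self):
        counts = _active_days(3)
        counts[0 * 1440 + 570] = 10.0
        counts[2 * 1440 + 570] = 20.0
        counts[1 * 1440 + 570] = np.nan  # 09:30 on day 2
        series = make_series(counts)
        mask = detect_nonwear(series)
        days = score_days(series, mask)
        out = impute(series, mask, days)
        assert out.counts[1 * 1440 + 570] == pytest.approx(15.0)

    def test_stage2_neighbour_mean(self):
        counts = _active_days(3)
        hole = 570
        for d in range(3):  # missing at the same clock time every day
            counts[d * 1440 + hole] = np.nan
        counts[1440 + hole - 3 : 1440 + hole] = [4.0, 6.0, 8.0]
        counts[1440 + hole + 1 : 1440 + hole + 4] = [10.0, 12.0, 14.0]
        series = make_series(counts)
        mask = detect_nonwear(series)
        out = impute(series, mask, score_days(series, mask))
        assert out.counts[1440 + hole] == pytest.approx(9.0)

    def test_no_missing_is_identity_and_observed_preserved(self):
        rng = np.random.default_rng(0)
        counts = rng.uniform(1, 100, 3 * 1440)
        series = make_series(counts)
        mask = detect_nonwear(series)
        out = impute(series, mask, score_days(series, mask))
        np.testing.assert_array_equal(out.counts, counts)

        counts2 = counts.copy()
        counts2[100:160] = np.nan
        series2 = make_series(counts2)
        mask2 = detect_nonwear(series2)
        out2 = impute(series2, mask2, score_days(series2, mask2))
        observed = ~np.isnan(counts2)
        np.testing.assert_array_equal(out2.counts[observed], counts2[observed])
        assert not np.isnan(out2.counts).any()

    def test_all_missing_record_is_degenerate(self):
        counts = np.zeros(3 * 1440)
        series = make_series(counts)
        mask = detect_nonwear(series)
        with pytest.raises(DegenerateInputError):
            impute(series, mask, score_days(series, mask))


class TestSelectValid:
    def test_all_days_retained(self):
        series = make_series(_active_days(7))
        mask = detect_nonwear(series)
        days = score_days(series, mask)
        out = select_valid(impute(series, mask, days), days)
        assert len(out) == 7 * 1440
        assert out.metadata["contiguous_days"]
        assert len(out) % out.epochs_per_day == 0

    def test_fewer_than_three_valid_days_rejected(self):
        counts = _active_days(3)
        counts[1440 * 1 + 100 : 1440 * 1 + 400] = np.nan  # 5-h gap kills day 2
        series = make_series(counts)
        mask = detect_nonwear(series)
        days = score_days(series, mask)
        filled = impute(series, mask, days)
        with pytest.raises(InsufficientDataError) as err:
            select_valid(filled, days)
        assert err.value.n_valid == 2

    def test_noncontiguous_days_flagged(self):
        counts = _active_days(5)
        for d in (1, 3):  # invalidate days 2 and 4 with 4-h gaps
            counts[1440 * d + 100 : 1440 * d + 340] = np.nan
        series = make_series(counts)
        mask = detect_nonwear(series)
        days = score_days(series, mask)
        out = select_valid(impute(series, mask, days), days)
        assert len(out) == 3 * 1440
        assert out.metadata["contiguous_days"] is False
        assert len(out.metadata["retained_dates"]) == 3


class TestPipeline:
    def test_planted_gap_fraction_recovered_exactly(self):
        spec = SyntheticSpec(
            n_days=3,
            noise_sd=20.0,  # keeps clipping (hence spurious zeros) away
            burst_rate=0.0,
            nonwear_gaps=[(60.0, 240.0), (10 * 60.0, 30.0)],  # night 4 h + day 30 min
            seed=3,
        )
        series, _ = generate_subject(spec)
        mask = detect_nonwear(series)
        planted = (240.0 + 30.0) / (3 * 1440)
        assert (~mask.wear).mean() == pytest.approx(planted)

    def test_pipeline_idempotent(self):
        spec = SyntheticSpec(
            n_days=4, noise_sd=20.0, nonwear_gaps=[(2 * 60.0, 200.0)], seed=5
        )
        series, _ = generate_subject(spec)
        once, _ = preprocess(series)
        twice, _ = preprocess(once)
        np.testing.assert_allclose(twice.counts, once.counts)
        assert len(twice) == len(once)
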