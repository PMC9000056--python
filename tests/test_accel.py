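from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from timeuse_coda.accel import (
    AccelConfig,
    CutPoints,
    DayRecord,
    PipelineError,
    SleepScorerConfig,
    classify_intensity,
    consolidate_sleep,
    detect_nonwear,
    process_cohort,
    process_subject,
    reintegrate,
    sleep_scores,
    summarize_subject,
)
from timeuse_coda.synthetic import StreamProfile, generate_count_stream

CUTS = CutPoints(sb_max=400, lpa_max=2000)
SYNTH_CFG = AccelConfig(
    cutpoints=CUTS, sleep_scorer=SleepScorerConfig.threshold_only(0)
)


def _series(counts, start="2018-03-05 11:59"):
    ts = pd.date_range(start, periods=len(counts), freq="min")
    return pd.DataFrame({"timestamp": ts, "counts": counts})


class TestReintegrate:
    def test_sums_finer_epochs(self):
        s = pd.DataFrame(
            {
                "timestamp": pd.date_range("2018-01-01", periods=4, freq="15s"),
                "counts": [10, 20, 30, 40],
            }
        )
        out = reintegrate(s, source_epoch_s=15, target_epoch_s=60)
        assert out["counts"].tolist() == [100]

    def test_identity_on_60s(self):
        s = _series([1, 2, 3])
        out = reintegrate(s, source_epoch_s=60)
        assert out["counts"].tolist() == [1, 2, 3]

    def test_conservation_random(self, rng):
        counts = rng.integers(0, 500, size=240)
        s = pd.DataFrame(
            {
                "timestamp": pd.date_range("2018-01-01", periods=240, freq="15s"),
                "counts": counts,
            }
        )
        out = reintegrate(s, source_epoch_s=15)
        assert out["counts"].sum() == counts.sum()

    def test_non_divisible_rejected(self):
        with pytest.raises(PipelineError):
            reintegrate(_series([1]), source_epoch_s=45, target_epoch_s=60)


class TestNonwear:
    def test_20_min_run_flagged_inclusive(self):
        c = np.ones(100, dtype=int)
        c[40:60] = 0
        assert detect_nonwear(c, min_run=20) == [(40, 60)]

    def test_19_min_run_not_flagged(self):
        c = np.ones(100, dtype=int)
        c[40:59] = 0
        assert detect_nonwear(c, min_run=20) == []

    def test_excluded_region_breaks_runs(self):
        c = np.zeros(60, dtype=int)
        excl = np.zeros(60, dtype=bool)
        excl[20:40] = True  # sleep period in the middle of a zero run
        runs = detect_nonwear(c, min_run=20, exclude=excl)
        assert runs == [(0, 20), (40, 60)]

    def test_monotone_in_min_run(self, rng):
        c = rng.integers(0, 2, size=2000) * rng.integers(0, 300, size=2000)
        total = {}
        for mr in (10, 20, 30):
            total[mr] = sum(b - a for a, b in detect_nonwear(c, min_run=mr))
        assert total[10] >= total[20] >= total[30]


class TestSleep:
    def test_all_zero_block_scores_as_sleep_with_default_constants(self):
        c = np.concatenate([np.full(120, 500), np.zeros(480), np.full(120, 500)])
        labels = sleep_scores(c, SleepScorerConfig()) > 0
        start, stop, minutes = consolidate_sleep(labels)
        assert 470 <= minutes <= 490

    def test_threshold_scorer_exact(self):
        c = np.concatenate([np.full(100, 300), np.zeros(480), np.full(100, 300)])
        labels = sleep_scores(c, SleepScorerConfig.threshold_only(0)) > 0
        start, stop, minutes = consolidate_sleep(labels)
        assert (start, stop, minutes) == (100, 580, 480)

    def test_bridging_merges_short_wake_gaps(self):
        labels = np.zeros(300, dtype=bool)
        labels[50:150] = True
        labels[160:260] = True  # 10-min gap <= bridge
        start, stop, minutes = consolidate_sleep(labels, bridge_max=20)
        assert (start, stop, minutes) == (50, 260, 200)

    def test_long_gap_not_bridged(self):
        labels = np.zeros(400, dtype=bool)
        labels[0:100] = True
        labels[200:330] = True
        start, stop, minutes = consolidate_sleep(labels, bridge_max=20)
        assert (start, stop, minutes) == (200, 330, 130)

    def test_short_night_invalid(self):
        p = StreamProfile(sleep_min=150, sb_min=1050, lpa_min=200, mvpa_min=40, days=2)
        s = generate_count_stream(p, seed=0)
        records = process_subject(s, SYNTH_CFG)
        assert all(not r.valid_sleep_night for r in records)
        assert all(r.night_sleep_min == 150 for r in records)


class TestClassify:
    def test_zero_counts_are_sb(self):
        assert classify_intensity(np.array([0]), CUTS).tolist() == [0]

    def test_cutpoint_boundaries_inclusive_below(self):
        out = classify_intensity(np.array([400, 401, 2000, 2001]), CUTS)
        assert out.tolist() == [0, 1, 1, 2]

    def test_missing_cutpoints_error(self):
        with pytest.raises(PipelineError, match="cut-points"):
            classify_intensity(np.array([1.0]), None)

    def test_nonincreasing_cutpoints_rejected(self):
        with pytest.raises(PipelineError):
            CutPoints(sb_max=100, lpa_max=100)


class TestRoundTrip:
    def test_planted_minutes_recovered(self):
        p = StreamProfile(sleep_min=480, sb_min=720, lpa_min=200, mvpa_min=40, days=5)
        s = generate_count_stream(p, seed=6)
        records = process_subject(s, SYNTH_CFG)
        for r in records:
            assert abs(r.night_sleep_min - 480) <= 2
            assert abs(r.sb_min - 720) <= 2
            assert abs(r.lpa_min - 200) <= 2
            assert abs(r.mvpa_min - 40) <= 2

    def test_planted_minutes_with_nonwear(self):
        p = StreamProfile(
            sleep_min=480, sb_min=670, lpa_min=200, mvpa_min=40,
            nonwear_bouts=tuple((d, 120, 50) for d in range(5)), days=5,
        )
        s = generate_count_stream(p, seed=8)
        records = process_subject(s, SYNTH_CFG)
        for r in records:
            assert r.nonwear_min == 50
            assert abs(r.sb_min - 670) <= 2
            assert abs(r.night_sleep_min - 480) <= 2

    def test_minute_conservation(self):
        p = StreamProfile(
            sleep_min=450, sb_min=700, lpa_min=200, mvpa_min=40,
            nonwear_bouts=((0, 100, 30), (2, 200, 25)), days=4,
        )
        s = generate_count_stream(p, seed=9)
        for r in process_subject(s, SYNTH_CFG):
            classified = r.sb_min + r.lpa_min + r.mvpa_min
            assert classified + r.sleep_min + r.nonwear_min == r.recorded_min


def _day(idx, date, night=480, wake=800, recorded=1440):
    weekend = date.weekday() in (4, 5)
    return DayRecord(
        date=date, day_index=idx, recorded_min=recorded, sleep_min=night,
        sb_min=wake - 240, lpa_min=200, mvpa_min=40,
        nonwear_min=recorded - night - wake, wake_wear_min=wake,
        night_sleep_min=night, is_first_day=idx == 0, is_weekend=weekend,
        valid_wake_day=wake >= 600, valid_sleep_night=night >= 160,
    )


class TestSummarize:
    def _week(self, nights):
        # Monday 2018-03-05 anchor; day i is Monday+i
        days = []
        for i in range(8):
            date = datetime(2018, 3, 5 + i, 11, 59)
            night = nights.get(i, 480)
            days.append(_day(i, date, night=night))
        return days

    def test_full_week_included(self):
        summary = summarize_subject(self._week({}), AccelConfig(cutpoints=CUTS))
        assert summary.included and summary.reasons == []

    def test_two_valid_nights_excluded(self):
        nights = {i: 100 for i in range(1, 8)}
        nights[2] = 480
        nights[5] = 480  # Saturday
        summary = summarize_subject(self._week(nights), AccelConfig(cutpoints=CUTS))
        assert not summary.included
        assert "lt3_valid_nights" in summary.reasons

    def test_weekday_only_nights_excluded(self):
        nights = {i: 100 for i in range(1, 8)}
        for i in (1, 2, 3):  # Tue-Thu only
            nights[i] = 480
        summary = summarize_subject(self._week(nights), AccelConfig(cutpoints=CUTS))
        assert not summary.included
        assert "no_weekend_night" in summary.reasons

    def test_first_day_dropped(self):
        days = self._week({})
        days[0] = _day(0, datetime(2018, 3, 5, 11, 59), night=1000)
        summary = summarize_subject(days, AccelConfig(cutpoints=CUTS))
        # the inflated first-day night must not contaminate the average
        assert summary.mean_sleep_min == pytest.approx(480.0)

    def test_identical_valid_days_average_to_daily_values(self):
        summary = summarize_subject(self._week({}), AccelConfig(cutpoints=CUTS))
        assert summary.mean_sleep_min == pytest.approx(480.0)
        assert summary.mean_mvpa_min == pytest.approx(40.0)

    def test_too_few_full_wear_days(self):
        days = self._week({})
        for i in range(4, 8):
            days[i] = _day(i, datetime(2018, 3, 5 + i, 11, 59), recorded=900, wake=420)
        summary = summarize_subject(days, AccelConfig(cutpoints=CUTS))
        assert "lt4_full_wear_days" in summary.reasons


class TestCohort:
    def test_process_cohort_tables_and_audit(self):
        good = generate_count_stream(StreamProfile(days=8), seed=1)
        short = generate_count_stream(StreamProfile(days=2), seed=2)
        days, subjects, audit = process_cohort(
            {"good": good, "short": short}, SYNTH_CFG
        )
        assert set(subjects["subject_id"]) == {"good", "short"}
        inc = subjects.set_index("subject_id")["included"]
        assert bool(inc["good"]) and not bool(inc["short"])
        assert any("short" in line and "excluded" in line for line in audit)
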