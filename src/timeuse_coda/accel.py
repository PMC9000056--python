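"""Reduction of per-epoch accelerometer counts to valid daily behavior minutes.

Stages, per subject: reintegration to 60-s epochs, per-minute sleep/wake
scoring (pluggable linear scorer), consolidation of the main nocturnal
sleep period, non-wear detection (zero runs of at least 20 minutes
outside the sleep period), intensity classification by configured
cut-points, daily validity rules, and subject-level summaries with
reason codes for exclusions.

Scientific thresholds (cut-points, sleep-scorer constants) are
configuration, not code: the classifier refuses to run without an
explicit :class:`CutPoints`, and the default sleep-scorer constants are
documented as sourced from the actigraphy literature.  Days are
delimited at the collection start clock time (11:59 a.m. by protocol),
so each night lies wholly inside one day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

import numpy as np
import pandas as pd

MIN_WAKE_WEAR = 600  # >= 10 h of wakefulness for a valid wake day
MIN_NIGHT_SLEEP = 160  # accumulated nightly sleep for a valid night
NONWEAR_MIN_RUN = 20  # zero-count minutes, boundary inclusive
WEEKEND_NIGHT_DAYS = (4, 5)  # a night belongs to the day starting Fri/Sat


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class CutPoints:
    """Counts/min thresholds: SB <= sb_max < LPA <= lpa_max < MVPA.

    Ties go to the lower intensity (a minute at exactly ``sb_max`` is
    sedentary).  No defaults: thresholds are population-specific and
    must be supplied explicitly.
    """

    sb_max: float
    lpa_max: float

    def __post_init__(self) -> None:
        if not self.sb_max < self.lpa_max:
            raise PipelineError("cut-points must be strictly increasing")


@dataclass(frozen=True)
class SleepScorerConfig:
    """Linear per-minute sleep score on 60-s count epochs.

    score = const - w_avg*AVG - w_nats*NATS - w_sd*SD - w_lg*LG, with
    AVG the mean counts in an 11-min window centered on the minute,
    NATS the number of window epochs with counts in [nats_lo, nats_hi),
    SD the standard deviation of the current and five preceding epochs,
    and LG the natural log of (current counts + 1).  score > 0 means
    sleep.  Default constants follow the Sadeh actigraphic algorithm as
    published for count-mode devices; they are configuration, and tests
    exercise the machinery with synthetic constants.
    """

    const: float = 7.601
    w_avg: float = 0.065
    w_nats: float = 1.08
    w_sd: float = 0.056
    w_lg: float = 0.703
    nats_lo: float = 50.0
    nats_hi: float = 100.0

    @classmethod
    def threshold_only(cls, max_sleep_counts: float = 0.0) -> "SleepScorerConfig":
        """Degenerate scorer: sleep iff counts <= max_sleep_counts.

        Sets the window weights to zero so classification is exactly
        local; used by synthetic round-trip tests.
        """
        cut = np.log(max_sleep_counts + 1.0)
        return cls(const=cut + 0.5, w_avg=0.0, w_nats=0.0, w_sd=0.0, w_lg=1.0)


@dataclass(frozen=True)
class AccelConfig:
    cutpoints: CutPoints | None = None
    sleep_scorer: SleepScorerConfig = field(default_factory=SleepScorerConfig)
    nonwear_min_run: int = NONWEAR_MIN_RUN
    sleep_bridge_max: int = 20  # wake gaps bridged inside the main sleep period
    min_wake_wear: int = MIN_WAKE_WEAR
    min_night_sleep: int = MIN_NIGHT_SLEEP
    drop_first_day: bool = True
    min_valid_nights: int = 3
    min_weekday_nights: int = 2
    min_weekend_nights: int = 1
    min_full_wear_days: int = 4


@dataclass
class DayRecord:
    date: datetime
    day_index: int
    recorded_min: int
    sleep_min: int
    sb_min: int
    lpa_min: int
    mvpa_min: int
    nonwear_min: int
    wake_wear_min: int
    night_sleep_min: int
    is_first_day: bool
    is_weekend: bool
    valid_wake_day: bool
    valid_sleep_night: bool


@dataclass
class SubjectSummary:
    subject_id: str
    included: bool
    reasons: list[str]
    n_valid_days: int
    n_valid_nights: int
    n_weekday_nights: int
    n_weekend_nights: int
    n_full_wear_days: int
    mean_sleep_min: float
    mean_sb_min: float
    mean_lpa_min: float
    mean_mvpa_min: float


def reintegrate(
    series: pd.DataFrame, source_epoch_s: int, target_epoch_s: int = 60
) -> pd.DataFrame:
    """Sum counts of finer epochs into ``target_epoch_s`` windows.

    Total counts are conserved.  ``series`` needs columns
    (timestamp, counts) at a constant ``source_epoch_s`` spacing.
    """
    if target_epoch_s % source_epoch_s != 0:
        raise PipelineError(
            f"target epoch {target_epoch_s}s not divisible by source "
            f"{source_epoch_s}s"
        )
    k = target_epoch_s // source_epoch_s
    if k == 1:
        return series.reset_index(drop=True)
    ts = pd.to_datetime(series["timestamp"]).to_numpy()
    counts = series["counts"].to_numpy()
    n = (len(counts) // k) * k
    agg = counts[:n].reshape(-1, k).sum(axis=1)
    return pd.DataFrame({"timestamp": ts[:n:k], "counts": agg})


def sleep_scores(counts: np.ndarray, cfg: SleepScorerConfig) -> np.ndarray:
    """Per-minute sleep score (see :class:`SleepScorerConfig`)."""
    c = np.asarray(counts, dtype=float)
    n = c.size
    s = pd.Series(c)
    avg = s.rolling(11, center=True, min_periods=1).mean().to_numpy()
    nats = (
        pd.Series(((c >= cfg.nats_lo) & (c < cfg.nats_hi)).astype(float))
        .rolling(11, center=True, min_periods=1)
        .sum()
        .to_numpy()
    )
    sd = s.rolling(6, min_periods=1).std(ddof=0).to_numpy()
    lg = np.log(c + 1.0)
    return (
        cfg.const - cfg.w_avg * avg - cfg.w_nats * nats - cfg.w_sd * sd - cfg.w_lg * lg
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as half-open (start, stop) index pairs."""
    out = []
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def consolidate_sleep(
    sleep_labels: np.ndarray, bridge_max: int = 20
) -> tuple[int, int, int]:
    """Main nocturnal sleep period from per-minute sleep labels.

    Sleep runs separated by wake gaps of at most ``bridge_max`` minutes
    are merged; the merged block containing the most sleep-labeled
    minutes wins.  Returns (start, stop, sleep_minutes_within); (0,0,0)
    if no sleep at all.
    """
    runs = _runs(np.asarray(sleep_labels, dtype=bool))
    if not runs:
        return (0, 0, 0)
    blocks: list[list[tuple[int, int]]] = [[runs[0]]]
    for run in runs[1:]:
        if run[0] - blocks[-1][-1][1] <= bridge_max:
            blocks[-1].append(run)
        else:
            blocks.append([run])
    best = max(blocks, key=lambda b: sum(stop - start for start, stop in b))
    start, stop = best[0][0], best[-1][1]
    minutes = sum(s2 - s1 for s1, s2 in best)
    return (start, stop, minutes)


def detect_nonwear(
    counts: np.ndarray,
    min_run: int = NONWEAR_MIN_RUN,
    exclude: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Maximal zero-count runs of length >= ``min_run`` (inclusive).

    Minutes where ``exclude`` is true (the scored sleep period) never
    count as non-wear and break runs.
    """
    c = np.asarray(counts)
    mask = c == 0
    if exclude is not None:
        mask = mask & ~np.asarray(exclude, dtype=bool)
    return [(a, b) for a, b in _runs(mask) if b - a >= min_run]


def classify_intensity(counts: np.ndarray, cutpoints: CutPoints | None) -> np.ndarray:
    """0=SB, 1=LPA, 2=MVPA per minute; upper bounds inclusive."""
    if cutpoints is None:
        raise PipelineError(
            "intensity cut-points are required configuration; refusing to "
            "classify without explicit thresholds"
        )
    c = np.asarray(counts, dtype=float)
    out = np.zeros(c.size, dtype=int)
    out[c > cutpoints.sb_max] = 1
    out[c > cutpoints.lpa_max] = 2
    return out


def process_subject(
    series: pd.DataFrame, config: AccelConfig, subject_id: str = "?"
) -> list[DayRecord]:
    """Split a 60-s epoch series into protocol days and score each.

    Conservation holds per day: sleep + SB + LPA + MVPA + non-wear
    equals recorded minutes.
    """
    ts = pd.to_datetime(series["timestamp"])
    counts = series["counts"].to_numpy()
    if len(counts) == 0:
        raise PipelineError(f"{subject_id}: empty series")
    if not ts.is_monotonic_increasing:
        raise PipelineError(f"{subject_id}: timestamps must be increasing")
    anchor = ts.iloc[0]
    day_idx = ((ts - anchor).dt.total_seconds() // 60 // 1440).astype(int).to_numpy()
    records: list[DayRecord] = []
    for d in np.unique(day_idx):
        sel = day_idx == d
        c = counts[sel]
        day_start = anchor + pd.Timedelta(minutes=int(d) * 1440)
        scores = sleep_scores(c, config.sleep_scorer)
        labels = scores > 0
        s_start, s_stop, night_sleep = consolidate_sleep(
            labels, bridge_max=config.sleep_bridge_max
        )
        in_sleep = np.zeros(c.size, dtype=bool)
        in_sleep[s_start:s_stop] = True
        sleep_min = int(labels[in_sleep].sum())
        nonwear_iv = detect_nonwear(
            c, min_run=config.nonwear_min_run, exclude=in_sleep
        )
        in_nonwear = np.zeros(c.size, dtype=bool)
        for a, b in nonwear_iv:
            in_nonwear[a:b] = True
        wake = ~in_sleep & ~in_nonwear
        # wake-labeled minutes inside the sleep period are rare
        # (bridged gaps); classify them with the rest of wake time
        wake_in_bed = in_sleep & ~labels
        classify_mask = wake | wake_in_bed
        intensities = classify_intensity(c[classify_mask], config.cutpoints)
        sb = int((intensities == 0).sum())
        lpa = int((intensities == 1).sum())
        mvpa = int((intensities == 2).sum())
        recorded = int(c.size)
        nonwear_min = int(in_nonwear.sum())
        wake_wear = recorded - sleep_min - nonwear_min
        weekday = day_start.weekday()
        records.append(
            DayRecord(
                date=day_start.to_pydatetime(),
                day_index=int(d),
                recorded_min=recorded,
                sleep_min=sleep_min,
                sb_min=sb,
                lpa_min=lpa,
                mvpa_min=mvpa,
                nonwear_min=nonwear_min,
                wake_wear_min=wake_wear,
                night_sleep_min=night_sleep,
                is_first_day=bool(d == 0),
                is_weekend=weekday in WEEKEND_NIGHT_DAYS,
                valid_wake_day=wake_wear >= config.min_wake_wear,
                valid_sleep_night=night_sleep >= config.min_night_sleep,
            )
        )
    return records


def summarize_subject(
    records: Sequence[DayRecord],
    config: AccelConfig | None = None,
    subject_id: str = "?",
) -> SubjectSummary:
    """Apply validity rules and average behaviors over valid days.

    The first (familiarization) day is dropped.  Inclusion requires at
    least ``min_valid_nights`` valid nights including
    ``min_weekend_nights`` weekend (Friday/Saturday) and
    ``min_weekday_nights`` weekday nights, plus
    ``min_full_wear_days`` days of complete 24-h recording.  Reason
    codes name every failed rule.
    """
    config = config or AccelConfig()
    days = [r for r in records if not (config.drop_first_day and r.is_first_day)]
    valid_days = [r for r in days if r.valid_wake_day and r.recorded_min == 1440]
    valid_nights = [r for r in days if r.valid_sleep_night]
    weekend = [r for r in valid_nights if r.is_weekend]
    weekday = [r for r in valid_nights if not r.is_weekend]
    full_wear = [r for r in days if r.recorded_min == 1440]
    reasons: list[str] = []
    if len(valid_nights) < config.min_valid_nights:
        reasons.append("lt3_valid_nights")
    if len(weekend) < config.min_weekend_nights:
        reasons.append("no_weekend_night")
    if len(weekday) < config.min_weekday_nights:
        reasons.append("lt2_weekday_nights")
    if len(full_wear) < config.min_full_wear_days:
        reasons.append("lt4_full_wear_days")

    def _mean(rs: Sequence[DayRecord], attr: str) -> float:
        return float(np.mean([getattr(r, attr) for r in rs])) if rs else float("nan")

    return SubjectSummary(
        subject_id=subject_id,
        included=not reasons,
        reasons=reasons,
        n_valid_days=len(valid_days),
        n_valid_nights=len(valid_nights),
        n_weekday_nights=len(weekday),
        n_weekend_nights=len(weekend),
        n_full_wear_days=len(full_wear),
        mean_sleep_min=_mean(valid_nights, "night_sleep_min"),
        mean_sb_min=_mean(valid_days, "sb_min"),
        mean_lpa_min=_mean(valid_days, "lpa_min"),
        mean_mvpa_min=_mean(valid_days, "mvpa_min"),
    )


def process_cohort(
    streams: dict[str, pd.DataFrame], config: AccelConfig
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Run the full chain over many subjects.

    Returns (per-day table, subject-level table, audit log lines).
    """
    day_rows, subj_rows, audit = [], [], []
    for sid, series in streams.items():
        records = process_subject(series, config, subject_id=sid)
        for r in records:
            row = {"id": sid, **r.__dict__}
            day_rows.append(row)
        summary = summarize_subject(records, config, subject_id=sid)
        subj_rows.append(summary.__dict__ | {"reasons": ";".join(summary.reasons)})
        if not summary.included:
            audit.append(f"{sid}: excluded ({', '.join(summary.reasons)})")
        dropped = [r for r in records if r.is_first_day and config.drop_first_day]
        for r in dropped:
            audit.append(f"{sid}: day {r.day_index} dropped (first_day)")
    return pd.DataFrame(day_rows), pd.DataFrame(subj_rows), audit
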