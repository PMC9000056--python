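"""Synthetic cohorts and accelerometer count streams with recorded truth.

The cohort generator draws four-part daily time-use compositions
logistic-normally (ilr coordinates are multivariate normal around the
ilr image of a configured center) and produces the outcome from a
planted linear model on the ilr coordinates plus age.  Every parameter
that downstream stages are expected to recover is kept in a truth
record, so the whole pipeline is testable without external data.

The count-stream generator lays out per-minute integer counts over
several simulated days (collection starting 11:59 a.m.) with sleep
blocks, non-wear runs of exact configured lengths, and wake counts
drawn inside configured cut-point bands, so that the filter chain can
be checked by round-trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from timeuse_coda.coda import IlrBasis, close, ilr, ilr_inverse, MINUTES_PER_DAY

#: Part order of the subject table (and of ``GeneratorConfig.center``).
SUBJECT_PARTS: tuple[str, ...] = ("sleep", "sb", "lpa", "mvpa")

#: Cohort center in % of day, order (sleep, SB, LPA, MVPA).
DEFAULT_CENTER: tuple[float, ...] = (34.31, 50.52, 12.82, 2.35)

# Pairwise log-ratio variance targets used to calibrate the default
# coordinate dispersion; chosen to span the 0.03-0.34 range of a real
# adolescent cohort so synthetic variability is realistic.
_VARIATION_TARGETS: dict[tuple[str, str], float] = {
    ("sleep", "sb"): 0.03,
    ("sleep", "lpa"): 0.11,
    ("sleep", "mvpa"): 0.33,
    ("sb", "lpa"): 0.11,
    ("sb", "mvpa"): 0.34,
    ("lpa", "mvpa"): 0.17,
}


def dispersion_from_variation(
    targets: dict[tuple[str, str], float] | None = None,
    parts: Sequence[str] = SUBJECT_PARTS,
) -> np.ndarray:
    """ilr covariance implied by a target variation matrix.

    Uses the identity ``S_clr = -0.5 * J T J`` (J the centering matrix)
    and projects onto the pivot basis over ``parts``.
    """
    targets = dict(targets or _VARIATION_TARGETS)
    parts = tuple(parts)
    D = len(parts)
    T = np.zeros((D, D))
    for (a, b), v in targets.items():
        i, j = parts.index(a), parts.index(b)
        T[i, j] = T[j, i] = v
    J = np.eye(D) - np.ones((D, D)) / D
    S_clr = -0.5 * J @ T @ J
    V = IlrBasis.pivot(parts).contrast
    return V @ S_clr @ V.T


class ConfigurationError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    ``beta_true`` applies to the design ``[1, ilr1, ilr2, ilr3, age]``
    where the ilr coordinates use the pivot basis over
    (sleep, sb, lpa, mvpa).  ``compliance_probs`` records expected
    per-sex guideline-attainment rates for labeling only; it does not
    distort the compositions.
    """

    n_subjects: int = 185
    center: tuple[float, ...] = DEFAULT_CENTER
    ilr_dispersion: np.ndarray | None = None
    beta_true: tuple[float, ...] = (0.0, 0.5, -0.3, 0.2, 0.28)
    sigma_eps: float = 0.9
    age_range: tuple[float, float] = (15.0, 18.0)
    sex_ratio: float = 0.508
    seed: int = 0
    compliance_probs: dict = field(
        default_factory=lambda: {
            "M": {"sleep": 0.234, "mvpa": 0.149, "st": 0.011},
            "F": {"sleep": 0.4285, "mvpa": 0.011, "st": 0.011},
        }
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be positive")
        c = np.asarray(self.center, dtype=float)
        if not (c > 0).all():
            raise ConfigurationError("center parts must be strictly positive")
        if abs(c.sum() - 100.0) > 1e-6:
            raise ConfigurationError("center must sum to 100 (% of day)")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError("sex_ratio must be in [0, 1]")
        if self.ilr_dispersion is None:
            self.ilr_dispersion = dispersion_from_variation()
        S = np.asarray(self.ilr_dispersion, dtype=float)
        if S.shape != (3, 3) or not np.allclose(S, S.T, atol=1e-10):
            raise ConfigurationError("ilr_dispersion must be symmetric 3x3")
        if np.linalg.eigvalsh(S).min() < -1e-10:
            raise ConfigurationError(
                "ilr_dispersion must be positive (semi-)definite"
            )
        self.ilr_dispersion = S
        if len(self.beta_true) != 5:
            raise ConfigurationError(
                "beta_true must have 5 entries: intercept, ilr1..3, age"
            )


@dataclass
class SyntheticCohort:
    """Subject table plus the ground truth used to generate it."""

    table: pd.DataFrame
    truth: dict

    def compositions(self) -> np.ndarray:
        cols = [f"{p}_min" for p in SUBJECT_PARTS]
        return self.table[cols].to_numpy()


def _dispersion_factor(S: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(S)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a synthetic cohort; deterministic given ``config.seed``.

    The global seed fans out to one independent substream per subject,
    so any subject subset is reproducible independently of cohort size.
    """
    basis = IlrBasis.pivot(SUBJECT_PARTS)
    mu = ilr(close(np.asarray(config.center), total=100.0), basis)
    L = _dispersion_factor(config.ilr_dispersion)
    beta = np.asarray(config.beta_true, dtype=float)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    rows = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sex = "M" if rng.random() < config.sex_ratio else "F"
        age = rng.uniform(*config.age_range)
        ses = float(np.clip(rng.normal(32.0, 8.4), 5.0, 70.0))
        screen = float(np.round(np.clip(rng.gamma(4.0, 1.7), 0.0, 18.0) * 2) / 2)
        z = mu + L @ rng.standard_normal(3)
        comp = ilr_inverse(z, basis, total=MINUTES_PER_DAY)
        zbmi = float(
            beta[0] + beta[1:4] @ z + beta[4] * age + rng.normal(0.0, config.sigma_eps)
        )
        rows.append(
            {
                "id": f"s{i + 1:04d}",
                "sex": sex,
                "age_years": age,
                "ses_score": round(ses, 1),
                "screen_hours": screen,
                "sleep_min": comp[0],
                "sb_min": comp[1],
                "lpa_min": comp[2],
                "mvpa_min": comp[3],
                "zbmi": zbmi,
            }
        )
    table = pd.DataFrame(rows)
    truth = {
        "beta_true": list(beta),
        "center": list(config.center),
        "seed": config.seed,
        "sigma_eps": config.sigma_eps,
        "basis_parts": list(SUBJECT_PARTS),
        "ilr_dispersion": np.asarray(config.ilr_dispersion).tolist(),
        "compliance_probs": config.compliance_probs,
    }
    return SyntheticCohort(table=table, truth=truth)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as CSV + XLSX and the truth record as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "csv": outdir / "cohort.csv",
        "xlsx": outdir / "cohort.xlsx",
        "truth": outdir / "truth.json",
    }
    cohort.table.to_csv(paths["csv"], index=False)
    cohort.table.to_excel(paths["xlsx"], index=False)
    paths["truth"].write_text(json.dumps(cohort.truth, indent=2))
    return paths


# ---------------------------------------------------------------------------
# epoch-level count streams


@dataclass
class StreamProfile:
    """Intended daily layout of a synthetic count stream.

    Minutes are per day; the four behaviors plus non-wear must not
    exceed 1440.  Any unallocated wake minutes are filled as sedentary.
    ``nonwear_bouts`` are (day_index, offset_min_from_day_start, length).
    Count bands must be consistent with the cut-points the downstream
    classifier will be configured with: sb_band at or below c1 (and
    strictly positive, so no spurious zero runs), lpa_band in (c1, c2],
    mvpa_band above c2.
    """

    days: int = 5
    sleep_min: int = 480
    sb_min: int = 720
    lpa_min: int = 200
    mvpa_min: int = 40
    nonwear_bouts: tuple[tuple[int, int, int], ...] = ()
    start: datetime = field(
        default_factory=lambda: datetime(2018, 3, 5, 11, 59)
    )
    sleep_onset_offset: int = 661  # minutes after 11:59 a.m. -> 23:00
    sb_band: tuple[int, int] = (200, 380)
    lpa_band: tuple[int, int] = (420, 1900)
    mvpa_band: tuple[int, int] = (2100, 5000)

    def __post_init__(self) -> None:
        per_day = self.sleep_min + self.sb_min + self.lpa_min + self.mvpa_min
        if per_day > 1440:
            raise ConfigurationError(
                f"intended behavior minutes sum to {per_day} > 1440"
            )
        if self.days < 1:
            raise ConfigurationError("need at least one day")
        if self.sb_band[0] < 1:
            raise ConfigurationError(
                "sb_band must be strictly positive (zeros are non-wear)"
            )


def generate_count_stream(profile: StreamProfile, seed: int = 0) -> pd.DataFrame:
    """Per-minute counts over ``profile.days`` days from 11:59 a.m.

    Returns a frame with columns (timestamp, counts).  Sleep and
    non-wear minutes are zero counts; wake minutes are drawn uniformly
    inside the configured bands, laid out as MVPA then LPA then SB
    within the wake time of each day.
    """
    rng = np.random.default_rng(seed)
    n = profile.days * 1440
    counts = np.zeros(n, dtype=int)
    nonwear_by_day: dict[int, list[tuple[int, int]]] = {}
    for day, off, length in profile.nonwear_bouts:
        nonwear_by_day.setdefault(day, []).append((off, length))
    for day in range(profile.days):
        base = day * 1440
        sleep_lo = profile.sleep_onset_offset
        sleep_hi = sleep_lo + profile.sleep_min
        if sleep_hi > 1440:
            raise ConfigurationError("sleep block must fit inside the day")
        occupied = np.zeros(1440, dtype=bool)
        occupied[sleep_lo:sleep_hi] = True
        nw_total = 0
        for off, length in nonwear_by_day.get(day, []):
            if off + length > 1440 or occupied[off : off + length].any():
                raise ConfigurationError(
                    f"non-wear bout at day {day} offset {off} overlaps sleep "
                    "or exceeds the day"
                )
            occupied[off : off + length] = True
            nw_total += length
        wake_idx = np.flatnonzero(~occupied)
        need = profile.mvpa_min + profile.lpa_min + profile.sb_min
        if need > wake_idx.size:
            raise ConfigurationError(
                f"day {day}: behaviors + non-wear exceed 1440 minutes"
            )
        m, l = profile.mvpa_min, profile.lpa_min
        mvpa_idx = wake_idx[:m]
        lpa_idx = wake_idx[m : m + l]
        sb_idx = wake_idx[m + l :]  # SB absorbs any slack
        counts[base + mvpa_idx] = rng.integers(
            profile.mvpa_band[0], profile.mvpa_band[1] + 1, size=mvpa_idx.size
        )
        counts[base + lpa_idx] = rng.integers(
            profile.lpa_band[0], profile.lpa_band[1] + 1, size=lpa_idx.size
        )
        counts[base + sb_idx] = rng.integers(
            profile.sb_band[0], profile.sb_band[1] + 1, size=sb_idx.size
        )
    ts = [profile.start + timedelta(minutes=i) for i in range(n)]
    return pd.DataFrame({"timestamp": ts, "counts": counts})


def write_count_stream(stream: pd.DataFrame, path: str | Path) -> Path:
    """Two-column CSV: ISO-8601 timestamp, counts per minute."""
    path = Path(path)
    out = stream.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out.to_csv(path, index=False)
    return path
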