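"""Guideline-compliance accounting and group comparisons.

Daily recommendations: 8-10 h of nightly sleep (inclusive bounds),
at least 60 min/day of MVPA, and under 2 h/day of self-reported screen
time.  Joint attainment is tabulated as the 8 cells of a three-set Venn
diagram, overall and by sex.  Group comparisons use a pooled
two-proportion z-test and a rank-sum test with the rank-biserial effect
size (bootstrap CI).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

SLEEP_LO_MIN = 480.0
SLEEP_HI_MIN = 600.0
MVPA_MIN = 60.0
SCREEN_MAX_H = 2.0

_GUIDELINES = ("sleep", "mvpa", "st")


def classify_compliance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject guideline booleans and the Venn-cell label.

    Expects columns ``mean_sleep_min``, ``mean_mvpa_min``,
    ``screen_hours`` (NaN screen time leaves ``st_ok`` missing and the
    subject out of screen-time denominators).  Keeps ``id`` and ``sex``
    if present.
    """
    out = pd.DataFrame(index=table.index)
    for col in ("id", "sex"):
        if col in table.columns:
            out[col] = table[col]
    sleep = table["mean_sleep_min"].astype(float)
    mvpa = table["mean_mvpa_min"].astype(float)
    screen = table["screen_hours"].astype(float)
    out["sleep_ok"] = (sleep >= SLEEP_LO_MIN) & (sleep <= SLEEP_HI_MIN)
    out["mvpa_ok"] = mvpa >= MVPA_MIN
    out["st_ok"] = pd.array(screen < SCREEN_MAX_H, dtype="boolean")
    out.loc[screen.isna(), "st_ok"] = pd.NA

    def _label(row) -> str:
        names = []
        if row["sleep_ok"]:
            names.append("sleep")
        if row["mvpa_ok"]:
            names.append("mvpa")
        if row["st_ok"] is True:
            names.append("st")
        return "+".join(names) if names else "none"

    out["label"] = out.apply(_label, axis=1)
    return out


def venn_counts(profiles: pd.DataFrame) -> dict:
    """8-cell joint-attainment counts, overall and by sex when available.

    Cells are keyed ``"sleep"``, ``"sleep+mvpa"``, ..., ``"none"``;
    they sum to the cohort size (missing screen time counts as
    non-compliant for cell assignment, mirroring a conservative read).
    """
    cells = ["none"] + [
        "+".join(c) for k in (1, 2, 3) for c in combinations(_GUIDELINES, k)
    ]

    def _table(df: pd.DataFrame) -> dict:
        counts = {c: 0 for c in cells}
        for lab in df["label"]:
            counts[lab] += 1
        counts["n"] = int(len(df))
        for g in _GUIDELINES:
            counts[f"{g}_total"] = int(
                sum(v for k, v in counts.items() if k in cells and g in k.split("+"))
            )
        return counts

    result = {"overall": _table(profiles)}
    if "sex" in profiles.columns:
        for sex, df in profiles.groupby("sex"):
            result[str(sex)] = _table(df)
    return result


@dataclass(frozen=True)
class ProportionTest:
    x1: int
    n1: int
    x2: int
    n2: int
    z: float
    p_value: float
    diff: float
    ci: tuple[float, float]
    degenerate: bool = False


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> ProportionTest:
    """Pooled two-proportion z-test, two-sided.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled
    proportion; the CI of the difference uses the unpooled SE.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 < 1 or n2 < 1:
        raise ValueError("need 0 <= x <= n and n >= 1 for both groups")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    diff = p1 - p2
    se_pooled = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    degenerate = se_pooled == 0.0
    z = float(diff / se_pooled) if not degenerate else float("nan")
    p = float(2 * stats.norm.sf(abs(z))) if not degenerate else float("nan")
    se_un = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    ci = (float(diff - 1.959963984540054 * se_un), float(diff + 1.959963984540054 * se_un))
    return ProportionTest(
        x1=x1, n1=n1, x2=x2, n2=n2, z=z, p_value=p, diff=float(diff), ci=ci,
        degenerate=bool(degenerate),
    )


_MAGNITUDES = ((0.1, "very small"), (0.3, "small"), (0.5, "moderate"))


def effect_magnitude(r: float) -> str:
    """|r| < 0.1 very small, <= 0.3 small, <= 0.5 moderate, else large."""
    a = abs(r)
    for bound, name in _MAGNITUDES:
        if a < bound or (a == bound and bound != 0.1):
            return name
    return "large"


@dataclass(frozen=True)
class RankTest:
    u: float
    w: float
    p_value: float
    r: float
    r_ci: tuple[float, float]
    magnitude: str
    method: str
    degenerate: bool = False


def _rank_biserial(a: np.ndarray, b: np.ndarray) -> float:
    n1, n2 = len(a), len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return float(2 * u / (n1 * n2) - 1)


def rank_compare(
    a: Sequence[float],
    b: Sequence[float],
    n_boot: int = 200,
    seed: int = 0,
    paired: bool = False,
) -> RankTest:
    """Rank test between two samples with rank-biserial effect size.

    Independent groups use the Mann-Whitney rank-sum (exact null
    distribution when both groups are small and tie-free, otherwise the
    normal approximation with midranks, tie correction, and continuity
    correction).  ``paired=True`` switches to the signed-rank variant.
    The rank-biserial r = 2U/(n1*n2) - 1 gets a percentile bootstrap CI
    (``n_boot`` replicates, fixed seed).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each group needs at least one observation")
    degenerate = len(np.unique(np.concatenate([a, b]))) == 1
    if degenerate:
        n1, n2 = len(a), len(b)
        u = n1 * n2 / 2
        return RankTest(
            u=u, w=u, p_value=1.0, r=0.0, r_ci=(0.0, 0.0),
            magnitude="very small", method="degenerate", degenerate=True,
        )
    if paired:
        res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True)
        u = w = float(res.statistic)
        r_val = float(1 - 2 * res.statistic / (len(a) * (len(a) + 1) / 2))
        method = "signed-rank"
    else:
        n1, n2 = len(a), len(b)
        pooled = np.concatenate([a, b])
        ties = len(np.unique(pooled)) < len(pooled)
        method_sel = "exact" if (max(n1, n2) <= 25 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method=method_sel, use_continuity=True
        )
        u = float(res.statistic)
        w = u  # reported W is the rank-sum U of the first group
        r_val = float(2 * u / (n1 * n2) - 1)
        method = f"rank-sum/{method_sel}"
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        if paired:
            idx = rng.integers(0, len(a), size=len(a))
            boots[i] = _rank_biserial(a[idx], b[idx])
        else:
            ra = rng.choice(a, size=len(a), replace=True)
            rb = rng.choice(b, size=len(b), replace=True)
            boots[i] = _rank_biserial(ra, rb)
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return RankTest(
        u=u,
        w=w,
        p_value=float(res.pvalue),
        r=r_val,
        r_ci=ci,
        magnitude=effect_magnitude(r_val),
        method=method,
        degenerate=False,
    )
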