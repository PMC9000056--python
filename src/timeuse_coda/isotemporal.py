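"""Isotemporal substitution: model-based zBMI change for time reallocations.

For a fixed duration t moved from one behavior to another (total time
held at 1440 min), the predicted outcome change is the ilr-coordinate
difference contracted with the compositional coefficients:
``delta = c' beta_ilr`` with ``c = ilr(reallocated) - ilr(baseline)``;
intercept and covariates cancel in the difference, so the estimate does
not depend on the covariate values held fixed.  Its variance is
``c' Sigma_ilr c`` and the CI uses the t distribution at the model's
residual degrees of freedom.

Estimates are not sign-symmetric in the pair: moving t minutes a->b and
b->a give deltas that generally do not sum to zero, a consequence of
the log-ratio geometry; :func:`asymmetry_report` tabulates this.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from timeuse_coda.coda import MINUTES_PER_DAY, close, geometric_center, ilr
from timeuse_coda.model import FittedModel
from timeuse_coda.synthetic import SUBJECT_PARTS

DEFAULT_DURATIONS: tuple[int, ...] = (15, 30, 45, 60, 75, 90, 120)

BaselineMode = Literal["center", "mean", "per_subject"]


class ReallocationError(ValueError):
    pass


@dataclass(frozen=True)
class ReallocationGrid:
    durations: tuple[int, ...] = DEFAULT_DURATIONS
    parts: tuple[str, ...] = SUBJECT_PARTS

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.durations):
            raise ReallocationError("durations must be nonnegative")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        """All ordered (to, from) behavior pairs."""
        return [(a, b) for a, b in permutations(self.parts, 2)]


@dataclass(frozen=True)
class ReallocationEstimate:
    to: str
    frm: str
    t: float
    delta: float
    ci: tuple[float, float]
    significant: bool
    feasible: bool
    baseline_mode: str


def reallocate(
    baseline: np.ndarray,
    to: str,
    frm: str,
    t: float,
    parts: Sequence[str] = SUBJECT_PARTS,
) -> np.ndarray:
    """Move ``t`` minutes from ``frm`` to ``to``; other parts unchanged."""
    parts = tuple(parts)
    if to == frm:
        raise ReallocationError("to and from behaviors must differ")
    x = np.asarray(baseline, dtype=float).copy()
    if abs(x.sum() - MINUTES_PER_DAY) > 1e-6:
        raise ReallocationError("baseline must be in minutes summing to 1440")
    i, j = parts.index(to), parts.index(frm)
    if t < 0:
        raise ReallocationError("duration must be nonnegative")
    if t >= x[j]:
        raise ReallocationError(
            f"cannot move {t} min from {frm} (only {x[j]:.1f} min available); "
            f"infeasible reallocation {frm}->{to}"
        )
    x[i] += t
    x[j] -= t
    return x


def baseline_composition(
    compositions: np.ndarray, mode: BaselineMode = "center"
) -> np.ndarray:
    """Cohort baseline in minutes: compositional center or arithmetic mean."""
    X = np.asarray(compositions, dtype=float)
    if mode == "center":
        return geometric_center(X, total=MINUTES_PER_DAY)
    if mode == "mean":
        return close(X.mean(axis=0), total=MINUTES_PER_DAY)
    raise ReallocationError(f"unknown baseline mode {mode!r}")


def _estimate_from_contrast(
    model: FittedModel, c: np.ndarray, level: float
) -> tuple[float, tuple[float, float]]:
    delta = float(c @ model.beta_ilr)
    var = float(c @ model.cov_ilr @ c)
    q = stats.t.ppf(0.5 + level / 2, model.df_resid)
    half = q * np.sqrt(var)
    return delta, (delta - half, delta + half)


def estimate_change(
    model: FittedModel,
    baseline: np.ndarray | None = None,
    grid: ReallocationGrid | None = None,
    compositions: np.ndarray | None = None,
    mode: BaselineMode = "center",
    level: float = 0.95,
) -> list[ReallocationEstimate]:
    """Reallocation estimates over the full (pair, duration) grid.

    ``baseline`` (minutes, summing to 1440) overrides ``mode``;
    otherwise the baseline is derived from ``compositions``.  In
    ``per_subject`` mode the ilr contrast is averaged over the subjects
    for which the reallocation is feasible (their own compositions as
    baselines).  Infeasible cells are reported with
    ``feasible=False`` rather than dropped.
    """
    grid = grid or ReallocationGrid()
    parts = grid.parts
    if baseline is not None:
        base = np.asarray(baseline, dtype=float)
        mode = "explicit"
    elif mode in ("center", "mean"):
        if compositions is None:
            raise ReallocationError("need compositions to derive the baseline")
        base = baseline_composition(compositions, mode)
    elif mode == "per_subject":
        if compositions is None:
            raise ReallocationError("per_subject mode needs compositions")
        base = None
    else:
        raise ReallocationError(f"unknown baseline mode {mode!r}")

    basis = model.basis
    order = [parts.index(p) for p in basis.parts]

    def _z(x: np.ndarray) -> np.ndarray:
        return ilr(np.asarray(x)[..., order], basis)

    out: list[ReallocationEstimate] = []
    for to, frm in grid.pairs:
        for t in grid.durations:
            if mode == "per_subject":
                X = close(np.asarray(compositions, float), MINUTES_PER_DAY)
                ok = X[:, parts.index(frm)] > t
                if not ok.any():
                    out.append(
                        ReallocationEstimate(to, frm, t, float("nan"),
                                             (float("nan"), float("nan")),
                                             False, False, mode)
                    )
                    continue
                Xb = X[ok]
                Xr = np.stack([reallocate(x, to, frm, t, parts) for x in Xb])
                c = (_z(Xr) - _z(Xb)).mean(axis=0)
            else:
                try:
                    xr = reallocate(base, to, frm, t, parts)
                except ReallocationError:
                    out.append(
                        ReallocationEstimate(to, frm, t, float("nan"),
                                             (float("nan"), float("nan")),
                                             False, False, mode)
                    )
                    continue
                c = _z(xr) - _z(base)
            delta, ci = _estimate_from_contrast(model, c, level)
            out.append(
                ReallocationEstimate(
                    to=to, frm=frm, t=t, delta=delta, ci=ci,
                    significant=not (ci[0] <= 0.0 <= ci[1]),
                    feasible=True, baseline_mode=mode,
                )
            )
    return out


def estimates_table(estimates: Sequence[ReallocationEstimate]) -> pd.DataFrame:
    """Wide table: rows = ordered pairs, columns = durations."""
    df = pd.DataFrame([e.__dict__ for e in estimates])
    df["cell"] = [
        "infeasible" if not e.feasible
        else f"{e.delta:.2f} ({e.ci[0]:.2f}, {e.ci[1]:.2f})"
        + ("*" if e.significant else "")
        for e in estimates
    ]
    df["pair"] = "up_" + df["to"] + "_down_" + df["frm"]
    return df.pivot(index="pair", columns="t", values="cell")


def asymmetry_report(estimates: Sequence[ReallocationEstimate]) -> pd.DataFrame:
    """Side-by-side deltas for (a->b, b->a) with their (non-zero) sum."""
    by_key = {(e.to, e.frm, e.t): e for e in estimates}
    rows = []
    seen = set()
    for (to, frm, t), e in by_key.items():
        if (frm, to, t) in seen:
            continue
        seen.add((to, frm, t))
        rev = by_key.get((frm, to, t))
        rows.append(
            {
                "pair": f"{to}/{frm}",
                "t": t,
                "delta_fwd": e.delta,
                "delta_rev": rev.delta if rev else float("nan"),
                "asymmetry": (e.delta + rev.delta) if rev else float("nan"),
            }
        )
    return pd.DataFrame(rows).sort_values(["pair", "t"]).reset_index(drop=True)
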