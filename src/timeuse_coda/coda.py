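"""Aitchison-geometry primitives for time-use compositions.

A daily time-use composition is a strictly positive vector of minutes
spent in each behavior (sleep, sedentary behavior, light and
moderate-to-vigorous physical activity) carrying only relative
information; the constant-sum constraint (1440 min/day, or 100 when
expressed in percent) is imposed by :func:`close`.

The isometric log-ratio (ilr) transform maps a D-part composition to
D-1 unconstrained orthonormal coordinates.  A particular basis is
specified by a sequential binary partition (SBP): a hierarchy of binary
splits of the parts encoded as a (D-1) x D sign matrix.  All quantities
that matter downstream (Mahalanobis distances, total variance, fitted
regression values, reallocation estimates) are invariant to the SBP
choice; the default is the pivot partition over (SB, LPA, MVPA, sleep).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from sklearn.covariance import MinCovDet

MINUTES_PER_DAY = 1440.0

#: Part order used for the default pivot basis (descriptive-table order).
DEFAULT_PARTS: tuple[str, ...] = ("sb", "lpa", "mvpa", "sleep")


class CompositionError(ValueError):
    """Raised for invalid compositional input (zero/negative parts, shape)."""


def _as_2d(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    if x.ndim == 2:
        return x, False
    raise CompositionError(f"expected 1-D or 2-D array, got ndim={x.ndim}")


def close(
    values: np.ndarray,
    total: float = MINUTES_PER_DAY,
    parts: Sequence[str] | None = None,
) -> np.ndarray:
    """Rescale strictly positive parts to sum to ``total``.

    Parameters
    ----------
    values
        1-D composition or 2-D array (rows are compositions).
    total
        Closure constant (1440 for minutes, 100 for percent).
    parts
        Optional part labels used to name the offending part in errors.

    Raises
    ------
    CompositionError
        If any part is zero or negative.  Zero replacement is out of
        scope: the analysis assumes strictly positive parts.
    """
    X, was_1d = _as_2d(values)
    bad = ~(X > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        label = parts[j] if parts is not None else f"column {j}"
        raise CompositionError(
            f"non-positive part ({label}={X[i, j]!r} in row {i}); "
            "compositions must be strictly positive"
        )
    out = X * (float(total) / X.sum(axis=1, keepdims=True))
    return out[0] if was_1d else out


def geometric_center(X: np.ndarray, total: float = 100.0) -> np.ndarray:
    """Compositional center: per-part geometric means, closed to ``total``."""
    X2, _ = _as_2d(X)
    if X2.shape[0] == 0:
        raise CompositionError("center of an empty set of compositions")
    if not (X2 > 0).all():
        raise CompositionError("compositions must be strictly positive")
    g = np.exp(np.log(X2).mean(axis=0))
    return close(g, total=total)


def _validate_sbp(sbp: np.ndarray) -> None:
    D = sbp.shape[1]
    if sbp.shape != (D - 1, D):
        raise ValueError(f"SBP must be (D-1) x D, got {sbp.shape}")
    if not np.isin(sbp, (-1, 0, 1)).all():
        raise ValueError("SBP entries must be in {-1, 0, +1}")
    for i, row in enumerate(sbp):
        if not ((row == 1).any() and (row == -1).any()):
            raise ValueError(f"SBP row {i} must contain both +1 and -1")
    # hierarchy: supports of two rows are nested (within one side) or disjoint
    supports = [set(np.flatnonzero(r != 0)) for r in sbp]
    sides = [
        (set(np.flatnonzero(r == 1)), set(np.flatnonzero(r == -1))) for r in sbp
    ]
    for i in range(D - 1):
        for j in range(i + 1, D - 1):
            si, sj = supports[i], supports[j]
            if si & sj:
                nested = (
                    sj <= sides[i][0]
                    or sj <= sides[i][1]
                    or si <= sides[j][0]
                    or si <= sides[j][1]
                )
                if not nested:
                    raise ValueError(
                        f"SBP rows {i} and {j} overlap without nesting: "
                        "not a valid sequential binary partition"
                    )


def _contrast_from_sbp(sbp: np.ndarray) -> np.ndarray:
    rows = []
    for row in sbp:
        r = float((row == 1).sum())
        s = float((row == -1).sum())
        v = np.zeros(len(row))
        v[row == 1] = np.sqrt(s / (r * (r + s)))
        v[row == -1] = -np.sqrt(r / (s * (r + s)))
        rows.append(v)
    return np.array(rows)


@dataclass(frozen=True)
class IlrBasis:
    """An ilr basis defined by a sequential binary partition.

    ``contrast`` is the (D-1) x D orthonormal log-contrast matrix with
    zero row sums; coordinates are ``contrast @ ln(x)``.
    """

    parts: tuple[str, ...]
    sbp: np.ndarray
    contrast: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        sbp = np.asarray(self.sbp, dtype=int)
        if sbp.shape[1] != len(self.parts):
            raise ValueError("SBP width must match number of parts")
        _validate_sbp(sbp)
        V = _contrast_from_sbp(sbp)
        D1 = V.shape[0]
        if not np.allclose(V @ V.T, np.eye(D1), atol=1e-12):
            raise ValueError("derived contrast matrix is not orthonormal")
        object.__setattr__(self, "sbp", sbp)
        object.__setattr__(self, "contrast", V)

    @property
    def n_parts(self) -> int:
        return len(self.parts)

    @classmethod
    def pivot(cls, parts: Sequence[str] = DEFAULT_PARTS) -> "IlrBasis":
        """Pivot SBP: part j against the geometric mean of parts j+1..D."""
        D = len(parts)
        sbp = np.zeros((D - 1, D), dtype=int)
        for j in range(D - 1):
            sbp[j, j] = 1
            sbp[j, j + 1 :] = -1
        return cls(parts=tuple(parts), sbp=sbp)

    def reordered(self, parts: Sequence[str]) -> "IlrBasis":
        """Pivot basis over the same part set in a different order."""
        if set(parts) != set(self.parts):
            raise ValueError("part sets differ")
        return IlrBasis.pivot(parts)


def ilr(x: np.ndarray, basis: IlrBasis | None = None) -> np.ndarray:
    """Map composition(s) to ilr coordinates: ``contrast @ ln(x)``.

    Scale-invariant: closure to 1440 or 100 gives identical coordinates.
    """
    if basis is None:
        basis = IlrBasis.pivot()
    X, was_1d = _as_2d(x)
    if X.shape[1] != basis.n_parts:
        raise CompositionError(
            f"composition has {X.shape[1]} parts, basis expects {basis.n_parts}"
        )
    if not (X > 0).all():
        raise CompositionError("compositions must be strictly positive")
    Z = np.log(X) @ basis.contrast.T
    return Z[0] if was_1d else Z


def ilr_inverse(
    z: np.ndarray, basis: IlrBasis | None = None, total: float = MINUTES_PER_DAY
) -> np.ndarray:
    """Back-transform ilr coordinates to a composition closed to ``total``."""
    if basis is None:
        basis = IlrBasis.pivot()
    Z, was_1d = _as_2d(z)
    if Z.shape[1] != basis.n_parts - 1:
        raise CompositionError(
            f"coordinate vector has length {Z.shape[1]}, expected {basis.n_parts - 1}"
        )
    X = np.exp(Z @ basis.contrast)
    X = close(X, total=total)
    return X[0] if was_1d else X


def aitchison_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Aitchison distance = Euclidean distance between ilr images."""
    D = np.asarray(x).shape[-1]
    basis = IlrBasis.pivot(tuple(f"p{i}" for i in range(D)))
    return float(np.linalg.norm(ilr(x, basis) - ilr(y, basis)))


# ---------------------------------------------------------------------------
# dispersion: variation matrix and robust scatter


@dataclass(frozen=True)
class VariationMatrix:
    """Pairwise log-ratio variances t_ij = Var(ln(x_i/x_j))."""

    t: np.ndarray
    parts: tuple[str, ...]
    method: str
    total_variance: float

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(self.t, index=self.parts, columns=self.parts)


def _mcd(
    Z: np.ndarray, support_fraction: float | None = 0.75, random_state: int = 0
) -> MinCovDet:
    n, p = Z.shape
    if n < 2 * p + 2:
        raise ValueError(
            f"n={n} too small for MCD scatter on {p} coordinates (need >= {2 * p + 2})"
        )
    est = MinCovDet(support_fraction=support_fraction, random_state=random_state)
    est.fit(Z)
    return est


def variation_matrix(
    X: np.ndarray,
    parts: Sequence[str] = DEFAULT_PARTS,
    method: Literal["classical", "robust"] = "classical",
    support_fraction: float | None = 0.75,
    random_state: int = 0,
) -> VariationMatrix:
    """Variation matrix of a compositional sample.

    ``classical`` computes unbiased sample variances of every pairwise
    log-ratio.  ``robust`` fits a Minimum Covariance Determinant scatter
    to the ilr coordinates (FastMCD with a fixed seed, so the estimate
    is reproducible and SBP-invariant) and derives every log-ratio
    variance from it via ``Var(ln x_i - ln x_j) = S_ii + S_jj - 2 S_ij``
    of the implied clr covariance.
    """
    X2, _ = _as_2d(X)
    D = X2.shape[1]
    n = X2.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 compositions, got n={n}")
    if method == "classical":
        L = np.log(close(X2, total=1.0, parts=tuple(parts)))
        t = np.zeros((D, D))
        for i in range(D):
            for j in range(i + 1, D):
                v = np.var(L[:, i] - L[:, j], ddof=1)
                t[i, j] = t[j, i] = v
    elif method == "robust":
        basis = IlrBasis.pivot(tuple(parts))
        Z = ilr(X2, basis)
        est = _mcd(Z, support_fraction=support_fraction, random_state=random_state)
        S_clr = basis.contrast.T @ est.covariance_ @ basis.contrast
        d = np.diag(S_clr)
        t = d[:, None] + d[None, :] - 2.0 * S_clr
        np.fill_diagonal(t, 0.0)
        t = np.maximum(t, 0.0)
        t = (t + t.T) / 2.0
    else:
        raise ValueError(f"unknown method {method!r}")
    total = float(t.sum() / (2 * D))
    return VariationMatrix(
        t=t, parts=tuple(parts), method=method, total_variance=total
    )


@dataclass(frozen=True)
class OutlierReport:
    """Robust Mahalanobis distances of ilr coordinates with a chi-square cutoff.

    ``flags[i]`` is true iff ``distance[i]**2 > cutoff`` where ``cutoff``
    is the chi-square(D-1) quantile at ``level``.
    """

    distance: np.ndarray
    cutoff: float
    level: float
    flags: np.ndarray

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def detect_outliers(
    X: np.ndarray,
    basis: IlrBasis | None = None,
    level: float = 0.975,
    support_fraction: float | None = 0.75,
    random_state: int = 0,
) -> OutlierReport:
    """Flag compositions by robust Mahalanobis distance in ilr coordinates.

    The MCD location/scatter is computed in a fixed canonical pivot
    basis internally, making the distances exactly invariant to the
    ``basis`` argument (they are basis-invariant mathematically; the
    canonical computation removes any estimator tie-breaking noise).
    """
    X2, _ = _as_2d(X)
    D = X2.shape[1]
    parts = basis.parts if basis is not None else tuple(f"p{i}" for i in range(D))
    canonical = IlrBasis.pivot(tuple(sorted(parts)))
    order = [parts.index(p) for p in canonical.parts]
    Z = ilr(X2[:, order], canonical)
    est = _mcd(Z, support_fraction=support_fraction, random_state=random_state)
    d2 = est.mahalanobis(Z)
    cutoff = float(stats.chi2.ppf(level, df=D - 1))
    return OutlierReport(
        distance=np.sqrt(d2), cutoff=cutoff, level=level, flags=d2 > cutoff
    )


def total_variance(X: np.ndarray, **kwargs) -> float:
    """Total compositional variance (normalized variation-matrix sum)."""
    return variation_matrix(X, **kwargs).total_variance
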