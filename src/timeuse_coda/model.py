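"""Compositional linear model of zBMI on ilr coordinates plus covariates.

The compositional predictor enters the design as a block of D-1 ilr
coordinates that is treated atomically: stepwise AIC simplification
(both directions) operates on the candidate covariates only and never
removes the block.  Fitted values, R-squared, F, AIC, and covariate
coefficients are invariant to the SBP choice; individual ilr
coefficients are basis-specific by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from timeuse_coda.coda import IlrBasis, ilr
from timeuse_coda.synthetic import SUBJECT_PARTS


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    outcome: str = "zbmi"
    covariates: tuple[str, ...] = ("sex", "age_years", "ses_score")
    stepwise: bool = True
    residual_flag_bound: float = 1.96


@dataclass
class FittedModel:
    """OLS fit of outcome ~ 1 + ilr block + retained covariates."""

    params: pd.Series
    cov_params: pd.DataFrame
    df_resid: int
    r2: float
    adj_r2: float
    fvalue: float
    f_df: tuple[int, int]
    f_pvalue: float
    aic: float
    basis: IlrBasis
    ilr_names: tuple[str, ...]
    retained_covariates: tuple[str, ...]
    vif: pd.Series
    results: object = field(repr=False, default=None)
    design: pd.DataFrame = field(repr=False, default=None)
    outcome: pd.Series = field(repr=False, default=None)

    @property
    def beta_ilr(self) -> np.ndarray:
        return self.params[list(self.ilr_names)].to_numpy()

    @property
    def cov_ilr(self) -> np.ndarray:
        names = list(self.ilr_names)
        return self.cov_params.loc[names, names].to_numpy()

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        q = stats.t.ppf(0.5 + level / 2, self.df_resid)
        se = pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)
        return pd.DataFrame(
            {"low": self.params - q * se, "high": self.params + q * se}
        )

    def flagged_residuals(self, bound: float = 1.96) -> np.ndarray:
        """Indices with internally studentized residuals outside +-bound.

        Diagnostic only: flagged rows are reported, not removed, unless
        :func:`fit` is called with ``refit_without_flagged=True``.
        """
        infl = self.results.get_influence()
        return np.flatnonzero(np.abs(infl.resid_studentized_internal) > bound)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "params": self.params.to_dict(),
            "cov_params": self.cov_params.to_dict(),
            "df_resid": self.df_resid,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "fvalue": self.fvalue,
            "f_df": list(self.f_df),
            "f_pvalue": self.f_pvalue,
            "aic": self.aic,
            "vif": self.vif.to_dict(),
            "basis_parts": list(self.basis.parts),
            "basis_sbp": self.basis.sbp.tolist(),
            "ilr_names": list(self.ilr_names),
            "retained_covariates": list(self.retained_covariates),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def design_matrix(
    table: pd.DataFrame,
    basis: IlrBasis,
    covariates: Sequence[str] = (),
    parts: Sequence[str] = SUBJECT_PARTS,
) -> pd.DataFrame:
    """[ilr1..ilr_{D-1}, covariates] built from ``<part>_min`` columns."""
    comp = table[[f"{p}_min" for p in basis.parts]].to_numpy()
    Z = ilr(comp, basis)
    X = pd.DataFrame(
        Z, columns=[f"ilr{i + 1}" for i in range(Z.shape[1])], index=table.index
    )
    for cov in covariates:
        if cov == "sex":
            X["sex"] = _encode_sex(table["sex"])
        else:
            X[cov] = pd.to_numeric(table[cov])
    return X


def _encode_sex(col: pd.Series) -> np.ndarray:
    if col.dtype.kind in "if":
        return col.to_numpy(dtype=float)
    return (col.astype(str).str.upper().isin(["M", "MALE", "1"])).to_numpy(dtype=float)


def _ols(y: np.ndarray, X: pd.DataFrame):
    Xc = sm.add_constant(X, has_constant="add")
    return sm.OLS(np.asarray(y, dtype=float), Xc).fit()


def _check_rank(X: pd.DataFrame) -> None:
    Xc = sm.add_constant(X, has_constant="add")
    arr = Xc.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        corr = np.corrcoef(arr[:, 1:], rowvar=False)
        pairs = [
            (X.columns[i], X.columns[j])
            for i in range(corr.shape[0])
            for j in range(i + 1, corr.shape[0])
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ModelError(f"rank-deficient design; collinear columns: {pairs}")


def stepwise_aic(
    y: np.ndarray,
    ilr_block: pd.DataFrame,
    candidates: pd.DataFrame,
    start_with_all: bool = True,
) -> list[str]:
    """Both-direction stepwise over covariates, ilr block protected.

    Greedy: at each step evaluate dropping any included covariate and
    adding any excluded one; take the move with the lowest AIC; stop
    when no move improves.
    """
    included = list(candidates.columns) if start_with_all else []
    pool = list(candidates.columns)

    def _aic(cols: list[str]) -> float:
        X = pd.concat([ilr_block, candidates[cols]], axis=1)
        return _ols(y, X).aic

    current = _aic(included)
    while True:
        moves: list[tuple[float, str, str]] = []
        for c in included:
            moves.append((_aic([x for x in included if x != c]), "drop", c))
        for c in pool:
            if c not in included:
                moves.append((_aic(included + [c]), "add", c))
        if not moves:
            break
        best = min(moves, key=lambda m: m[0])
        if best[0] < current - 1e-10:
            current = best[0]
            if best[1] == "drop":
                included.remove(best[2])
            else:
                included.append(best[2])
        else:
            break
    return included


def vif_table(X: pd.DataFrame) -> pd.Series:
    """VIF_k = 1/(1 - R2_k) of predictor k regressed on the others.

    Empty for single-predictor designs.
    """
    cols = list(X.columns)
    if len(cols) < 2:
        return pd.Series(dtype=float)
    out = {}
    for k in cols:
        others = [c for c in cols if c != k]
        r2 = _ols(X[k].to_numpy(), X[others]).rsquared
        out[k] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def fit(
    table: pd.DataFrame,
    basis: IlrBasis | None = None,
    spec: ModelSpec | None = None,
    refit_without_flagged: bool = False,
) -> FittedModel:
    """Fit the compositional model with optional stepwise simplification."""
    basis = basis or IlrBasis.pivot(SUBJECT_PARTS)
    spec = spec or ModelSpec()
    y = pd.to_numeric(table[spec.outcome]).to_numpy()
    covs = [c for c in spec.covariates if c == "sex" or c in table.columns]
    covs = [c for c in covs if (c in table.columns)]
    X_full = design_matrix(table, basis, covariates=covs)
    ilr_names = tuple(c for c in X_full.columns if c.startswith("ilr"))
    ilr_block = X_full[list(ilr_names)]
    cand = X_full[covs]
    if len(table) <= X_full.shape[1] + 1:
        raise ModelError("not enough rows for the candidate design")
    _check_rank(X_full)
    retained = stepwise_aic(y, ilr_block, cand) if spec.stepwise else covs
    X = pd.concat([ilr_block, cand[retained]], axis=1)
    res = _ols(y, X)

    def _guard(v: float) -> float:
        # constant outcome -> zero TSS -> NaN R2/F; report 0 instead
        return float(v) if np.isfinite(v) else 0.0

    model = FittedModel(
        params=res.params,
        cov_params=res.cov_params(),
        df_resid=int(res.df_resid),
        r2=_guard(res.rsquared),
        adj_r2=_guard(res.rsquared_adj),
        fvalue=_guard(res.fvalue),
        f_df=(int(res.df_model), int(res.df_resid)),
        f_pvalue=float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 1.0,
        aic=float(res.aic),
        basis=basis,
        ilr_names=ilr_names,
        retained_covariates=tuple(retained),
        vif=vif_table(X),
        results=res,
        design=X,
        outcome=pd.Series(y, index=table.index),
    )
    if refit_without_flagged:
        flagged = model.flagged_residuals(spec.residual_flag_bound)
        if flagged.size:
            keep = np.setdiff1d(np.arange(len(table)), flagged)
            sub = table.iloc[keep]
            inner = ModelSpec(
                outcome=spec.outcome,
                covariates=tuple(retained),
                stepwise=False,
                residual_flag_bound=spec.residual_flag_bound,
            )
            return fit(sub, basis, inner, refit_without_flagged=False)
    return model


def predict(model: FittedModel, X_new: pd.DataFrame) -> np.ndarray:
    Xc = sm.add_constant(X_new[model.design.columns], has_constant="add")
    return Xc.to_numpy() @ model.params.to_numpy()


def anova(model: FittedModel) -> pd.DataFrame:
    """Sequential (type-I) ANOVA: ilr block first, then covariates.

    The last row is the overall regression F against residuals; it
    satisfies F = (R2/(1-R2)) * df_resid/df_model.
    """
    y = model.outcome.to_numpy()
    X = model.design
    terms: list[tuple[str, list[str]]] = [("ilr", list(model.ilr_names))]
    for cov in model.retained_covariates:
        terms.append((cov, [cov]))
    n = len(y)
    tss = float(((y - y.mean()) ** 2).sum())
    rows = []
    cols: list[str] = []
    prev_rss = tss
    for name, tcols in terms:
        cols = cols + tcols
        rss = float(_ols(y, X[cols]).ssr)
        rows.append(
            {"term": name, "df": len(tcols), "sum_sq": prev_rss - rss}
        )
        prev_rss = rss
    resid_df = model.df_resid
    mse = prev_rss / resid_df
    for row in rows:
        row["F"] = (row["sum_sq"] / row["df"]) / mse
        row["p"] = float(stats.f.sf(row["F"], row["df"], resid_df))
    df_model = sum(r["df"] for r in rows)
    rows.append(
        {
            "term": "overall",
            "df": df_model,
            "sum_sq": tss - prev_rss,
            "F": ((tss - prev_rss) / df_model) / mse,
            "p": float(stats.f.sf(((tss - prev_rss) / df_model) / mse, df_model, resid_df)),
        }
    )
    rows.append({"term": "residual", "df": resid_df, "sum_sq": prev_rss,
                 "F": float("nan"), "p": float("nan")})
    return pd.DataFrame(rows)
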