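"""Statistical screening of abiotic and biotic drivers of metabolic limitation.

Provides the estimators the pipeline's driver stage relies on:

* Pearson correlation with pairwise deletion of missing values,
* ordinary least squares with adjusted R² and Gaussian AIC,
* one-way ANOVA for two-region comparisons,
* the Mantel permutation test relating two distance matrices,
* forward stepwise model selection by AIC,
* model-agnostic permutation importance (mean MSE increase after
  shuffling one predictor, reported as relative contributions).

Permutation importance is used here as the variable-attribution method:
it measures exactly the permute-and-score quantity that tree-ensemble
importance measures estimate, but around the fitted linear model, so the
attribution is reproducible from the definition alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import qr as scipy_qr

from .core import DistanceMatrix, DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "MantelResult",
    "AnovaResult",
    "pearson",
    "ols",
    "anova_oneway",
    "mantel",
    "forward_stepwise",
    "permutation_importance",
]


@dataclass
class RegressionResult:
    """Fitted OLS model: coefficients, fit statistics and p-values."""

    predictors: list[str]
    coefficients: dict[str, float]
    intercept: float
    r2: float
    adj_r2: float
    p_values: dict[str, float]
    aic: float
    n: int

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        yhat = np.full(len(X), self.intercept, dtype=float)
        for name in self.predictors:
            yhat += self.coefficients[name] * X[name].to_numpy(dtype=float)
        return yhat


@dataclass(frozen=True)
class MantelResult:
    """Observed matrix correlation and its one-tailed permutation p-value."""

    r_obs: float
    p_value: float
    n_perm: int
    n: int


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float


def pearson(
    xs, ys, x_name: str = "x", y_name: str = "y"
) -> tuple[float, float]:
    """Pearson correlation with two-sided t-based p-value.

    Missing values are removed pairwise; both vectors must be non-constant
    with at least 3 complete pairs.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise DomainError("fewer than 3 complete pairs for correlation")
    for v, name in ((x, x_name), (y, y_name)):
        if np.ptp(v) == 0:
            raise DomainError(f"variable {name!r} is constant; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _as_design(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1:
        X = X.T
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Columns made redundant by earlier ones, via pivoted QR."""
    rank = np.linalg.matrix_rank(design)
    _, _, piv = scipy_qr(design, pivoting=True, mode="economic")
    redundant = sorted(piv[rank:])
    return [names[i] for i in redundant if i > 0]  # skip the constant column


def ols(y, X) -> RegressionResult:
    """Ordinary least squares of y on X with an intercept.

    Rows with any missing value are dropped listwise.  A rank-deficient
    design raises an error naming the collinear columns.
    """
    Xdf = _as_design(X)
    y = np.asarray(y, dtype=float)
    if len(y) != len(Xdf):
        raise ValueError("response and design have different lengths")
    ok = np.isfinite(y) & np.isfinite(Xdf.to_numpy(dtype=float)).all(axis=1)
    if not ok.all():
        logger.info("ols: dropping %d rows with missing values", int((~ok).sum()))
    Xdf = Xdf.loc[ok].reset_index(drop=True)
    y = y[ok]
    n, p = len(y), Xdf.shape[1]
    if n <= p + 1:
        raise DomainError(f"need n > p + 1 observations (n={n}, p={p})")
    names = ["const"] + list(Xdf.columns)
    design = np.column_stack([np.ones(n), Xdf.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, names)
        raise DomainError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, pd.DataFrame(design, columns=names)).fit()
    coef = {c: float(fit.params[c]) for c in Xdf.columns}
    pvals = {c: float(fit.pvalues[c]) for c in Xdf.columns}
    r2 = float(fit.rsquared) if p > 0 else 0.0
    adj = float(fit.rsquared_adj) if p > 0 else 0.0
    return RegressionResult(
        predictors=list(Xdf.columns),
        coefficients=coef,
        intercept=float(fit.params["const"]),
        r2=r2,
        adj_r2=adj,
        p_values=pvals,
        aic=float(fit.aic),
        n=n,
    )


def anova_oneway(groups: list) -> AnovaResult:
    """Classic one-way ANOVA; with two groups F equals the pooled t²."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    gs = [g[np.isfinite(g)] for g in gs]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise DomainError("need >= 2 groups with >= 2 values each")
    all_vals = np.concatenate(gs)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b = len(gs) - 1
    df_w = len(all_vals) - len(gs)
    if ssw <= 0:
        raise DomainError("zero within-group variance; F undefined")
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(f_stat=float(f), df_between=df_b, df_within=df_w, p_value=p)


def _pearson_r_rows(A: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson r of each row of A against v (both already 1-D compatible)."""
    Ac = A - A.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((Ac**2).sum(axis=1) * (vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Ac @ vc) / denom


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel test: Pearson correlation of two distance matrices.

    The null distribution is built by jointly permuting the rows and
    columns of the second matrix; the one-tailed (greater) p-value uses
    the add-one convention p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm).
    """
    if d1.ids != d2.ids:
        raise DomainError("distance matrices have mismatched ids/order")
    n = d1.n
    if n < 4:
        raise DomainError("Mantel test needs at least 4 samples")
    iu = np.triu_indices(n, k=1)
    v1 = d1.d[iu]
    v2 = d2.d[iu]
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise DomainError("constant distance matrix; Mantel r undefined")
    r_obs = float(stats.pearsonr(v1, v2)[0])

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    # gather permuted upper triangles of d2 in one vectorised indexing step
    A = d2.d[perms[:, iu[0]], perms[:, iu[1]]]
    r_perm = _pearson_r_rows(A, v1)
    n_ge = int(np.sum(r_perm >= r_obs - 1e-12))
    p = (1 + n_ge) / (1 + n_perm)
    return MantelResult(r_obs=r_obs, p_value=float(p), n_perm=n_perm, n=n)


def forward_stepwise(y, X) -> RegressionResult:
    """Greedy forward selection by AIC.

    Starts from the intercept-only model, at each step adds the candidate
    that most lowers AIC (ties broken by column order), and stops when no
    addition lowers it.  Returns the final model's fit.
    """
    Xdf = _as_design(X)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y) & np.isfinite(Xdf.to_numpy(dtype=float)).all(axis=1)
    Xdf = Xdf.loc[ok].reset_index(drop=True)
    y = y[ok]

    selected: list[str] = []
    current = ols(y, Xdf[selected])
    remaining = list(Xdf.columns)
    while remaining:
        fits = []
        for cand in remaining:
            try:
                fits.append((cand, ols(y, Xdf[selected + [cand]])))
            except DomainError:  # collinear with already-selected set
                continue
        if not fits:
            break
        best_cand, best_fit = min(
            fits, key=lambda cf: (cf[1].aic, list(Xdf.columns).index(cf[0]))
        )
        if best_fit.aic < current.aic:
            selected.append(best_cand)
            remaining.remove(best_cand)
            current = best_fit
        else:
            break
    return current


def permutation_importance(
    model: RegressionResult,
    y,
    X: pd.DataFrame,
    n_rep: int = 100,
    seed: int = 0,
    predictors: list[str] | None = None,
) -> pd.DataFrame:
    """Mean MSE increase after permuting each predictor column.

    Importances are averaged over ``n_rep`` shuffles and additionally
    reported as percentages of their (non-negative) sum, matching the
    convention of reporting relative contributions of drivers.
    """
    if n_rep < 1:
        raise DomainError("n_rep must be >= 1")
    preds = predictors if predictors is not None else list(model.predictors)
    for p in preds:
        if p not in model.predictors:
            raise DomainError(f"predictor {p!r} is not in the fitted model")
    y = np.asarray(y, dtype=float)
    base_mse = float(np.mean((y - model.predict(X)) ** 2))
    rng = np.random.default_rng(seed)
    rows = []
    for p in preds:
        increases = np.empty(n_rep)
        Xp = X.copy()
        for rep in range(n_rep):
            Xp[p] = rng.permutation(X[p].to_numpy())
            increases[rep] = np.mean((y - model.predict(Xp)) ** 2) - base_mse
        rows.append({"predictor": p, "mse_increase": float(increases.mean())})
    df = pd.DataFrame(rows)
    pos = df["mse_increase"].clip(lower=0.0)
    total = pos.sum()
    df["contribution_pct"] = 100.0 * pos / total if total > 0 else np.nan
    return df
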