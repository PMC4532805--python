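"""Clinical-score regression: Box-Cox, backward stepwise OLS, Bonferroni,
leave-one-out cross-validation.

The predictor matrix is the per-subject MLV of each observed signature
combination plus demographic/psychological covariates. For each response a
backward stepwise search (AIC by default, p-value optional) selects the
model; the model F-test p-value is Bonferroni-corrected over ``m`` tests
and prediction quality is summarized by the adjusted R^2 and p of the
leave-one-out predicted-versus-observed fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

#: significance markers at the conventional thresholds
SIGNIFICANCE_SYMBOLS = ((0.001, "*"), (0.01, "#"), (0.05, "†"))
NONSIG_SYMBOL = "‡"


def significance_symbol(p: float) -> str:
    for thresh, sym in SIGNIFICANCE_SYMBOLS:
        if p < thresh:
            return sym
    return NONSIG_SYMBOL


def boxcox(
    y: np.ndarray,
    lmbda: float | None = None,
    grid: tuple[float, float, float] = (-3.0, 3.0, 0.01),
) -> tuple[np.ndarray, float]:
    """Box-Cox power transform; lambda by maximum likelihood over a grid.

    y(lambda) = (y**lambda - 1) / lambda for lambda != 0, log(y) otherwise.
    Inputs must be strictly positive (use :func:`shift_positive` first).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("need a 1D sample of at least 2 values")
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if lmbda is None:
        lo, hi, step = grid
        lambdas = np.arange(lo, hi + step / 2, step)
        llf = np.array([stats.boxcox_llf(l, y) for l in lambdas])
        lmbda = float(lambdas[int(np.argmax(llf))])
    transformed = stats.boxcox(y, lmbda=lmbda)
    return np.asarray(transformed, dtype=float), float(lmbda)


def shift_positive(y: np.ndarray) -> tuple[np.ndarray, float]:
    """Shift a sample by (1 - min) if any value is non-positive."""
    y = np.asarray(y, dtype=float)
    shift = 0.0
    if y.min() <= 0:
        shift = 1.0 - float(y.min())
    return y + shift, shift


def bonferroni(p: float, m: int = 7) -> float:
    """min(1, p * m)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be a positive count")
    return min(1.0, p * m)


@dataclass
class RegressionResult:
    """Outcome of stepwise selection (and optionally LOO CV) for one response."""

    response: str
    predictors: list[str]
    coefficients: dict[str, float]
    predictor_pvalues: dict[str, float]
    model_pvalue: float
    corrected_pvalue: float
    adj_r2: float
    r2: float
    boxcox_lambda: float | None = None
    dropped_zero_variance: list[str] = field(default_factory=list)
    loo_predictions: np.ndarray | None = None
    loo_adj_r2: float | None = None
    loo_pvalue: float | None = None
    loo_corrected_pvalue: float | None = None


def _fit_ols(X: pd.DataFrame, y: np.ndarray):
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return sm.OLS(np.asarray(y, dtype=float), design).fit()


def _drop_aliased(X: pd.DataFrame) -> pd.DataFrame:
    """Drop columns until the design (with intercept) has full rank."""
    cols = list(X.columns)
    while cols:
        design = sm.add_constant(X[cols], has_constant="add")
        if np.linalg.matrix_rank(design.to_numpy()) == design.shape[1]:
            break
        dropped = cols.pop()  # drop from the right, deterministic
        log.warning("dropping aliased predictor %s", dropped)
    return X[cols]


def backward_stepwise(
    X: pd.DataFrame,
    y: np.ndarray,
    response: str = "y",
    criterion: str = "aic",
    alpha: float = 0.05,
    m: int = 7,
) -> RegressionResult:
    """Backward elimination from the full predictor set.

    ``criterion='aic'``: repeatedly remove the predictor whose removal most
    lowers the AIC, until no removal lowers it. ``criterion='pvalue'``:
    remove the predictor with the largest p-value while it exceeds
    ``alpha``. Zero-variance predictors are dropped up front; when there
    are more predictors than can be fit (p >= n - 2) the pool is
    pre-screened by marginal regression p-value.
    """
    if criterion not in ("aic", "pvalue"):
        raise ValueError(f"unknown criterion {criterion!r}")
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and y length mismatch")

    variances = X.var(axis=0)
    dropped = [c for c in X.columns if variances[c] == 0]
    if dropped:
        log.warning("dropping zero-variance predictors: %s", dropped)
    X = X.drop(columns=dropped)

    if X.shape[1] >= n - 2 and X.shape[1] > 0:
        marginal = {
            c: _fit_ols(X[[c]], y).pvalues[c] for c in X.columns
        }
        keep = sorted(X.columns, key=lambda c: marginal[c])[: max(1, n - 3)]
        log.warning("pre-screening %d predictors down to %d", X.shape[1], len(keep))
        X = X[keep]

    X = _drop_aliased(X)
    current = list(X.columns)
    model = _fit_ols(X[current], y)
    while current:
        if criterion == "aic":
            candidates = {c: _fit_ols(X[[k for k in current if k != c]], y) for c in current}
            best = min(candidates, key=lambda c: candidates[c].aic)
            if candidates[best].aic < model.aic:
                current.remove(best)
                model = candidates[best]
            else:
                break
        else:
            pvals = model.pvalues.drop("const", errors="ignore")
            worst = pvals.idxmax()
            if pvals[worst] > alpha:
                current.remove(worst)
                model = _fit_ols(X[current], y)
            else:
                break

    coeffs = {c: float(model.params[c]) for c in current}
    pvals = {c: float(model.pvalues[c]) for c in current}
    model_p = float(model.f_pvalue) if current else float("nan")
    return RegressionResult(
        response=response,
        predictors=current,
        coefficients=coeffs,
        predictor_pvalues=pvals,
        model_pvalue=model_p,
        corrected_pvalue=bonferroni(model_p, m) if np.isfinite(model_p) else float("nan"),
        adj_r2=float(model.rsquared_adj) if current else 0.0,
        r2=float(model.rsquared) if current else 0.0,
        dropped_zero_variance=dropped,
    )


def loo_cv(
    X: pd.DataFrame, y: np.ndarray, m: int = 7
) -> tuple[np.ndarray, float, float]:
    """Leave-one-out refits of a fixed predictor set.

    Each subject's score is predicted from a model fit on the other n-1;
    the observed scores are then regressed on the predictions and that
    fit's adjusted R^2 and F-test p-value are returned. Singular held-out
    fits yield a NaN prediction and are excluded from the summary fit.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    k = X.shape[1]
    if n < k + 2:
        raise ValueError(f"need n >= p + 2 for LOO (n={n}, p={k})")
    preds = np.full(n, np.nan)
    Xv = X.to_numpy(dtype=float)
    for i in range(n):
        mask = np.arange(n) != i
        Xi = X.iloc[mask]
        design = sm.add_constant(Xi, has_constant="add")
        if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
            log.warning("singular leave-one-out fit for subject %d; prediction skipped", i)
            continue
        fit = _fit_ols(Xi, y[mask])
        row = np.concatenate([[1.0], Xv[i]])
        preds[i] = float(row @ fit.params.to_numpy())
    ok = np.isfinite(preds)
    if ok.sum() < 3:
        return preds, float("nan"), float("nan")
    if np.var(preds[ok]) == 0:
        return preds, 0.0, 1.0
    summary = _fit_ols(pd.DataFrame({"predicted": preds[ok]}), y[ok])
    return preds, float(summary.rsquared_adj), float(summary.f_pvalue)


def regress_response(
    X: pd.DataFrame,
    y: np.ndarray,
    response: str = "y",
    apply_boxcox: bool = False,
    criterion: str = "aic",
    alpha: float = 0.05,
    m: int = 7,
    run_loo: bool = True,
) -> RegressionResult:
    """Transform (optionally), select, and cross-validate one response."""
    lam = None
    if apply_boxcox:
        shifted, _ = shift_positive(np.asarray(y, dtype=float))
        y, lam = boxcox(shifted)
    result = backward_stepwise(X, y, response=response, criterion=criterion, alpha=alpha, m=m)
    result.boxcox_lambda = lam
    if run_loo and result.predictors and len(y) >= len(result.predictors) + 2:
        preds, adj, p = loo_cv(X[result.predictors], y, m=m)
        result.loo_predictions = preds
        result.loo_adj_r2 = adj
        result.loo_pvalue = p
        result.loo_corrected_pvalue = bonferroni(p, m) if np.isfinite(p) else float("nan")
    return result


def regress_all(
    predictors: pd.DataFrame,
    covariates: pd.DataFrame,
    scores: pd.DataFrame,
    boxcox_responses: tuple[str, ...] | list[str] = (),
    criterion: str = "aic",
    alpha: float = 0.05,
    m: int = 7,
) -> list[RegressionResult]:
    """Run the selection for every score column, sharing one design matrix."""
    X = predictors.join(covariates, how="inner")
    if len(X) != len(predictors):
        raise ValueError("predictor and covariate tables index different subjects")
    results = []
    for response in scores.columns:
        y = scores.loc[X.index, response].to_numpy(dtype=float)
        results.append(
            regress_response(
                X, y, response=response,
                apply_boxcox=response in boxcox_responses,
                criterion=criterion, alpha=alpha, m=m,
            )
        )
    return results


def format_report(results: list[RegressionResult]) -> str:
    """Two-block text report: per-model statistics, then per-predictor p-values."""
    names = [r.response for r in results]
    lines = ["# Model-level statistics", "\t" + "\t".join(names)]

    def fmt(x: float | None) -> str:
        return "" if x is None or not np.isfinite(x) else f"{x:.5f}"

    def row(label: str, vals: list[float | None], symbols: bool = False) -> str:
        cells = []
        for v in vals:
            cell = fmt(v)
            if symbols and cell:
                cell += significance_symbol(float(v))  # type: ignore[arg-type]
            cells.append(cell)
        return label + "\t" + "\t".join(cells)

    lines.append(row("p_value", [r.model_pvalue for r in results], symbols=True))
    lines.append(row("corrected_p_value", [r.corrected_pvalue for r in results], symbols=True))
    lines.append(row("adjusted_R2", [r.adj_r2 for r in results]))
    lines.append("")
    lines.append("# Leave-one-out cross-validation")
    lines.append(row("p_value", [r.loo_pvalue for r in results], symbols=True))
    lines.append(row("corrected_p_value", [r.loo_corrected_pvalue for r in results], symbols=True))
    lines.append(row("adjusted_R2", [r.loo_adj_r2 for r in results]))
    lines.append("")
    lines.append("# Per-predictor p-values (selected models)")
    all_predictors: list[str] = []
    for r in results:
        for pred in r.predictors:
            if pred not in all_predictors:
                all_predictors.append(pred)
    lines.append("predictor\t" + "\t".join(names))
    for pred in all_predictors:
        cells = []
        for r in results:
            p = r.predictor_pvalues.get(pred)
            cells.append("" if p is None else f"{p:.4f}{significance_symbol(p)}")
        lines.append(pred + "\t" + "\t".join(cells))
    lines.append("")
    lines.append(f"symbols: * p<0.001, # p<0.01, † p<0.05, ‡ not significant")
    return "\n".join(lines) + "\n"
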