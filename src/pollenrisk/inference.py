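"""Regression stack: OLS with backward elimination, residual normality,
simple regression, and reduced major axis (RMA) regression.

Backward elimination follows the protocol of the field study this package
reproduces: starting from the full model, the single predictor with the
largest t-test p-value above alpha (default 0.05) is dropped and the model
refit, until every retained predictor is significant at alpha.  The
intercept is never a candidate.  Residual normality of each fitted model
is reported as a Shapiro-Wilk p-value.

RMA (geometric-mean) regression is used where both variables carry error:
the slope is sign(r) * SD(y)/SD(x), and the default p-value is the
two-sided t-test of Pearson r = 0 on n-2 degrees of freedom, with a seeded
permutation alternative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "RMAResult",
    "ols_fit",
    "backward_eliminate",
    "shapiro_wilk",
    "rma_regression",
    "simple_regression",
]

logger = logging.getLogger(__name__)

_SMALL_N_WARN = 15
_COND_LIMIT = 1e8


@dataclass(frozen=True)
class RegressionResult:
    """An OLS fit, optionally after backward elimination."""

    response: str
    terms: tuple[tuple[str, float, float], ...]  # (predictor, beta, p)
    intercept: float
    r_squared: float
    model_p: float                # overall F-test p (nan for empty model)
    residual_normality_p: float   # Shapiro-Wilk p on residuals
    n_obs: int
    elimination_trace: tuple[tuple[str, float], ...] = ()  # (dropped, exit p)
    std_errors: tuple[float, ...] = ()  # SE per retained term, same order

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(t[0] for t in self.terms)

    def term(self, name: str) -> tuple[float, float]:
        """(coefficient, p-value) of one retained predictor."""
        for t, beta, p in self.terms:
            if t == name:
                return beta, p
        raise KeyError(f"{name!r} not retained in model for {self.response!r}")


@dataclass(frozen=True)
class RMAResult:
    """Reduced major axis regression of y on x."""

    slope: float
    intercept: float
    r: float
    p_value: float
    n_obs: int


def _design(X: pd.DataFrame) -> pd.DataFrame:
    if X.shape[1] > 0:
        cond = np.linalg.cond(np.column_stack(
            [np.ones(len(X)), (X - X.mean()).to_numpy()]))
        if cond > _COND_LIMIT:
            corr = X.corr().abs()
            np.fill_diagonal(corr.to_numpy(), 0.0)
            i, j = np.unravel_index(np.argmax(corr.to_numpy()), corr.shape)
            raise ValueError(
                f"design matrix ill-conditioned (cond={cond:.2e}); "
                f"near-dependency between {corr.index[i]!r} and {corr.columns[j]!r}")
    return sm.add_constant(X, has_constant="add")


def ols_fit(y, X: pd.DataFrame, response: str = "y") -> RegressionResult:
    """Ordinary least squares of ``y`` on the columns of ``X``.

    Reports per-term t-test p-values, the overall F-test, R^2 and the
    Shapiro-Wilk p of the residuals.  Raises on an ill-conditioned design.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("y and X lengths differ")
    if len(y) <= X.shape[1] + 1:
        raise ValueError(f"need n > p + 1 (n={len(y)}, p={X.shape[1]})")
    if len(y) < _SMALL_N_WARN:
        logger.warning("small sample (n=%d): p-values rest on normality", len(y))
    fit = sm.OLS(y, _design(X)).fit()
    terms = tuple((c, float(fit.params[c]), float(fit.pvalues[c]))
                  for c in X.columns)
    if X.shape[1] > 0:
        model_p = float(fit.f_pvalue)
        r2 = float(fit.rsquared)
    else:
        model_p, r2 = float("nan"), 0.0
    resid = np.asarray(fit.resid)
    norm_p = shapiro_wilk(resid)[1] if np.ptp(resid) > 0 else float("nan")
    ses = tuple(float(fit.bse[c]) for c in X.columns)
    return RegressionResult(response, terms, float(fit.params["const"]),
                            r2, model_p, norm_p, len(y), std_errors=ses)


def backward_eliminate(y, X: pd.DataFrame, alpha: float = 0.05,
                       response: str = "y") -> RegressionResult:
    """Backward elimination at ``alpha``; drops worst predictor per round.

    Ties on the exit p-value are broken deterministically in favour of the
    later column.  The result is a fixed point: re-running elimination on
    the retained set changes nothing.  An all-noise design can legitimately
    end intercept-only (empty ``terms``).
    """
    kept = list(X.columns)
    trace: list[tuple[str, float]] = []
    while True:
        res = ols_fit(y, X[kept], response=response)
        if not kept:
            break
        pvals = {t: p for t, _, p in res.terms}
        worst = max(kept, key=lambda c: (pvals[c], kept.index(c)))
        if pvals[worst] <= alpha:
            break
        kept.remove(worst)
        trace.append((worst, pvals[worst]))
    return RegressionResult(res.response, res.terms, res.intercept,
                            res.r_squared, res.model_p,
                            res.residual_normality_p, res.n_obs, tuple(trace),
                            std_errors=res.std_errors)


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (Royston's algorithm via scipy)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3 or len(v) > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant vector")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns for n < 8 ties etc.
        w, p = scipy.stats.shapiro(v)
    return float(w), float(p)


def rma_regression(x, y, n_perm: int | None = None,
                   seed: int | None = None) -> RMAResult:
    """Reduced major axis regression of ``y`` on ``x``.

    slope = sign(r) * SD(y)/SD(x); intercept = mean(y) - slope * mean(x).
    The p-value tests r = 0: by default the two-sided t-test on n-2 df;
    with ``n_perm`` set, a seeded permutation test on |r| instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("RMA needs n >= 3 paired observations")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("RMA undefined when either variable has zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    if n_perm is None:
        p = _corr_p(r, n)
    else:
        rng = np.random.default_rng(seed)
        hits = sum(
            abs(float(np.corrcoef(x, rng.permutation(y))[0, 1])) >= abs(r) - 1e-12
            for _ in range(n_perm))
        p = (1 + hits) / (1 + n_perm)
    return RMAResult(float(slope), intercept, r, float(p), n)


def _corr_p(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return float(2 * scipy.stats.t.sf(abs(t), df=n - 2))


def simple_regression(x, y, response: str = "y",
                      predictor: str = "x") -> RegressionResult:
    """OLS with a single predictor."""
    x = np.asarray(x, dtype=float)
    X = pd.DataFrame({predictor: x})
    return ols_fit(y, X, response=response)
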