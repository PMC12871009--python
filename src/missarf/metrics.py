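"""Evaluation metrics for imputation quality and pooled inference.

NRMSE standardizes both tables by the per-feature mean and SD of the
original complete table and takes the Frobenius-norm RMSE over cells.
Multiple-imputation inference pools m logistic-regression fits with Rubin's
rules: pooled estimate = mean of estimates, total variance = mean
within-imputation variance plus (1 + 1/m) times the between-imputation
variance, with the classical degrees of freedom.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

import statsmodels.api as sm


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature mean and SD of the complete original table (sample SD)."""

    mu: np.ndarray
    sigma: np.ndarray

    @classmethod
    def from_table(cls, X: np.ndarray) -> "StandardizationParams":
        X = np.asarray(X, dtype=float)
        return cls(X.mean(axis=0), X.std(axis=0, ddof=1))


def nrmse(imputed, original, params: StandardizationParams | None = None, mask=None) -> float:
    """Standardized Frobenius RMSE between an imputed and the original table.

    Both tables are standardized by the original's per-feature mean/SD. With
    ``mask`` (boolean, True = scored cell) the average runs over the masked
    cells only — used by the benchmark to score the amputed cells, where the
    two tables can differ.
    """
    imputed = np.asarray(imputed, dtype=float)
    original = np.asarray(original, dtype=float)
    if imputed.shape != original.shape:
        raise ValueError("tables must have identical shape")
    if params is None:
        params = StandardizationParams.from_table(original)
    if np.any(params.sigma <= 0):
        bad = np.flatnonzero(params.sigma <= 0)
        raise ValueError(f"zero-SD column(s) {bad.tolist()} cannot be standardized")
    diff = (imputed - params.mu) / params.sigma - (original - params.mu) / params.sigma
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            return 0.0
        return float(np.sqrt(np.mean(diff[mask] ** 2)))
    return float(np.sqrt(np.mean(diff**2)))


def brier(predicted, y) -> float:
    """Mean squared distance between predicted probabilities and outcomes."""
    predicted = np.asarray(predicted, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.mean((predicted - y) ** 2))


def _ridge_logit(X, y, alpha=1e-4):
    """Newton logistic fit with a small L2 penalty; SEs from the penalized
    Hessian. Fallback for separation / non-convergence."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, q = X.shape
    beta = np.zeros(q)
    for _ in range(100):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-10)
        g = X.T @ (y - p) - alpha * beta
        H = (X.T * w) @ X + alpha * np.eye(q)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(p * (1 - p), 1e-10)
    H = (X.T * w) @ X + alpha * np.eye(q)
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, se


def fit_logistic(X, y):
    """Maximum-likelihood logistic regression with intercept.

    Returns (coef, se, flagged) for the p features (intercept dropped).
    Perfect separation or non-convergence falls back to a lightly ridge-
    penalized fit and sets ``flagged``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        coef = np.asarray(res.params)
        se = np.asarray(res.bse)
        ok = bool(res.mle_retvals.get("converged", True)) and np.all(np.isfinite(se))
        ok = ok and np.all(se < 1e3)
        if ok:
            return coef[1:], se[1:], False
    except Exception:
        pass
    coef, se = _ridge_logit(Xc, y)
    return coef[1:], se[1:], True


def predict_logistic(X, coef, intercept) -> np.ndarray:
    eta = np.clip(intercept + np.asarray(X, dtype=float) @ coef, -30, 30)
    return 1.0 / (1.0 + np.exp(-eta))


def downstream_brier(train_X, y_train, test_X, y_test) -> float:
    """Fit logistic regression on the imputed training table, predict on the
    imputed test table, return the Brier score against the true outcomes."""
    train_X = np.asarray(train_X, dtype=float)
    Xc = sm.add_constant(train_X, has_constant="add")
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = sm.Logit(np.asarray(y_train, dtype=float), Xc).fit(disp=0, maxiter=200)
        params = np.asarray(res.params)
        if not np.all(np.isfinite(params)):
            raise ValueError
    except Exception:
        params, _ = _ridge_logit(Xc, np.asarray(y_train, dtype=float))
    pred = predict_logistic(test_X, params[1:], params[0])
    return brier(pred, y_test)


@dataclass
class PooledEstimate:
    """Rubin-pooled coefficients with standard errors and CIs per feature."""

    beta_bar: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    df: np.ndarray
    flagged: bool = False


def rubin_pool(estimates, ses, alpha: float = 0.05) -> PooledEstimate:
    """Pool m per-imputation estimates (rows) by Rubin's rules.

    W = mean squared SE, B = between-imputation variance (divisor m-1),
    total = W + (1 + 1/m) B, df = (m-1)(1 + W/((1+1/m)B))^2. With B = 0 (or
    m = 1, flagged) the normal quantile is used.
    """
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    ses = np.atleast_2d(np.asarray(ses, dtype=float))
    m = est.shape[0]
    beta_bar = est.mean(axis=0)
    if m == 1:
        se = ses[0]
        z = stats.norm.ppf(1 - alpha / 2)
        return PooledEstimate(
            beta_bar, se, beta_bar - z * se, beta_bar + z * se,
            np.full(beta_bar.shape, np.inf), flagged=True,
        )
    W = np.mean(ses**2, axis=0)
    B = est.var(axis=0, ddof=1)
    total = W + (1 + 1 / m) * B
    se = np.sqrt(total)
    with np.errstate(divide="ignore"):
        df = (m - 1) * (1 + W / ((1 + 1 / m) * B)) ** 2
    q = np.where(np.isfinite(df), stats.t.ppf(1 - alpha / 2, np.maximum(df, 1e-9)),
                 stats.norm.ppf(1 - alpha / 2))
    # degenerate between-variance: fall back to the normal quantile
    q = np.where(B > 0, q, stats.norm.ppf(1 - alpha / 2))
    return PooledEstimate(beta_bar, se, beta_bar - q * se, beta_bar + q * se, df)


def coverage_rate(cis, beta_true) -> float:
    """Fraction of (a, b) intervals with a < beta_true < b."""
    cis = np.asarray(cis, dtype=float)
    a, b = cis[:, 0], cis[:, 1]
    return float(np.mean((a < beta_true) & (beta_true < b)))


def avg_ci_width(cis) -> float:
    """Mean difference between upper and lower CI bounds."""
    cis = np.asarray(cis, dtype=float)
    return float(np.mean(cis[:, 1] - cis[:, 0]))


def coef_rmse(estimates, beta_true) -> float:
    """Root mean squared error of replicate coefficient estimates."""
    estimates = np.asarray(estimates, dtype=float)
    return float(np.sqrt(np.mean((estimates - beta_true) ** 2)))
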