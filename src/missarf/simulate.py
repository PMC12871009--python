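"""Gaussian-copula benchmark data, amputation patterns, and the study grid.

Feature tables are drawn from a Gaussian copula with Toeplitz latent
correlation 0.5^|i-j| and one of five marginals (standard normal,
Bernoulli(0.5), Poisson(2), Gamma(shape 2, rate 0.5), Uniform(-1, 1)).
A binary outcome follows a logistic model with equidistant coefficients
beta = (-0.5, ..., 0.5) on the features (linear effect) or their squares.

Missingness is introduced in half of the features (the 1st, 3rd, ... columns)
with an exact count of round(rate * n) cells per target column: MCAR deletes
uniformly at random; MAR and MNAR delete within one randomly chosen side of
a median split — of the adjacent fully observed control column for MAR, of
the target column itself for MNAR.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cholesky, toeplitz
from scipy.special import expit, ndtr

from . import metrics as _metrics
from .dataset import Dataset, Feature, Schema
from .forest import ARFConfig
from .imputation import (
    ImputeConfig,
    impute_median,
    impute_missarf_multiple,
    impute_missarf_single,
    impute_random,
)

MARGINALS = ("normal", "binary", "poisson", "gamma", "uniform")
PATTERNS = ("MCAR", "MAR", "MNAR")
EFFECTS = ("linear", "squared")


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of the benchmark grid."""

    marginal: str = "normal"
    n: int = 500
    p: int = 4
    effect: str = "linear"
    pattern: str = "MCAR"
    rate: float = 0.2

    def __post_init__(self) -> None:
        if self.marginal not in MARGINALS:
            raise ValueError(f"unknown marginal {self.marginal!r}")
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if not (0 < self.rate <= 0.5):
            raise ValueError("rate must lie in (0, 0.5]")
        if self.n < 1 or self.p < 2:
            raise ValueError("need n >= 1 and p >= 2")

    @property
    def beta(self) -> np.ndarray:
        return make_beta(self.p)

    def key(self) -> str:
        return f"{self.marginal}|{self.n}|{self.p}|{self.effect}|{self.pattern}|{self.rate}"


def make_beta(p: int) -> np.ndarray:
    """Equidistant effect sizes from -0.5 to 0.5."""
    return np.linspace(-0.5, 0.5, p)


def _schema_for(marginal: str, p: int) -> Schema:
    names = [f"x{j+1}" for j in range(p)]
    if marginal == "binary":
        feats = [Feature(nm, "categorical", ("0", "1")) for nm in names]
    else:
        feats = [Feature(nm, "continuous") for nm in names]
    return Schema(feats)


def gen_copula_features(marginal: str, n: int, p: int, rng) -> Dataset:
    """Draw an n×p table from the Gaussian copula with the given marginal."""
    corr = toeplitz(0.5 ** np.arange(p))
    L = cholesky(corr, lower=True)
    Z = rng.standard_normal((n, p)) @ L.T
    U = ndtr(Z)
    if marginal == "normal":
        X = Z
    elif marginal == "binary":
        X = (U > 0.5).astype(float)
    elif marginal == "poisson":
        X = stats.poisson.ppf(U, mu=2.0)
    elif marginal == "gamma":
        X = stats.gamma.ppf(U, a=2.0, scale=2.0)  # rate 0.5
    elif marginal == "uniform":
        X = 2.0 * U - 1.0
    else:
        raise ValueError(marginal)
    return Dataset(X, _schema_for(marginal, p))


def gen_outcome(X, effect: str, beta, rng) -> np.ndarray:
    """Bernoulli outcomes with logistic probabilities on X or X^2."""
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    lin = X @ beta if effect == "linear" else (X**2) @ beta
    pi = expit(lin)
    return (rng.random(X.shape[0]) < pi).astype(np.int64)


def default_target_columns(p: int) -> list[int]:
    """The 1st, 3rd, ... columns (0-based even indices) receive missingness."""
    return list(range(0, p, 2))


def _control_column(j: int, p: int) -> int:
    return j + 1 if j + 1 < p else j - 1


def ampute(X, pattern: str, rate: float, rng, target_cols=None):
    """Delete exactly round(rate*n) cells per target column.

    Returns (amputed array with NaNs, boolean mask of deleted cells). For
    MAR/MNAR, rows at the median count as the lower side; if the upper side
    is chosen and is too small due to ties, deletions spill into rows tied
    at the median.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}")
    if target_cols is None:
        target_cols = default_target_columns(p)
    k = int(np.floor(rate * n + 0.5))
    out = X.copy()
    mask = np.zeros((n, p), dtype=bool)
    if k == 0:
        return out, mask
    for j in target_cols:
        if pattern == "MCAR":
            rows = rng.choice(n, size=k, replace=False)
        else:
            ref = X[:, j] if pattern == "MNAR" else X[:, _control_column(j, p)]
            med = np.median(ref)
            lower_side = rng.random() < 0.5
            if lower_side:
                pool = np.flatnonzero(ref <= med)
                if pool.size < k:
                    raise ValueError("not enough rows on the chosen median side")
                rows = rng.choice(pool, size=k, replace=False)
            else:
                upper = np.flatnonzero(ref > med)
                tied = np.flatnonzero(ref == med)
                if upper.size >= k:
                    rows = rng.choice(upper, size=k, replace=False)
                elif upper.size + tied.size >= k:
                    spill = rng.choice(tied, size=k - upper.size, replace=False)
                    rows = np.concatenate([upper, spill])
                else:
                    raise ValueError("not enough rows on the chosen median side")
        out[rows, j] = np.nan
        mask[rows, j] = True
    return out, mask


@dataclass
class SimulatedStudy:
    """Complete and amputed train/test tables for one replicate."""

    config: SimulationConfig
    train: Dataset
    test: Dataset
    y_train: np.ndarray
    y_test: np.ndarray
    train_amputed: Dataset
    test_amputed: Dataset
    train_mask: np.ndarray
    test_mask: np.ndarray


def simulate_study(cfg: SimulationConfig, rng) -> SimulatedStudy:
    train = gen_copula_features(cfg.marginal, cfg.n, cfg.p, rng)
    test = gen_copula_features(cfg.marginal, cfg.n, cfg.p, rng)
    beta = cfg.beta
    y_train = gen_outcome(train.values, cfg.effect, beta, rng)
    y_test = gen_outcome(test.values, cfg.effect, beta, rng)
    Xa_train, m_train = ampute(train.values, cfg.pattern, cfg.rate, rng)
    Xa_test, m_test = ampute(test.values, cfg.pattern, cfg.rate, rng)
    return SimulatedStudy(
        config=cfg,
        train=train,
        test=test,
        y_train=y_train,
        y_test=y_test,
        train_amputed=Dataset(Xa_train, train.schema),
        test_amputed=Dataset(Xa_test, test.schema),
        train_mask=m_train,
        test_mask=m_test,
    )


# ---------------------------------------------------------------------------
# imputer plug-in interface: fn(data, m_or_None, seed) -> Dataset | [Dataset]


def _missarf_imputer(arf: ARFConfig | None = None) -> Callable:
    def fn(data: Dataset, m, seed):
        base = arf or ARFConfig()
        if m is None:
            return impute_missarf_single(data, ImputeConfig(seed=seed, arf=base))
        return list(impute_missarf_multiple(data, ImputeConfig(m=m, seed=seed, arf=base)))

    fn.supports_multiple = True
    return fn


def _random_imputer(data: Dataset, m, seed):
    res = impute_random(data, m=m or 1, seed=seed)
    return res[0] if m is None else list(res)


_random_imputer.supports_multiple = True


def _median_imputer(data: Dataset, m, seed):
    if m is not None:
        raise ValueError("median imputation cannot produce multiple datasets")
    return impute_median(data)


_median_imputer.supports_multiple = False


def builtin_imputers(arf: ARFConfig | None = None) -> dict[str, Callable]:
    return {
        "missarf": _missarf_imputer(arf),
        "random": _random_imputer,
        "median": _median_imputer,
    }


def _crc(s: str) -> int:
    return zlib.crc32(s.encode())


def replicate_seed(master_seed: int, cfg: SimulationConfig, k: int, tag: str = "") -> np.random.SeedSequence:
    """Deterministic substream per (setting, replicate, consumer)."""
    return np.random.SeedSequence(
        [int(master_seed), _crc(cfg.key()), int(k), _crc(tag)]
    )


def run_replicate(
    cfg: SimulationConfig,
    k: int,
    master_seed: int,
    imputers: dict[str, Callable],
    modes=("single", "multiple"),
    m: int = 20,
    alpha: float = 0.05,
):
    """Simulate, ampute, impute and score one replicate; returns result rows."""
    rng_sim = np.random.default_rng(replicate_seed(master_seed, cfg, k, "sim"))
    study = simulate_study(cfg, rng_sim)
    params = _metrics.StandardizationParams.from_table(study.train.values)
    beta_true = cfg.beta
    rows = []

    def emit(imputer, mode, metric, value, feature=None, flagged=False):
        rows.append(
            {
                "marginal": cfg.marginal,
                "n": cfg.n,
                "p": cfg.p,
                "effect": cfg.effect,
                "pattern": cfg.pattern,
                "rate": cfg.rate,
                "replicate": k,
                "imputer": imputer,
                "mode": mode,
                "metric": metric,
                "feature": "" if feature is None else f"x{feature+1}",
                "value": value,
                "flagged": flagged,
            }
        )

    for name, fn in imputers.items():
        seed_i = int(
            replicate_seed(master_seed, cfg, k, f"imp:{name}").generate_state(1)[0]
            % (2**31)
        )
        if "single" in modes:
            try:
                imp_train = fn(study.train_amputed, None, seed_i)
                imp_test = fn(study.test_amputed, None, seed_i + 1)
                emit(
                    name,
                    "single",
                    "nrmse",
                    _metrics.nrmse(
                        imp_train.values, study.train.values, params, study.train_mask
                    ),
                )
                emit(
                    name,
                    "single",
                    "brier",
                    _metrics.downstream_brier(
                        imp_train.values, study.y_train, imp_test.values, study.y_test
                    ),
                )
            except Exception as exc:  # keep the grid going
                emit(name, "single", "error", np.nan, flagged=True)
        if "multiple" in modes and getattr(fn, "supports_multiple", True):
            try:
                completions = fn(study.train_amputed, m, seed_i + 2)
                ests, ses = [], []
                any_flag = False
                for d in completions:
                    coef, se, fl = _metrics.fit_logistic(d.values, study.y_train)
                    ests.append(coef)
                    ses.append(se)
                    any_flag = any_flag or fl
                pooled = _metrics.rubin_pool(np.array(ests), np.array(ses), alpha)
                for j in range(cfg.p):
                    covered = float(
                        pooled.ci_lower[j] < beta_true[j] < pooled.ci_upper[j]
                    )
                    emit(name, "multiple", "covered", covered, feature=j, flagged=any_flag)
                    emit(
                        name,
                        "multiple",
                        "ci_width",
                        float(pooled.ci_upper[j] - pooled.ci_lower[j]),
                        feature=j,
                        flagged=any_flag,
                    )
                    emit(
                        name,
                        "multiple",
                        "beta_err",
                        float(pooled.beta_bar[j] - beta_true[j]),
                        feature=j,
                        flagged=any_flag,
                    )
            except Exception:
                emit(name, "multiple", "error", np.nan, flagged=True)
    return rows


def run_grid(
    settings,
    K: int,
    master_seed: int,
    imputers: dict[str, Callable] | None = None,
    modes=("single", "multiple"),
    m: int = 20,
    progress: bool = False,
    skip: set | None = None,
) -> pd.DataFrame:
    """Run the replicated benchmark grid; returns a long-format table.

    ``skip`` is a set of (setting_key, replicate) pairs already completed
    (used to resume an interrupted run). Seeds are derived per (setting,
    replicate, imputer), so results do not depend on iteration order.
    """
    if imputers is None:
        imputers = builtin_imputers()
    all_rows = []
    for cfg in settings:
        for k in range(K):
            if skip and (cfg.key(), k) in skip:
                continue
            all_rows.extend(
                run_replicate(cfg, k, master_seed, imputers, modes=modes, m=m)
            )
            if progress:
                print(f"done {cfg.key()} replicate {k}", flush=True)
    cols = [
        "marginal", "n", "p", "effect", "pattern", "rate",
        "replicate", "imputer", "mode", "metric", "feature", "value", "flagged",
    ]
    return pd.DataFrame(all_rows, columns=cols)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a grid result to per-imputer summary statistics.

    Single imputation: per-setting replicate means of NRMSE / Brier, then
    mean (SD) across settings with equal setting weight. Multiple
    imputation: per-(setting, feature) coverage rate, mean CI width and
    coefficient RMSE across replicates, then median (IQR) across
    setting-feature cells.
    """
    setting_cols = ["marginal", "n", "p", "effect", "pattern", "rate"]
    out = []
    for imputer, df in results.groupby("imputer"):
        row = {"imputer": imputer}
        for metric in ("nrmse", "brier"):
            sub = df[(df.metric == metric) & ~df.flagged]
            if len(sub):
                per_setting = sub.groupby(setting_cols)["value"].mean()
                row[f"{metric}_mean"] = per_setting.mean()
                row[f"{metric}_sd"] = per_setting.std(ddof=1) if len(per_setting) > 1 else 0.0
        cov = df[df.metric == "covered"]
        if len(cov):
            per_cell = cov.groupby(setting_cols + ["feature"])["value"].mean() * 100
            row["coverage_median"] = per_cell.median()
            row["coverage_iqr"] = per_cell.quantile(0.75) - per_cell.quantile(0.25)
        wid = df[df.metric == "ci_width"]
        if len(wid):
            per_cell = wid.groupby(setting_cols + ["feature"])["value"].mean()
            row["ci_width_median"] = per_cell.median()
            row["ci_width_iqr"] = per_cell.quantile(0.75) - per_cell.quantile(0.25)
        err = df[df.metric == "beta_err"]
        if len(err):
            per_cell = err.groupby(setting_cols + ["feature"])["value"].apply(
                lambda e: float(np.sqrt(np.mean(np.square(e))))
            )
            row["coef_rmse_median"] = per_cell.median()
            row["coef_rmse_iqr"] = per_cell.quantile(0.75) - per_cell.quantile(0.25)
        out.append(row)
    return pd.DataFrame(out)
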