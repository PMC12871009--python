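"""Conditioning the leaf mixture on observed values.

Given evidence x_C on the observed index set C, each leaf weight is rescaled
by the leaf's density of the evidence and renormalized,

    w~_l  proportional to  omega_l * prod_{j in C} p_lj(x_j),

computed in log space with log-sum-exp. Leaves whose bounds exclude any
observed value receive exactly zero weight. The conditional density of the
missing features is then the w~-weighted mixture of the per-leaf products,
and imputations are drawn by sampling one leaf per completion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .dataset import Dataset
from .leaves import DensityModel, _sample_features


@dataclass(frozen=True)
class Evidence:
    """A partial observation: observed indices with values, missing indices."""

    observed: tuple[int, ...]
    values: tuple[float, ...]  # encoded (codes for categorical)
    missing: tuple[int, ...]
    row_id: int | None = None

    def __post_init__(self) -> None:
        if len(self.observed) != len(self.values):
            raise ValueError("observed indices and values differ in length")
        if set(self.observed) & set(self.missing):
            raise ValueError("observed and missing sets overlap")
        if any(np.isnan(v) for v in self.values):
            raise ValueError("observed values cannot be missing markers")

    @classmethod
    def from_row(cls, row, row_id: int | None = None) -> "Evidence":
        row = np.asarray(row, dtype=np.float64).ravel()
        miss = np.isnan(row)
        return cls(
            observed=tuple(np.flatnonzero(~miss)),
            values=tuple(row[~miss]),
            missing=tuple(np.flatnonzero(miss)),
            row_id=row_id,
        )


@dataclass
class AdjustedWeights:
    """Per-leaf conditional weights w~ plus the evidence log-density."""

    weights: np.ndarray  # (L,) sums to 1
    log_evidence: float  # log p_ARF(x_C)
    fallback: bool = False  # True when no leaf was compatible


def adjust_weights(model: DensityModel, ev: Evidence) -> AdjustedWeights:
    """Condition the leaf weights on the evidence (log-space, normalized).

    If no leaf is compatible with the evidence (possible for values outside
    every leaf's bounds) the unadjusted weights are returned with
    ``fallback=True`` so imputation can still produce a value.
    """
    with np.errstate(divide="ignore"):
        logw = np.where(model.weights > 0, np.log(model.weights), -np.inf)
    for j, x in zip(ev.observed, ev.values):
        logw = logw + model.leaf_log_density(j, x)
    if np.all(np.isneginf(logw)):
        return AdjustedWeights(model.weights.copy(), -np.inf, fallback=True)
    norm = logsumexp(logw)
    return AdjustedWeights(np.exp(logw - norm), float(norm), fallback=False)


def conditional_density(model: DensityModel, ev: Evidence, x_missing) -> float:
    """w~-weighted mixture density of the missing features at ``x_missing``."""
    adj = adjust_weights(model, ev)
    x_missing = np.atleast_1d(np.asarray(x_missing, dtype=np.float64))
    if len(ev.missing) != x_missing.size:
        raise ValueError("x_missing length must match the missing index set")
    with np.errstate(divide="ignore"):
        logw = np.where(adj.weights > 0, np.log(adj.weights), -np.inf)
    for j, x in zip(ev.missing, x_missing):
        logw = logw + model.leaf_log_density(j, x)
    if np.all(np.isneginf(logw)):
        return 0.0
    return float(np.exp(logsumexp(logw)))


def sample_conditional(model: DensityModel, ev: Evidence, k: int, rng) -> np.ndarray:
    """k completions of the row: a fresh leaf ~ w~ is drawn per completion,
    then every missing feature independently from that leaf; observed cells
    pass through unchanged."""
    p = len(model.schema)
    out = np.empty((k, p))
    for j, x in zip(ev.observed, ev.values):
        out[:, j] = x
    if not ev.missing:
        return out
    adj = adjust_weights(model, ev)
    leaves = rng.choice(model.n_leaves, size=k, p=adj.weights)
    vals = _sample_features(model, leaves, list(ev.missing), rng)
    for c, j in enumerate(ev.missing):
        out[:, j] = vals[:, c]
    return out


def conditional_expectation(model: DensityModel, ev: Evidence, j: int) -> float:
    """E[X_j | X_C = x_C] = sum_l w~_l mu_lj with empirical leaf means."""
    if model.schema.is_categorical[j]:
        raise ValueError("conditional_expectation requires a continuous feature")
    if j not in ev.missing:
        raise ValueError("feature j must be missing in the evidence")
    adj = adjust_weights(model, ev)
    return float(adj.weights @ model.emp_mean[:, j])


def conditional_mode(model: DensityModel, ev: Evidence, j: int):
    """Most frequent category over the selected leaves, weighted by w~.

    Returns the level code; ties break toward the earlier declared level.
    """
    if not model.schema.is_categorical[j]:
        raise ValueError("conditional_mode requires a categorical feature")
    if j not in ev.missing:
        raise ValueError("feature j must be missing in the evidence")
    adj = adjust_weights(model, ev)
    scores = adj.weights @ model.cat_probs[j]
    return int(np.argmax(scores))
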