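"""Leaf harvesting and per-leaf univariate densities.

Every leaf of every tree is a hyperrectangle: per continuous feature a
half-open interval (lo, hi] plus an NA-admissibility flag, per categorical
feature an admissible level set (with NA as its own pseudo-level). Leaves
carry weights omega_l = n_tl / (T * n_t): the fraction of real training rows
routed to the leaf, averaged over trees, so the weights over the whole
forest sum to one.

Within a leaf, features are modelled as mutually independent: continuous
features get a maximum-likelihood truncated Gaussian on the leaf interval,
categorical ones a multinomial over the admissible levels. The forest-wide
density is the omega-weighted mixture of the per-leaf products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from . import _truncnorm
from .dataset import Dataset
from .forest import ForestModel, _NA_LEVEL


@dataclass
class DensityModel:
    """All leaves of a forest, flattened, with fitted distributions."""

    schema: object
    num_trees: int
    tree_index: np.ndarray  # (L,)
    weights: np.ndarray  # (L,) sums to 1
    n_tl: np.ndarray  # (L,) real-row counts
    lo: np.ndarray  # (L, p) -inf for categorical columns
    hi: np.ndarray  # (L, p)
    na_admitted: np.ndarray  # (L, p) bool
    cat_allowed: dict  # j -> (L, k_j) bool
    # fitted parameters (set by fit_leaf_distributions)
    mu: np.ndarray | None = None  # (L, p)
    sigma: np.ndarray | None = None
    logz: np.ndarray | None = None  # log truncation mass
    emp_mean: np.ndarray | None = None  # empirical leaf means
    cat_probs: dict = field(default_factory=dict)  # j -> (L, k_j)
    global_mean: np.ndarray | None = None
    global_sd: np.ndarray | None = None
    global_cat_probs: dict = field(default_factory=dict)
    fitted: bool = False
    # private: per-tree leaf assignment of the real training rows
    _assign: np.ndarray | None = None
    _leaf_offset: np.ndarray | None = None

    @property
    def n_leaves(self) -> int:
        return self.weights.size

    def empty_interval(self, j: int) -> np.ndarray:
        """Leaves whose interval for feature j admits no real value."""
        return self.lo[:, j] >= self.hi[:, j]

    def leaf_log_density(self, j: int, value: float) -> np.ndarray:
        """log p_lj(value) for every leaf (−inf outside the leaf bounds)."""
        if not self.fitted:
            raise RuntimeError("call fit_leaf_distributions first")
        if self.schema.is_categorical[j]:
            code = int(value)
            with np.errstate(divide="ignore"):
                return np.log(self.cat_probs[j][:, code])
        return _truncnorm.logpdf(
            value,
            self.mu[:, j],
            self.sigma[:, j],
            self.lo[:, j],
            self.hi[:, j],
            self.logz[:, j],
        )


def extract_leaves(forest: ForestModel, real: Dataset) -> DensityModel:
    """Flatten the forest's leaves into bound arrays and leaf weights.

    Bounds are the conjunction of the split constraints on each root-to-leaf
    path; unconstrained continuous features keep (−inf, +inf), unconstrained
    categorical ones the full level set. ``n_tl`` counts the real rows routed
    to each leaf, so weights are n_tl / (T * n).
    """
    schema = real.schema
    p = real.p
    T = forest.num_trees
    is_cat = schema.is_categorical
    k_of = {j: schema.n_levels(j) for j in np.flatnonzero(is_cat)}

    n_leaves_per_tree = [t.n_leaves for t in forest.trees]
    offset = np.concatenate([[0], np.cumsum(n_leaves_per_tree)])
    L = int(offset[-1])

    lo = np.full((L, p), -np.inf)
    hi = np.full((L, p), np.inf)
    na_adm = np.ones((L, p), dtype=bool)
    cat_allowed = {j: np.ones((L, k), dtype=bool) for j, k in k_of.items()}
    tree_index = np.empty(L, dtype=np.int64)

    for t, tree in enumerate(forest.trees):
        base = offset[t]
        # DFS carrying the accumulated constraints
        stack = [(0, {}, {}, {})]  # node, {j: (lo, hi)}, {j: set}, {j: na}
        while stack:
            node, ivals, sets, nas = stack.pop()
            if tree.feature[node] < 0:
                g = base + tree.leaf_id[node]
                tree_index[g] = t
                for j, (a, b) in ivals.items():
                    lo[g, j], hi[g, j] = a, b
                for j, allowed in sets.items():
                    cat_allowed[j][g] = False
                    cat_allowed[j][g, sorted(allowed)] = True
                for j, adm in nas.items():
                    na_adm[g, j] = adm
                continue
            j = tree.feature[node]
            nl = dict(nas)
            nl[j] = nas.get(j, True) and tree.na_left[node]
            nr = dict(nas)
            nr[j] = nas.get(j, True) and not tree.na_left[node]
            if tree.left_codes[node] is None:
                s = tree.threshold[node]
                a, b = ivals.get(j, (-np.inf, np.inf))
                l_iv = dict(ivals)
                l_iv[j] = (a, min(b, s))
                r_iv = dict(ivals)
                r_iv[j] = (max(a, s), b)
                stack.append((tree.left[node], l_iv, sets, nl))
                stack.append((tree.right[node], r_iv, sets, nr))
            else:
                full = sets.get(j, set(range(k_of[j])))
                l_sets = dict(sets)
                l_sets[j] = full & tree.left_codes[node]
                r_sets = dict(sets)
                r_sets[j] = full - tree.left_codes[node]
                stack.append((tree.left[node], ivals, l_sets, nl))
                stack.append((tree.right[node], ivals, r_sets, nr))

    assign = forest.route_all(real.values)  # (T, n)
    n_tl = np.zeros(L, dtype=np.int64)
    for t in range(T):
        np.add.at(n_tl, offset[t] + assign[t], 1)
    weights = n_tl / (T * real.n)

    return DensityModel(
        schema=schema,
        num_trees=T,
        tree_index=tree_index,
        weights=weights,
        n_tl=n_tl,
        lo=lo,
        hi=hi,
        na_admitted=na_adm,
        cat_allowed=cat_allowed,
        _assign=assign,
        _leaf_offset=offset[:-1],
    )


def fit_leaf_distributions(
    model: DensityModel, real: Dataset, cat_alpha: float = 0.0
) -> DensityModel:
    """Fit per-leaf univariate distributions from the real rows in each leaf.

    Continuous features: truncated-Gaussian MLE on the leaf interval from the
    leaf's real non-missing values (closed form when the interval is
    unbounded; sigma floored at 1e-6 of the feature's marginal SD). Leaves
    with no real non-missing value of a feature inherit the global marginal
    estimate truncated to the leaf bounds. Categorical features: relative
    level frequencies with pseudo-count ``cat_alpha``.
    """
    if model._assign is None:
        raise RuntimeError("model lacks the leaf assignment of the real rows")
    X = real.values
    n, p = X.shape
    L = model.n_leaves
    T = model.num_trees
    offset = model._leaf_offset
    is_cat = model.schema.is_categorical

    mu = np.full((L, p), np.nan)
    sigma = np.full((L, p), np.nan)
    logz = np.full((L, p), 0.0)
    emp_mean = np.full((L, p), np.nan)
    g_mean = np.full(p, np.nan)
    g_sd = np.full(p, np.nan)

    for j in range(p):
        col = X[:, j]
        obs = ~np.isnan(col)
        vals = col[obs]
        if is_cat[j]:
            k = model.schema.n_levels(j)
            counts = np.bincount(vals.astype(np.int64), minlength=k).astype(float)
            gp = counts / counts.sum() if counts.sum() > 0 else np.full(k, 1.0 / k)
            model.global_cat_probs[j] = gp
            cnt = np.zeros((L, k))
            for t in range(T):
                g = offset[t] + model._assign[t][obs]
                np.add.at(cnt, (g, vals.astype(np.int64)), 1.0)
            cnt += cat_alpha
            allowed = model.cat_allowed[j]
            cnt = np.where(allowed, cnt, 0.0)
            tot = cnt.sum(axis=1, keepdims=True)
            probs = np.divide(cnt, tot, out=np.zeros_like(cnt), where=tot > 0)
            # leaves with no mass inherit the global frequencies restricted
            # to their admissible levels (or unrestricted if that is empty)
            empty = tot[:, 0] <= 0
            if empty.any():
                fallback = np.where(allowed[empty], gp[None, :], 0.0)
                fs = fallback.sum(axis=1, keepdims=True)
                fallback = np.where(fs > 0, fallback / np.maximum(fs, 1e-300), gp[None, :])
                probs[empty] = fallback
            model.cat_probs[j] = probs
            continue

        g_mean[j] = vals.mean() if vals.size else 0.0
        g_sd[j] = vals.std(ddof=1) if vals.size > 1 else 0.0
        floor = 1e-6 * g_sd[j] if g_sd[j] > 0 else 1e-9

        cnt = np.zeros(L)
        sm = np.zeros(L)
        sq = np.zeros(L)
        for t in range(T):
            g = offset[t] + model._assign[t][obs]
            np.add.at(cnt, g, 1.0)
            np.add.at(sm, g, vals)
            np.add.at(sq, g, vals * vals)
        with np.errstate(invalid="ignore"):
            m = np.where(cnt > 0, sm / np.maximum(cnt, 1), g_mean[j])
            v = np.where(cnt > 0, sq / np.maximum(cnt, 1) - m * m, g_sd[j] ** 2)
        v = np.maximum(v, 0.0)
        emp_mean[:, j] = m
        mu_j, sig_j = _truncnorm.mle(m, v, model.lo[:, j], model.hi[:, j], floor)
        # a single observation cannot support a variance estimate: keep its
        # mean but inherit the global marginal SD, else the floored sigma
        # turns the leaf into a delta spike at the row's own observed value
        # and self-conditioning hijacks the adjusted weights
        single = cnt == 1
        sig_j = np.where(single, max(g_sd[j], floor), sig_j)
        # zero-data leaves: global marginal truncated to the leaf bounds
        none = cnt == 0
        mu_j = np.where(none, g_mean[j], mu_j)
        sig_j = np.where(none, max(g_sd[j], floor), sig_j)
        mu[:, j] = mu_j
        sigma[:, j] = np.maximum(sig_j, floor)
        logz[:, j] = _truncnorm.log_mass(
            mu[:, j], sigma[:, j], model.lo[:, j], model.hi[:, j]
        )

    model.mu = mu
    model.sigma = sigma
    model.logz = logz
    model.emp_mean = emp_mean
    model.global_mean = g_mean
    model.global_sd = g_sd
    model.fitted = True
    return model


def fit_density_model(
    forest: ForestModel, real: Dataset, cat_alpha: float = 0.0
) -> DensityModel:
    """Convenience: extract leaves then fit their distributions."""
    return fit_leaf_distributions(extract_leaves(forest, real), real, cat_alpha)


def density(model: DensityModel, x) -> float:
    """Mixture density sum_l omega_l prod_j p_lj(x_j) at a complete row."""
    x = np.asarray(x, dtype=np.float64).ravel()
    if np.isnan(x).any():
        raise ValueError("density requires a complete row")
    with np.errstate(divide="ignore"):
        logw = np.where(model.weights > 0, np.log(model.weights), -np.inf)
    for j in range(x.size):
        logw = logw + model.leaf_log_density(j, x[j])
    if np.all(np.isneginf(logw)):
        return 0.0
    return float(np.exp(logsumexp(logw)))


def _sample_features(model: DensityModel, leaves: np.ndarray, cols, rng) -> np.ndarray:
    """Draw the features in ``cols`` independently from the leaf
    distributions of the given (per-row) leaves."""
    k = leaves.size
    out = np.empty((k, len(cols)))
    for c, j in enumerate(cols):
        if model.schema.is_categorical[j]:
            probs = model.cat_probs[j][leaves]
            cp = np.cumsum(probs, axis=1)
            cp[:, -1] = 1.0
            u = rng.random(k)
            out[:, c] = (u[:, None] > cp).sum(axis=1)
        else:
            lo = model.lo[leaves, j]
            hi = model.hi[leaves, j]
            mu = model.mu[leaves, j]
            sg = model.sigma[leaves, j]
            # degenerate (NA-only) intervals: fall back to the untruncated
            # leaf Gaussian so imputations are never missing
            empty = lo >= hi
            lo = np.where(empty, -np.inf, lo)
            hi = np.where(empty, np.inf, hi)
            out[:, c] = _truncnorm.sample(mu, sg, lo, hi, rng.random(k))
    return out


def sample_unconditional(model: DensityModel, k: int, rng) -> Dataset:
    """Generate k rows: draw leaves ~ omega, then features independently."""
    if not model.fitted:
        raise RuntimeError("call fit_leaf_distributions first")
    leaves = rng.choice(model.n_leaves, size=k, p=model.weights)
    vals = _sample_features(model, leaves, list(range(len(model.schema))), rng)
    return Dataset(vals, model.schema)
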