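"""Discriminator forest: synthetic sampling, MIA splits, adversarial loop."""

import numpy as np
import pytest
from scipy import stats

from missarf.dataset import Dataset, Feature, Schema
from missarf.forest import (
    ARFConfig,
    best_mia_split,
    fit_discriminator,
    sample_leafwise_synthetic,
    sample_naive_synthetic,
    train_arf,
)
from helpers import continuous_schema, make_two_cluster_data


# ---------------------------------------------------------------- naive synth


def test_naive_synth_constant_column_stays_constant():
    data = Dataset(np.full((50, 1), 3.5), continuous_schema(1))
    out = sample_naive_synthetic(data, np.random.default_rng(0))
    assert np.all(out.values == 3.5)


def test_naive_synth_values_come_from_original_column():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(40, 3))
    X[rng.random((40, 3)) < 0.3] = np.nan
    data = Dataset(X, continuous_schema(3))
    out = sample_naive_synthetic(data, rng)
    for j in range(3):
        col = out.values[:, j]
        src = set(X[~np.isnan(X[:, j]), j])
        assert all(np.isnan(v) or v in src for v in col)


def test_naive_synth_binary_fraction_within_binomial_band():
    # oracle: the synthetic count of ones is Binomial(n, q)
    rng = np.random.default_rng(2)
    n = 10000
    X = (rng.random((n, 1)) < 0.3).astype(float)
    q = X.mean()
    data = Dataset(X, continuous_schema(1))
    out = sample_naive_synthetic(data, np.random.default_rng(3))
    count = int(out.values.sum())
    lo, hi = stats.binom.ppf([0.0005, 0.9995], n, q)
    assert lo <= count <= hi


# ---------------------------------------------------------------- MIA splits


def test_mia_split_separates_missingness_perfectly():
    v = np.array([1.0, 2.0, 3.0, np.nan, np.nan])
    y = np.array([0, 0, 0, 1, 1])
    res = best_mia_split(v, y, min_node_size=1)
    assert res is not None
    assert res["impurity"] == pytest.approx(0.0)
    assert res["na_left"] in (True, False)


def test_mia_split_pure_node_returns_none():
    v = np.array([1.0, 2.0, np.nan, 4.0])
    y = np.array([1, 1, 1, 1])
    assert best_mia_split(v, y, min_node_size=1) is None


def _brute_force_numeric(v, y, min_child):
    """Exhaustive enumeration over all candidate thresholds x {A, B}."""
    isna = np.isnan(v)
    obs = np.unique(v[~isna])
    n = len(y)
    cands = []
    if isna.any():
        cands.append(-np.inf)
    for a, b in zip(obs[:-1], obs[1:]):
        thr = (a + b) / 2
        cands.append(a if thr >= b else thr)
    if isna.any() and obs.size:
        cands.append(obs[-1])
    best = None
    for thr in cands:
        for na_left in (True, False):
            left = (v <= thr) | (isna & na_left)
            nl, nr = left.sum(), n - left.sum()
            if nl < min_child or nr < min_child:
                continue
            pl = y[left].mean()
            pr = y[~left].mean()
            imp = (
                nl * (1 - pl**2 - (1 - pl) ** 2) + nr * (1 - pr**2 - (1 - pr) ** 2)
            ) / n
            if best is None or imp < best - 1e-12:
                best = imp
    return best


@pytest.mark.parametrize("trial", range(30))
def test_mia_split_matches_exhaustive_enumeration(trial):
    rng = np.random.default_rng(100 + trial)
    n = int(rng.integers(6, 50))
    v = rng.normal(size=n).round(1)  # ties on purpose
    v[rng.random(n) < 0.25] = np.nan
    y = rng.integers(0, 2, size=n)
    min_child = int(rng.integers(1, 4))
    res = best_mia_split(v, y, min_node_size=min_child)
    oracle = _brute_force_numeric(v, y, min_child)
    ones = y.sum()
    parent = 1 - (ones / n) ** 2 - (1 - ones / n) ** 2
    if oracle is None or oracle >= parent - 1e-12:
        assert res is None
    else:
        assert res is not None
        assert res["impurity"] == pytest.approx(oracle, abs=1e-10)


def _brute_force_categorical(v, y, min_child, k):
    isna = np.isnan(v)
    levels = [-1] * int(isna.any()) + sorted(int(c) for c in np.unique(v[~isna]))
    n = len(y)
    best = None
    for mask in range(1, 1 << len(levels)):
        left_set = {levels[i] for i in range(len(levels)) if mask >> i & 1}
        if len(left_set) == len(levels):
            continue
        left = np.array(
            [(-1 in left_set) if np.isnan(x) else (int(x) in left_set) for x in v]
        )
        nl, nr = left.sum(), n - left.sum()
        if nl < min_child or nr < min_child:
            continue
        pl, pr = y[left].mean(), y[~left].mean()
        imp = (
            nl * (1 - pl**2 - (1 - pl) ** 2) + nr * (1 - pr**2 - (1 - pr) ** 2)
        ) / n
        if best is None or imp < best - 1e-12:
            best = imp
    return best


@pytest.mark.parametrize("trial", range(15))
def test_categorical_mia_split_matches_enumeration(trial):
    rng = np.random.default_rng(300 + trial)
    n = int(rng.integers(8, 50))
    k = int(rng.integers(2, 5))
    v = rng.integers(0, k, size=n).astype(float)
    v[rng.random(n) < 0.2] = np.nan
    y = rng.integers(0, 2, size=n)
    res = best_mia_split(v, y, min_node_size=1, is_categorical=True, n_levels=k)
    oracle = _brute_force_categorical(v, y, 1, k)
    ones = y.sum()
    parent = 1 - (ones / n) ** 2 - (1 - ones / n) ** 2
    if oracle is None or oracle >= parent - 1e-12:
        assert res is None
    else:
        assert res is not None
        assert res["impurity"] == pytest.approx(oracle, abs=1e-10)


# ------------------------------------------------------------- discriminator


def test_discriminator_cannot_separate_identical_tables():
    # Identical classes are not separable above chance. (OOB accuracy drops
    # *below* 0.5 here: each out-of-bag copy is anti-predicted by its in-bag
    # twin, the usual duplicated-points OOB artefact.)
    rng = np.random.default_rng(5)
    X = rng.normal(size=(300, 3))
    data = Dataset(X, continuous_schema(3))
    fm = fit_discriminator(data, data.copy(), ARFConfig(num_trees=50), rng)
    se = np.sqrt(0.25 / (2 * 300))
    assert fm.oob_accuracy < 0.5 + 5 * se


def test_discriminator_separates_disjoint_supports():
    rng = np.random.default_rng(6)
    real = Dataset(np.abs(rng.normal(size=(200, 2))) + 0.5, continuous_schema(2))
    synth = Dataset(-np.abs(rng.normal(size=(200, 2))) - 0.5, continuous_schema(2))
    fm = fit_discriminator(real, synth, ARFConfig(num_trees=30), rng)
    assert fm.oob_accuracy > 0.95


def test_discriminator_learns_dependence_from_shuffled_copy():
    # XOR-style dependence: x2 = s * x1 with random sign has independent
    # marginals but strong joint structure; shuffling a column destroys it.
    rng = np.random.default_rng(7)
    n = 400
    x1 = rng.normal(size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    X = np.column_stack([x1, sign * x1])
    Xs = X.copy()
    Xs[:, 1] = rng.permutation(Xs[:, 1])
    real = Dataset(X, continuous_schema(2))
    synth = Dataset(Xs, continuous_schema(2))
    fm = fit_discriminator(real, synth, ARFConfig(num_trees=50), rng)
    se = np.sqrt(0.25 / (2 * n))
    assert fm.oob_accuracy > 0.5 + 3 * se


def test_discriminator_rejects_schema_mismatch():
    a = Dataset(np.zeros((20, 1)), continuous_schema(1))
    b = Dataset(
        np.zeros((20, 1)), Schema([Feature("c1", "categorical", ("0", "1"))])
    )
    with pytest.raises(ValueError):
        fit_discriminator(a, b, ARFConfig(), np.random.default_rng(0))


def test_min_node_size_respected_in_leaves():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(200, 2))
    data = Dataset(X, continuous_schema(2))
    cfg = ARFConfig(num_trees=10, min_node_size=10)
    synth = sample_naive_synthetic(data, rng)
    fm = fit_discriminator(data, synth, cfg, rng)
    stacked = np.vstack([X, synth.values])
    for t, tree in enumerate(fm.trees):
        inbag_rows = np.repeat(
            np.arange(2 * 200), fm.inbag_counts[t].astype(int)
        )
        leaves = tree.route(stacked[inbag_rows])
        counts = np.bincount(leaves, minlength=tree.n_leaves)
        assert counts.min() >= cfg.min_node_size


def test_routing_totality_including_all_missing_rows():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(100, 3))
    X[rng.random((100, 3)) < 0.3] = np.nan
    data = Dataset(X, continuous_schema(3))
    fm, _ = train_arf(data, ARFConfig(num_trees=20, seed=3, max_iters=2))
    probe = np.vstack([X, np.full((5, 3), np.nan)])
    for tree in fm.trees:
        leaves = tree.route(probe)
        assert leaves.shape == (105,)
        assert np.all((leaves >= 0) & (leaves < tree.n_leaves))


# --------------------------------------------------------------- leafwise synth


def test_leafwise_synth_reduces_to_naive_for_stump_forest():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(60, 2))
    data = Dataset(X, continuous_schema(2))
    # enormous min_node_size: every tree is a stump with a single leaf
    cfg = ARFConfig(num_trees=5, min_node_size=1000)
    fm = fit_discriminator(data, sample_naive_synthetic(data, rng), cfg, rng)
    assert all(t.n_leaves == 1 for t in fm.trees)
    out = sample_leafwise_synthetic(fm, data, np.random.default_rng(11))
    for j in range(2):
        assert set(out.values[:, j]) <= set(X[:, j])


def test_leafwise_synth_mixes_clusters_less_than_naive():
    data = make_two_cluster_data(n_per=150, seed=12)
    rng = np.random.default_rng(13)
    naive = sample_naive_synthetic(data, rng)
    fm = fit_discriminator(data, naive, ARFConfig(num_trees=30), rng)
    mixed_naive = 0
    mixed_leaf = 0
    reps = 5
    for r in range(reps):
        nv = sample_naive_synthetic(data, rng).values
        lw = sample_leafwise_synthetic(fm, data, rng).values
        mixed_naive += int(np.sum(nv[:, 0] * nv[:, 1] > 0))
        mixed_leaf += int(np.sum(lw[:, 0] * lw[:, 1] > 0))
    assert mixed_leaf < mixed_naive


# ------------------------------------------------------------------ train_arf


def test_train_arf_converges_immediately_on_independent_columns():
    rng = np.random.default_rng(14)
    X = rng.normal(size=(2000, 3))
    data = Dataset(X, continuous_schema(3))
    fm, _ = train_arf(data, ARFConfig(num_trees=50, delta=0.02, seed=15))
    assert fm.converged
    assert len(fm.history) == 1
    assert fm.history[0] < 0.52


def test_train_arf_history_bounded_and_nonconvergence_flagged():
    data = make_two_cluster_data(n_per=60, seed=16)
    cfg = ARFConfig(num_trees=20, max_iters=3, delta=0.0, seed=17)
    fm, _ = train_arf(data, cfg)
    assert len(fm.history) <= 3
    if not fm.converged:
        assert fm.oob_accuracy == min(fm.history)


def test_train_arf_deterministic_given_seed():
    data = make_two_cluster_data(n_per=50, seed=18)
    cfg = ARFConfig(num_trees=10, seed=19, max_iters=2)
    fm1, s1 = train_arf(data, cfg)
    fm2, s2 = train_arf(data, cfg)
    assert np.array_equal(s1.values, s2.values)
    assert fm1.history == fm2.history
    for t1, t2 in zip(fm1.trees, fm2.trees):
        assert t1.feature == t2.feature
        assert t1.threshold == t2.threshold or np.allclose(
            np.nan_to_num(t1.threshold), np.nan_to_num(t2.threshold)
        )
        assert t1.na_left == t2.na_left


def test_oob_accuracy_median_nonincreasing_over_first_rounds():
    # adversarial refinement should not make synthetic data easier to spot
    accs = []
    for seed in range(20):
        rng = np.random.default_rng(500 + seed)
        cov = np.array([[1.0, 0.7], [0.7, 1.0]])
        X = rng.multivariate_normal([0, 0], cov, size=150)
        data = Dataset(X, continuous_schema(2))
        cfg = ARFConfig(num_trees=20, max_iters=2, delta=0.0, seed=600 + seed)
        fm, _ = train_arf(data, cfg)
        h = fm.history + [fm.history[-1]] * (2 - len(fm.history))
        accs.append(h[:2])
    accs = np.array(accs)
    assert np.median(accs[:, 1]) <= np.median(accs[:, 0])


def test_arfconfig_validation():
    with pytest.raises(ValueError):
        ARFConfig(delta=0.5)
    with pytest.raises(ValueError):
        ARFConfig(num_trees=0)
    with pytest.raises(ValueError):
        ARFConfig(max_iters=0)
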