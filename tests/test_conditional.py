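"""Adjusted leaf weights, conditional density/sampling/expectation/mode."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

from missarf.conditional import (
    Evidence,
    adjust_weights,
    conditional_density,
    conditional_expectation,
    conditional_mode,
    sample_conditional,
)
from missarf.dataset import Feature, Schema
from missarf.leaves import DensityModel

from helpers import continuous_schema


def toy_model(weights, mus, sigmas, lo=None, hi=None, emp_means=None):
    """Hand-built density model with continuous features only."""
    weights = np.asarray(weights, dtype=float)
    mus = np.asarray(mus, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    L, p = mus.shape
    lo = np.full((L, p), -np.inf) if lo is None else np.asarray(lo, dtype=float)
    hi = np.full((L, p), np.inf) if hi is None else np.asarray(hi, dtype=float)
    model = DensityModel(
        schema=continuous_schema(p),
        num_trees=1,
        tree_index=np.zeros(L, dtype=np.int64),
        weights=weights,
        n_tl=np.ones(L, dtype=np.int64),
        lo=lo,
        hi=hi,
        na_admitted=np.ones((L, p), dtype=bool),
        cat_allowed={},
    )
    from missarf import _truncnorm

    model.mu = mus
    model.sigma = sigmas
    model.logz = _truncnorm.log_mass(mus, sigmas, lo, hi)
    model.emp_mean = mus.copy() if emp_means is None else np.asarray(emp_means, float)
    model.global_mean = mus.mean(axis=0)
    model.global_sd = np.ones(p)
    model.fitted = True
    return model


def cat_toy_model(weights, probs):
    """Hand-built model with one categorical feature (levels a, b[, c...])."""
    weights = np.asarray(weights, dtype=float)
    probs = np.asarray(probs, dtype=float)
    L, k = probs.shape
    levels = tuple("abcdefg"[:k])
    model = DensityModel(
        schema=Schema([Feature("g", "categorical", levels)]),
        num_trees=1,
        tree_index=np.zeros(L, dtype=np.int64),
        weights=weights,
        n_tl=np.ones(L, dtype=np.int64),
        lo=np.full((L, 1), -np.inf),
        hi=np.full((L, 1), np.inf),
        na_admitted=np.ones((L, 1), dtype=bool),
        cat_allowed={0: np.ones((L, k), dtype=bool)},
    )
    model.mu = np.full((L, 1), np.nan)
    model.sigma = np.full((L, 1), np.nan)
    model.logz = np.zeros((L, 1))
    model.emp_mean = np.full((L, 1), np.nan)
    model.cat_probs = {0: probs}
    model.global_cat_probs = {0: probs.mean(axis=0)}
    model.fitted = True
    return model


# ------------------------------------------------------------ adjust_weights


def test_empty_condition_returns_unadjusted_weights(two_cluster_model):
    _, model = two_cluster_model
    ev = Evidence(observed=(), values=(), missing=(0, 1))
    adj = adjust_weights(model, ev)
    assert np.allclose(adj.weights, model.weights, atol=1e-15)
    assert adj.weights.sum() == pytest.approx(1.0, abs=1e-12)


def test_leaves_excluding_evidence_get_zero_weight(two_cluster_model):
    _, model = two_cluster_model
    ev = Evidence(observed=(0,), values=(-1.0,), missing=(1,))
    adj = adjust_weights(model, ev)
    # any leaf whose x1-interval excludes -1 must carry exactly zero weight
    excl = (model.lo[:, 0] >= -1.0) | (model.hi[:, 0] < -1.0)
    assert np.all(adj.weights[excl] == 0.0)
    assert adj.weights.sum() == pytest.approx(1.0, abs=1e-12)


def test_adjusted_weights_match_bruteforce_on_toy_model():
    w = np.array([0.2, 0.5, 0.3])
    mus = np.array([[0.0, 1.0], [2.0, -1.0], [-1.0, 3.0]])
    sgs = np.array([[1.0, 1.0], [0.5, 2.0], [2.0, 0.7]])
    model = toy_model(w, mus, sgs)
    x1 = 0.7
    ev = Evidence(observed=(0,), values=(x1,), missing=(1,))
    adj = adjust_weights(model, ev)
    lik = w * stats.norm.pdf(x1, mus[:, 0], sgs[:, 0])
    expected = lik / lik.sum()
    assert np.allclose(adj.weights, expected, atol=1e-12)
    assert adj.log_evidence == pytest.approx(np.log(lik.sum()), abs=1e-12)


def test_all_incompatible_evidence_falls_back_with_flag():
    w = np.array([0.5, 0.5])
    mus = np.zeros((2, 1))
    sgs = np.ones((2, 1))
    lo = np.array([[0.0], [1.0]])
    hi = np.array([[1.0], [2.0]])
    model = toy_model(w, mus, sgs, lo=lo, hi=hi)
    ev = Evidence(observed=(0,), values=(5.0,), missing=())
    adj = adjust_weights(model, ev)
    assert adj.fallback
    assert np.allclose(adj.weights, w)


# ------------------------------------------------------- conditional density


def test_conditional_density_with_no_missing_is_one(two_cluster_model):
    _, model = two_cluster_model
    ev = Evidence(observed=(0, 1), values=(-1.0, 1.0), missing=())
    assert conditional_density(model, ev, []) == pytest.approx(1.0, abs=1e-12)


def test_single_leaf_conditional_equals_marginal_density():
    model = toy_model(np.array([1.0]), np.array([[0.0, 2.0]]), np.array([[1.0, 0.5]]))
    ev = Evidence(observed=(0,), values=(3.0,), missing=(1,))
    val = conditional_density(model, ev, [2.3])
    assert val == pytest.approx(stats.norm.pdf(2.3, 2.0, 0.5), abs=1e-12)


def test_conditional_density_integrates_to_one(bivariate_normal_model):
    _, model = bivariate_normal_model
    ev = Evidence(observed=(0,), values=(0.5,), missing=(1,))
    grid = np.linspace(-8, 8, 6001)
    vals = np.array([conditional_density(model, ev, [g]) for g in grid])
    assert np.trapezoid(vals, grid) == pytest.approx(1.0, abs=1e-3)


def test_conditioning_on_nothing_reproduces_unconditional_density(two_cluster_model):
    from missarf.leaves import density

    _, model = two_cluster_model
    ev = Evidence(observed=(), values=(), missing=(0, 1))
    for pt in ([-1.0, 1.0], [0.3, -0.2], [1.1, -0.9]):
        lw = np.log(np.where(model.weights > 0, model.weights, np.nan))
        cond = conditional_density(model, ev, pt)
        assert cond == pytest.approx(density(model, pt), abs=1e-10)


# ------------------------------------------------------ conditional sampling


def test_conditional_samples_concentrate_on_matching_cluster(two_cluster_model):
    _, model = two_cluster_model
    ev = Evidence(observed=(0,), values=(-1.0,), missing=(1,))
    out = sample_conditional(model, ev, 500, np.random.default_rng(1))
    assert np.all(out[:, 0] == -1.0)
    assert abs(np.mean(out[:, 1]) - 1.0) < 0.1
    assert np.mean(np.abs(out[:, 1] - 1.0) < 0.5) > 0.99


def test_conditional_sampler_matches_rejection_sampling_oracle(two_cluster_model):
    # dual route: exact conditioning vs unconditional generation + filtering.
    # The acceptance window must be small relative to the within-leaf density
    # variation (leaf scale ~0.05 here), otherwise the oracle itself is
    # biased: window-mass leaf weights differ measurably from point-density
    # weights for any correct implementation.
    from missarf.leaves import sample_unconditional

    _, model = two_cluster_model
    rng = np.random.default_rng(2)
    ev = Evidence(observed=(0,), values=(-1.0,), missing=(1,))
    cond = sample_conditional(model, ev, 2000, rng)[:, 1]
    unc = sample_unconditional(model, 600000, rng).values
    keep = np.abs(unc[:, 0] - (-1.0)) < 0.003
    reject = unc[keep, 1]
    assert reject.size > 1000
    ks = stats.ks_2samp(cond, reject)
    assert ks.pvalue > 0.01


def test_no_missing_features_returns_row_unchanged(two_cluster_model):
    _, model = two_cluster_model
    ev = Evidence(observed=(0, 1), values=(0.25, -0.75), missing=())
    out = sample_conditional(model, ev, 7, np.random.default_rng(3))
    assert out.shape == (7, 2)
    assert np.all(out == [0.25, -0.75])


# --------------------------------------------------- expectation and mode


def test_single_compatible_leaf_returns_its_empirical_mean():
    lo = np.array([[-np.inf, -np.inf], [2.0, -np.inf]])
    hi = np.array([[2.0, np.inf], [np.inf, np.inf]])
    model = toy_model(
        np.array([0.5, 0.5]),
        np.array([[0.0, 1.5], [4.0, -2.5]]),
        np.ones((2, 2)),
        lo=lo,
        hi=hi,
    )
    ev = Evidence(observed=(0,), values=(0.0,), missing=(1,))
    assert conditional_expectation(model, ev, 1) == pytest.approx(1.5)


def test_conditional_expectation_weighted_average_arithmetic():
    # w~ = (0.25, 0.75), mu = (0, 4) -> 3
    model = toy_model(
        np.array([0.25, 0.75]),
        np.array([[0.0, 0.0], [0.0, 4.0]]),
        np.ones((2, 2)),
    )
    ev = Evidence(observed=(), values=(), missing=(0, 1))
    assert conditional_expectation(model, ev, 1) == pytest.approx(3.0)


def test_conditional_expectation_matches_monte_carlo_oracle(bivariate_normal_model):
    # replace within-leaf draws by leaf means: the k -> inf average equals
    # the analytic weighted sum of empirical leaf means
    _, model = bivariate_normal_model
    rng = np.random.default_rng(4)
    ev = Evidence(observed=(0,), values=(0.8,), missing=(1,))
    adj = adjust_weights(model, ev)
    leaves = rng.choice(model.n_leaves, size=5000, p=adj.weights)
    mc = model.emp_mean[leaves, 1].mean()
    exact = conditional_expectation(model, ev, 1)
    mc_se = model.emp_mean[:, 1][np.isfinite(model.emp_mean[:, 1])].std() / np.sqrt(5000)
    assert abs(mc - exact) < 4 * max(mc_se, 1e-3)


def test_conditional_expectation_within_leaf_mean_range(bivariate_normal_model):
    _, model = bivariate_normal_model
    ev = Evidence(observed=(0,), values=(0.0,), missing=(1,))
    adj = adjust_weights(model, ev)
    contributing = adj.weights > 0
    val = conditional_expectation(model, ev, 1)
    assert model.emp_mean[contributing, 1].min() <= val <= model.emp_mean[contributing, 1].max()


def test_conditional_mode_single_leaf():
    model = cat_toy_model(np.array([1.0]), np.array([[0.7, 0.3]]))
    ev = Evidence(observed=(), values=(), missing=(0,))
    assert conditional_mode(model, ev, 0) == 0


def test_conditional_mode_two_leaf_arithmetic():
    # 0.5*(0.9, 0.1) + 0.5*(0.2, 0.8) = (0.55, 0.45) -> first level
    model = cat_toy_model(np.array([0.5, 0.5]), np.array([[0.9, 0.1], [0.2, 0.8]]))
    ev = Evidence(observed=(), values=(), missing=(0,))
    assert conditional_mode(model, ev, 0) == 0


@pytest.mark.parametrize("trial", range(10))
def test_conditional_mode_matches_summation_oracle(trial):
    rng = np.random.default_rng(800 + trial)
    L, k = 10, int(rng.integers(2, 6))
    w = rng.dirichlet(np.ones(L))
    probs = rng.dirichlet(np.ones(k), size=L)
    model = cat_toy_model(w, probs)
    ev = Evidence(observed=(), values=(), missing=(0,))
    got = conditional_mode(model, ev, 0)
    scores = w @ probs
    assert got == int(np.argmax(scores))


def test_evidence_validation():
    with pytest.raises(ValueError):
        Evidence(observed=(0,), values=(np.nan,), missing=(1,))
    with pytest.raises(ValueError):
        Evidence(observed=(0,), values=(1.0,), missing=(0,))
    with pytest.raises(ValueError):
        Evidence(observed=(0, 1), values=(1.0,), missing=())
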