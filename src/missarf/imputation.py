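"""Dataset-level single and multiple imputation.

``impute`` is the user-facing entry point: one call with a table returns a
single completed table; passing ``m`` returns m completed tables drawn from
the conditional distribution, with the forest trained exactly once.

Baselines: random imputation (uniform draws from each column's observed
values) and median/most-frequent imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import forest as _forest
from .conditional import Evidence, adjust_weights
from .dataset import Dataset, check_no_all_missing
from .forest import ARFConfig, train_arf
from .leaves import DensityModel, _sample_features, fit_density_model


@dataclass(frozen=True)
class ImputeConfig:
    """Settings of the imputation run.

    mode applies to single imputation: "expectation" fills continuous cells
    with the conditional expectation and categorical cells with the weighted
    mode; "sample" draws one value from the conditional distribution.
    """

    m: int = 20
    mode: str = "expectation"
    arf: ARFConfig = field(default_factory=ARFConfig)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.mode not in ("expectation", "sample"):
            raise ValueError("mode must be 'expectation' or 'sample'")


@dataclass
class ImputationSet:
    """m completed datasets plus provenance."""

    datasets: list[Dataset]
    method: str
    seed: int | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)

    def __getitem__(self, i: int) -> Dataset:
        return self.datasets[i]


def _row_rng(master_seed, *tags) -> np.random.Generator:
    entropy = [0 if master_seed is None else int(master_seed)] + [int(t) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _train_model(data: Dataset, cfg: ImputeConfig):
    check_no_all_missing(data)
    arf_cfg = cfg.arf
    if arf_cfg.seed is None and cfg.seed is not None:
        arf_cfg = ARFConfig(
            num_trees=arf_cfg.num_trees,
            min_node_size=arf_cfg.min_node_size,
            delta=arf_cfg.delta,
            max_iters=arf_cfg.max_iters,
            mtry=arf_cfg.mtry,
            seed=int(np.random.SeedSequence([cfg.seed, 0]).generate_state(1)[0] % (2**31)),
        )
    fm, _ = train_arf(data, arf_cfg)
    model = fit_density_model(fm, data)
    warnings = [] if fm.converged else ["ARF did not converge within max_iters"]
    return model, warnings


def _fill_row_point(model: DensityModel, ev: Evidence, schema) -> dict[int, float]:
    """Expectation / weighted-mode fill for one row (single imputation)."""
    from .conditional import conditional_expectation, conditional_mode

    out = {}
    for j in ev.missing:
        if schema.is_categorical[j]:
            out[j] = float(conditional_mode(model, ev, j))
        else:
            out[j] = conditional_expectation(model, ev, j)
    return out


def impute_missarf_single(data: Dataset, cfg: ImputeConfig | None = None) -> Dataset:
    """Train one adversarial forest and fill every missing cell.

    Complete rows are untouched; observed cells pass through bit-exactly.
    """
    cfg = cfg or ImputeConfig()
    model, _ = _train_model(data, cfg)
    return _complete_with_model(data, model, cfg, imputation_index=0)


def _complete_with_model(
    data: Dataset, model: DensityModel, cfg: ImputeConfig, imputation_index: int
) -> Dataset:
    out = data.values.copy()
    rows = np.flatnonzero(data.missing_mask.any(axis=1))
    for i in rows:
        ev = Evidence.from_row(data.values[i], row_id=int(i))
        if cfg.mode == "expectation":
            fills = _fill_row_point(model, ev, data.schema)
            for j, v in fills.items():
                out[i, j] = v
        else:
            adj = adjust_weights(model, ev)
            rng = _row_rng(cfg.seed, 1, imputation_index, i)
            leaf = rng.choice(model.n_leaves, p=adj.weights)
            vals = _sample_features(model, np.array([leaf]), list(ev.missing), rng)
            for c, j in enumerate(ev.missing):
                out[i, j] = vals[0, c]
    return Dataset(out, data.schema)


def impute_missarf_multiple(data: Dataset, cfg: ImputeConfig | None = None) -> ImputationSet:
    """m completions from one trained forest (no refitting per imputation).

    Each completion draws a fresh leaf per incomplete row from the adjusted
    leaf weights and samples the missing features within that leaf, so the
    spread across the m tables reflects the conditional distribution.
    """
    cfg = cfg or ImputeConfig()
    model, warns = _train_model(data, cfg)
    rows = np.flatnonzero(data.missing_mask.any(axis=1))
    evidences = {
        int(i): Evidence.from_row(data.values[i], row_id=int(i)) for i in rows
    }
    adjusted = {i: adjust_weights(model, ev) for i, ev in evidences.items()}
    n_fallback = sum(1 for a in adjusted.values() if a.fallback)
    if n_fallback:
        warns = warns + [f"{n_fallback} row(s) fell back to unadjusted leaf weights"]
    datasets = []
    for imp in range(cfg.m):
        out = data.values.copy()
        for i in rows:
            ev = evidences[int(i)]
            rng = _row_rng(cfg.seed, 1, imp, i)
            leaf = rng.choice(model.n_leaves, p=adjusted[int(i)].weights)
            vals = _sample_features(model, np.array([leaf]), list(ev.missing), rng)
            for c, j in enumerate(ev.missing):
                out[i, j] = vals[0, c]
        datasets.append(Dataset(out, data.schema))
    return ImputationSet(datasets, method="missarf", seed=cfg.seed, warnings=warns)


def impute(data: Dataset, m: int | None = None, **kwargs) -> Dataset | ImputationSet:
    """Two-call user API: ``impute(data)`` for a single completed table,
    ``impute(data, m=20)`` for multiple imputation."""
    if m is None:
        return impute_missarf_single(data, ImputeConfig(**kwargs))
    return impute_missarf_multiple(data, ImputeConfig(m=m, **kwargs))


def impute_random(data: Dataset, m: int = 1, rng=None, seed=None) -> ImputationSet:
    """Fill each missing cell with a uniform draw from the column's observed
    values, independently per imputation."""
    check_no_all_missing(data)
    if rng is None:
        rng = np.random.default_rng(seed)
    mask = data.missing_mask
    datasets = []
    for _ in range(m):
        out = data.values.copy()
        for j in range(data.p):
            mj = mask[:, j]
            if not mj.any():
                continue
            obs = data.values[~mj, j]
            out[mj, j] = obs[rng.integers(0, obs.size, size=int(mj.sum()))]
        datasets.append(Dataset(out, data.schema))
    return ImputationSet(datasets, method="random", seed=seed)


def impute_median(data: Dataset) -> Dataset:
    """Column median for continuous cells; most frequent observed level for
    categorical ones (ties toward the earlier declared level)."""
    check_no_all_missing(data)
    out = data.values.copy()
    mask = data.missing_mask
    for j in range(data.p):
        mj = mask[:, j]
        if not mj.any():
            continue
        obs = data.values[~mj, j]
        if data.schema.is_categorical[j]:
            counts = np.bincount(obs.astype(np.int64), minlength=data.schema.n_levels(j))
            fill = float(np.argmax(counts))
        else:
            fill = float(np.median(obs))
        out[mj, j] = fill
    return Dataset(out, data.schema)
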