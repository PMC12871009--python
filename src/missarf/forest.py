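"""Adversarial random forest training with missingness-aware splits.

The discriminator is a Gini random forest grown on real rows (label 1)
stacked over synthetic rows (label 0). Missing values are handled by the
"missingness incorporated in attributes" rule: numeric splits choose the
child that receives NAs, categorical splits treat NA as an extra level.
Training alternates discriminator fits with leaf-wise refinement of the
synthetic data until the out-of-bag accuracy falls below 0.5 + delta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._split import best_numeric_split
from .dataset import Dataset

#: incremented by every :func:`train_arf` call (used to assert that multiple
#: imputation trains a single forest).
TRAIN_CALLS = 0

_EPS_IMP = 1e-12
_NA_LEVEL = -1  # sentinel code for "NA as its own category"


@dataclass(frozen=True)
class ARFConfig:
    """Hyperparameters of the adversarial forest.

    delta is the slack on the convergence criterion: training stops once the
    discriminator's OOB accuracy drops below 0.5 + delta.
    """

    num_trees: int = 100
    min_node_size: int = 10
    delta: float = 0.0
    max_iters: int = 10
    mtry: int | None = None  # default floor(sqrt(p))
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.num_trees < 1:
            raise ValueError("num_trees must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if not (0.0 <= self.delta < 0.5):
            raise ValueError("delta must lie in [0, 0.5)")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")

    def resolve_mtry(self, p: int) -> int:
        if self.mtry is not None:
            if self.mtry > p:
                raise ValueError("mtry cannot exceed the number of features")
            return self.mtry
        return max(1, int(math.isqrt(p)))


class Tree:
    """A binary tree of MIA split nodes stored as parallel arrays.

    Numeric nodes route ``x <= threshold`` left (NA per ``na_left``);
    categorical nodes route codes in ``left_codes`` left (NA per ``na_left``).
    """

    __slots__ = (
        "feature",
        "threshold",
        "na_left",
        "left_codes",
        "left",
        "right",
        "leaf_id",
        "leaf_pred",
        "n_leaves",
    )

    def __init__(self) -> None:
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.na_left: list[bool] = []
        self.left_codes: list[frozenset | None] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.leaf_id: list[int] = []
        self.leaf_pred: list[int] = []
        self.n_leaves = 0

    def _new_node(self) -> int:
        self.feature.append(-1)
        self.threshold.append(np.nan)
        self.na_left.append(True)
        self.left_codes.append(None)
        self.left.append(-1)
        self.right.append(-1)
        self.leaf_id.append(-1)
        self.leaf_pred.append(0)
        return len(self.feature) - 1

    def route(self, X: np.ndarray) -> np.ndarray:
        """Leaf id for every row of ``X``; all-missing rows are routed too."""
        n = X.shape[0]
        out = np.empty(n, dtype=np.int64)
        stack = [(0, np.arange(n))]
        while stack:
            node, idx = stack.pop()
            if self.feature[node] < 0:
                out[idx] = self.leaf_id[node]
                continue
            j = self.feature[node]
            v = X[idx, j]
            isna = np.isnan(v)
            if self.left_codes[node] is None:
                go_left = (v <= self.threshold[node]) | (isna & self.na_left[node])
            else:
                codes = np.array(sorted(self.left_codes[node]), dtype=np.float64)
                go_left = np.isin(v, codes) | (isna & self.na_left[node])
            stack.append((self.left[node], idx[go_left]))
            stack.append((self.right[node], idx[~go_left]))
        return out


@dataclass
class ForestModel:
    """A trained discriminator forest plus its adversarial-loop bookkeeping."""

    trees: list[Tree]
    config: ARFConfig
    oob_accuracy: float
    inbag_counts: np.ndarray  # (T, 2n) bootstrap multiplicities
    n_real: int
    history: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def num_trees(self) -> int:
        return len(self.trees)

    def route_all(self, X: np.ndarray) -> np.ndarray:
        """(T, n) leaf-id matrix for the rows of ``X``."""
        return np.stack([t.route(X) for t in self.trees])


def _best_categorical_split(v, y, min_child, n_levels, max_exhaustive=10):
    """Exhaustive (small k) MIA split for one categorical feature.

    NA is a level of its own (sentinel -1). Partitions are enumerated once
    each by excluding the highest level from the left set; enumeration order
    is the tie-break. For many levels, candidate left sets are prefixes of
    the levels sorted by class-1 proportion (then code), a standard
    reduction.
    """
    isna = np.isnan(v)
    codes = v[~isna].astype(np.int64)
    y = np.asarray(y)
    n = v.shape[0]
    present = np.unique(codes)
    levels = ([_NA_LEVEL] if isna.any() else []) + [int(c) for c in present]
    k = len(levels)
    if k < 2:
        return None
    counts = {}
    for lev in levels:
        if lev == _NA_LEVEL:
            sel = isna
        else:
            sel = (~isna) & (v == lev)
        counts[lev] = (int(sel.sum()), int(y[sel].sum()))
    total1 = int(y.sum())

    if k <= max_exhaustive:
        subsets = []
        for mask in range(1, 1 << (k - 1)):
            subsets.append([levels[i] for i in range(k - 1) if mask >> i & 1])
    else:
        def prop(lev):
            c, o = counts[lev]
            return (o / c, lev)

        ordered = sorted(levels, key=prop)
        subsets = [ordered[: i + 1] for i in range(k - 1)]

    best = None
    for left_set in subsets:
        nl = sum(counts[lev][0] for lev in left_set)
        l1 = sum(counts[lev][1] for lev in left_set)
        nr, r1 = n - nl, total1 - l1
        if nl < min_child or nr < min_child:
            continue
        pl, pr = l1 / nl, r1 / nr
        imp = (
            nl * (1 - pl * pl - (1 - pl) * (1 - pl))
            + nr * (1 - pr * pr - (1 - pr) * (1 - pr))
        ) / n
        if best is None or imp < best[0] - _EPS_IMP:
            na_left = _NA_LEVEL in left_set if isna.any() else True
            best = (imp, frozenset(c for c in left_set if c != _NA_LEVEL), na_left)
    return best


def best_mia_split(values, labels, *, min_node_size, is_categorical=False, n_levels=0):
    """Impurity-minimizing MIA split of one feature at a node, or ``None``.

    Returns a dict with keys ``impurity`` and either ``threshold``/``na_left``
    (numeric) or ``left_codes``/``na_left`` (categorical). ``None`` means no
    candidate split satisfies the child-size constraint or all labels agree.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    n = labels.size
    ones = labels.sum()
    if ones == 0 or ones == n:
        return None
    parent = 1.0 - (ones / n) ** 2 - (1 - ones / n) ** 2
    if is_categorical:
        res = _best_categorical_split(values, labels, min_node_size, n_levels)
        if res is None or res[0] >= parent - _EPS_IMP:
            return None
        imp, left_codes, na_left = res
        return {"impurity": imp, "left_codes": left_codes, "na_left": na_left}
    found, imp, thr, na_left = best_numeric_split(
        values, labels, np.int64(min_node_size)
    )
    if not found or imp >= parent - _EPS_IMP:
        return None
    return {"impurity": imp, "threshold": float(thr), "na_left": bool(na_left)}


def _grow_tree(X, y, inbag_idx, cfg: ARFConfig, is_cat, n_levels, rng) -> Tree:
    p = X.shape[1]
    mtry = cfg.resolve_mtry(p)
    min_node = cfg.min_node_size
    tree = Tree()

    def build(idx: np.ndarray) -> int:
        node = tree._new_node()
        yb = y[idx]
        n_node = idx.size
        ones = int(yb.sum())
        best = None
        if n_node >= 2 * min_node and 0 < ones < n_node:
            feats = np.sort(rng.choice(p, size=mtry, replace=False))
            for j in feats:
                cand = best_mia_split(
                    X[idx, j],
                    yb,
                    min_node_size=min_node,
                    is_categorical=bool(is_cat[j]),
                    n_levels=n_levels[j],
                )
                if cand is not None and (
                    best is None or cand["impurity"] < best[1]["impurity"] - _EPS_IMP
                ):
                    best = (int(j), cand)
        if best is None:
            tree.leaf_id[node] = tree.n_leaves
            tree.n_leaves += 1
            # majority in-bag class; ties go to the synthetic class 0
            tree.leaf_pred[node] = 1 if ones * 2 > n_node else 0
            return node
        j, cand = best
        v = X[idx, j]
        isna = np.isnan(v)
        if "threshold" in cand:
            go_left = (v <= cand["threshold"]) | (isna & cand["na_left"])
            tree.threshold[node] = cand["threshold"]
        else:
            codes = np.array(sorted(cand["left_codes"]), dtype=np.float64)
            go_left = np.isin(v, codes) | (isna & cand["na_left"])
            tree.left_codes[node] = cand["left_codes"]
        tree.feature[node] = j
        tree.na_left[node] = cand["na_left"]
        left = build(idx[go_left])
        right = build(idx[~go_left])
        tree.left[node] = left
        tree.right[node] = right
        return node

    build(inbag_idx)
    return tree


def _schema_info(schema):
    is_cat = schema.is_categorical
    n_levels = np.array(
        [schema.n_levels(j) if is_cat[j] else 0 for j in range(len(schema))]
    )
    return is_cat, n_levels


def fit_discriminator(real: Dataset, synth: Dataset, cfg: ARFConfig, rng) -> ForestModel:
    """Fit the real-vs-synthetic forest and measure its OOB accuracy."""
    if real.schema != synth.schema:
        raise ValueError("real and synthetic datasets must share a schema")
    X = np.vstack([real.values, synth.values])
    y = np.concatenate(
        [np.ones(real.n, dtype=np.int64), np.zeros(synth.n, dtype=np.int64)]
    )
    n2 = X.shape[0]
    is_cat, n_levels = _schema_info(real.schema)

    T = cfg.num_trees
    tree_seeds = rng.integers(0, 2**63, size=T)
    trees: list[Tree] = []
    inbag = np.zeros((T, n2), dtype=np.uint16)
    votes1 = np.zeros(n2, dtype=np.int64)
    votes = np.zeros(n2, dtype=np.int64)
    for t in range(T):
        rng_t = np.random.default_rng(np.random.PCG64(int(tree_seeds[t])))
        idx = rng_t.integers(0, n2, size=n2)
        np.add.at(inbag[t], idx, 1)
        tree = _grow_tree(X, y, idx, cfg, is_cat, n_levels, rng_t)
        trees.append(tree)
        oob_rows = np.flatnonzero(inbag[t] == 0)
        if oob_rows.size:
            leaf_node_pred = _leaf_pred_array(tree)
            leaves = tree.route(X[oob_rows])
            pred = leaf_node_pred[leaves]
            votes1[oob_rows] += pred
            votes[oob_rows] += 1
    has_vote = votes > 0
    # majority vote over OOB trees; ties toward the synthetic class 0
    pred_row = (2 * votes1[has_vote]) > votes[has_vote]
    oob_acc = float(np.mean(pred_row == (y[has_vote] == 1))) if has_vote.any() else 0.5
    return ForestModel(
        trees=trees,
        config=cfg,
        oob_accuracy=oob_acc,
        inbag_counts=inbag,
        n_real=real.n,
    )


def _leaf_pred_array(tree: Tree) -> np.ndarray:
    arr = np.zeros(tree.n_leaves, dtype=np.int64)
    for node, lid in enumerate(tree.leaf_id):
        if lid >= 0:
            arr[lid] = tree.leaf_pred[node]
    return arr


def sample_naive_synthetic(data: Dataset, rng) -> Dataset:
    """Bootstrap each column independently (the product-of-marginals draw).

    Missing markers are drawable cells, so each column's missingness rate is
    preserved in expectation and the discriminator cannot win on missingness
    alone.
    """
    n = data.n
    if n < 1:
        raise ValueError("empty table")
    out = np.empty_like(data.values)
    for j in range(data.p):
        out[:, j] = data.values[rng.integers(0, n, size=n), j]
    return Dataset(out, data.schema)


def sample_leafwise_synthetic(forest: ForestModel, real: Dataset, rng) -> Dataset:
    """Column-wise bootstrap within leaves: draw a tree, a leaf by its real
    coverage, then each feature independently from that leaf's real members."""
    n, p = real.n, real.p
    out = np.empty((n, p))
    T = forest.num_trees
    # leaf membership of the real rows, per tree
    leaf_of_real = forest.route_all(real.values)
    tree_draw = rng.integers(0, T, size=n)
    for t in range(T):
        rows = np.flatnonzero(tree_draw == t)
        if rows.size == 0:
            continue
        leaves_t = leaf_of_real[t]
        occupied, counts = np.unique(leaves_t, return_counts=True)
        probs = counts / counts.sum()
        pick = rng.choice(occupied.size, size=rows.size, p=probs)
        for li in np.unique(pick):
            rws = rows[pick == li]
            members = np.flatnonzero(leaves_t == occupied[li])
            for j in range(p):
                sel = members[rng.integers(0, members.size, size=rws.size)]
                out[rws, j] = real.values[sel, j]
    return Dataset(out, real.schema)


def train_arf(data: Dataset, cfg: ARFConfig) -> tuple[ForestModel, Dataset]:
    """Alternate discriminator fits and leaf-wise synthesis to convergence.

    Returns the first forest whose OOB accuracy drops below 0.5 + delta
    (the discriminator that can no longer distinguish real from synthetic)
    together with the synthetic table it was trained against. If the loop
    hits ``max_iters`` without converging, the lowest-OOB-accuracy forest is
    returned with ``converged=False``.
    """
    global TRAIN_CALLS
    TRAIN_CALLS += 1
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    synth = sample_naive_synthetic(data, rng)
    history: list[float] = []
    best: tuple[float, ForestModel, Dataset] | None = None
    threshold = 0.5 + cfg.delta
    for _ in range(cfg.max_iters):
        forest = fit_discriminator(data, synth, cfg, rng)
        history.append(forest.oob_accuracy)
        if best is None or forest.oob_accuracy < best[0]:
            best = (forest.oob_accuracy, forest, synth)
        if forest.oob_accuracy < threshold:
            forest.history = history
            forest.converged = True
            return forest, synth
        synth = sample_leafwise_synthetic(forest, data, rng)
    _, forest, synth = best
    forest.history = history
    forest.converged = False
    return forest, synth
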