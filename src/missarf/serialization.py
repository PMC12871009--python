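"""JSON layouts for trained forests and density models.

Trees are nested node objects: internal nodes carry ``feature`` plus either
``threshold`` (numeric) or ``left_codes`` (categorical) and ``na_left``;
leaves carry ``leaf`` (the per-tree leaf id) and ``pred``. Infinities are
encoded as the strings "inf"/"-inf" to stay inside strict JSON.
"""

from __future__ import annotations

import json

import numpy as np

from .dataset import Schema
from .forest import ARFConfig, ForestModel, Tree
from .leaves import DensityModel


def _enc(x: float):
    if np.isposinf(x):
        return "inf"
    if np.isneginf(x):
        return "-inf"
    return float(x)


def _dec(x) -> float:
    if x == "inf":
        return np.inf
    if x == "-inf":
        return -np.inf
    return float(x)


def _node_to_obj(tree: Tree, node: int):
    if tree.feature[node] < 0:
        return {"leaf": tree.leaf_id[node], "pred": tree.leaf_pred[node]}
    obj = {"feature": tree.feature[node], "na_left": bool(tree.na_left[node])}
    if tree.left_codes[node] is None:
        obj["threshold"] = _enc(tree.threshold[node])
    else:
        obj["left_codes"] = sorted(tree.left_codes[node])
    obj["left"] = _node_to_obj(tree, tree.left[node])
    obj["right"] = _node_to_obj(tree, tree.right[node])
    return obj


def _obj_to_tree(obj) -> Tree:
    tree = Tree()

    def build(o) -> int:
        node = tree._new_node()
        if "leaf" in o:
            tree.leaf_id[node] = int(o["leaf"])
            tree.leaf_pred[node] = int(o["pred"])
            tree.n_leaves = max(tree.n_leaves, tree.leaf_id[node] + 1)
            return node
        tree.feature[node] = int(o["feature"])
        tree.na_left[node] = bool(o["na_left"])
        if "threshold" in o:
            tree.threshold[node] = _dec(o["threshold"])
        else:
            tree.left_codes[node] = frozenset(int(c) for c in o["left_codes"])
        left = build(o["left"])
        right = build(o["right"])
        tree.left[node] = left
        tree.right[node] = right
        return node

    build(obj)
    return tree


def forest_to_dict(fm: ForestModel) -> dict:
    cfg = fm.config
    return {
        "kind": "missarf-forest",
        "config": {
            "num_trees": cfg.num_trees,
            "min_node_size": cfg.min_node_size,
            "delta": cfg.delta,
            "max_iters": cfg.max_iters,
            "mtry": cfg.mtry,
            "seed": cfg.seed,
        },
        "oob_accuracy": fm.oob_accuracy,
        "history": list(fm.history),
        "converged": fm.converged,
        "n_real": fm.n_real,
        "trees": [_node_to_obj(t, 0) for t in fm.trees],
    }


def forest_from_dict(d: dict) -> ForestModel:
    if d.get("kind") != "missarf-forest":
        raise ValueError("not a serialized forest")
    cfg = ARFConfig(**d["config"])
    trees = [_obj_to_tree(o) for o in d["trees"]]
    return ForestModel(
        trees=trees,
        config=cfg,
        oob_accuracy=float(d["oob_accuracy"]),
        inbag_counts=np.zeros((len(trees), 0), dtype=np.uint16),
        n_real=int(d["n_real"]),
        history=list(d.get("history", [])),
        converged=bool(d.get("converged", True)),
    )


def density_to_dict(model: DensityModel) -> dict:
    if not model.fitted:
        raise ValueError("fit the leaf distributions before serializing")
    enc2 = lambda arr: [[_enc(v) for v in row] for row in np.asarray(arr)]
    return {
        "kind": "missarf-density",
        "schema": model.schema.to_dict(),
        "num_trees": model.num_trees,
        "tree_index": model.tree_index.tolist(),
        "weights": model.weights.tolist(),
        "n_tl": model.n_tl.tolist(),
        "lo": enc2(model.lo),
        "hi": enc2(model.hi),
        "na_admitted": model.na_admitted.tolist(),
        "mu": enc2(model.mu),
        "sigma": enc2(model.sigma),
        "logz": enc2(model.logz),
        "emp_mean": enc2(model.emp_mean),
        "cat_allowed": {str(j): a.tolist() for j, a in model.cat_allowed.items()},
        "cat_probs": {str(j): p.tolist() for j, p in model.cat_probs.items()},
        "global_mean": [_enc(v) for v in model.global_mean],
        "global_sd": [_enc(v) for v in model.global_sd],
        "global_cat_probs": {
            str(j): p.tolist() for j, p in model.global_cat_probs.items()
        },
    }


def density_from_dict(d: dict) -> DensityModel:
    if d.get("kind") != "missarf-density":
        raise ValueError("not a serialized density model")
    dec2 = lambda rows: np.array([[_dec(v) for v in row] for row in rows], dtype=float)
    model = DensityModel(
        schema=Schema.from_dict(d["schema"]),
        num_trees=int(d["num_trees"]),
        tree_index=np.array(d["tree_index"], dtype=np.int64),
        weights=np.array(d["weights"], dtype=float),
        n_tl=np.array(d["n_tl"], dtype=np.int64),
        lo=dec2(d["lo"]),
        hi=dec2(d["hi"]),
        na_admitted=np.array(d["na_admitted"], dtype=bool),
        cat_allowed={int(j): np.array(a, dtype=bool) for j, a in d["cat_allowed"].items()},
    )
    model.mu = dec2(d["mu"])
    model.sigma = dec2(d["sigma"])
    model.logz = dec2(d["logz"])
    model.emp_mean = dec2(d["emp_mean"])
    model.cat_probs = {int(j): np.array(p, dtype=float) for j, p in d["cat_probs"].items()}
    model.global_mean = np.array([_dec(v) for v in d["global_mean"]], dtype=float)
    model.global_sd = np.array([_dec(v) for v in d["global_sd"]], dtype=float)
    model.global_cat_probs = {
        int(j): np.array(p, dtype=float) for j, p in d["global_cat_probs"].items()
    }
    model.fitted = True
    return model


def save_forest(fm: ForestModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(forest_to_dict(fm), fh)


def load_forest(path) -> ForestModel:
    with open(path) as fh:
        return forest_from_dict(json.load(fh))


def save_density(model: DensityModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(density_to_dict(model), fh)


def load_density(path) -> DensityModel:
    with open(path) as fh:
        return density_from_dict(json.load(fh))
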