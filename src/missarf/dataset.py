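"""Rectangular tables with missing cells and a continuous/categorical schema.

Internally every table is held as a dense float matrix: continuous cells are
stored as-is, categorical cells as integer level codes, and missing cells as
NaN. Level codes follow the declared level order of the schema, which is also
the tie-breaking order everywhere a "first level wins" rule applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"


@dataclass(frozen=True)
class Feature:
    """One column: a name, a kind, and (for categorical) ordered levels."""

    name: str
    kind: str  # "continuous" | "categorical"
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "categorical":
            if len(self.levels) == 0:
                raise ValueError(f"categorical feature {self.name!r} needs levels")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"duplicate levels for feature {self.name!r}")
        elif self.levels:
            raise ValueError(f"continuous feature {self.name!r} cannot have levels")

    @property
    def is_categorical(self) -> bool:
        return self.kind == "categorical"


class Schema:
    """Ordered collection of :class:`Feature` definitions."""

    def __init__(self, features: Iterable[Feature]):
        self.features = tuple(features)
        if not self.features:
            raise ValueError("schema needs at least one feature")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")
        self.names = tuple(names)
        self.is_categorical = np.array([f.is_categorical for f in self.features])

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, j: int) -> Feature:
        return self.features[j]

    def __eq__(self, other) -> bool:
        return isinstance(other, Schema) and self.features == other.features

    def n_levels(self, j: int) -> int:
        return len(self.features[j].levels)

    def to_dict(self) -> dict:
        return {
            f.name: (
                {"kind": f.kind, "levels": list(f.levels)}
                if f.is_categorical
                else {"kind": f.kind}
            )
            for f in self.features
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Schema":
        feats = []
        for name, desc in d.items():
            kind = desc["kind"]
            levels = tuple(str(v) for v in desc.get("levels", ()))
            feats.append(Feature(name, kind, levels))
        return cls(feats)


@dataclass
class Dataset:
    """An n×p table with missing markers (NaN) and a schema.

    ``values`` is float64 with categorical cells encoded as level codes.
    """

    values: np.ndarray
    schema: Schema

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise ValueError("dataset must have at least one row and one column")
        if p != len(self.schema):
            raise ValueError("schema length does not match number of columns")
        for j in np.flatnonzero(self.schema.is_categorical):
            col = self.values[:, j]
            obs = col[~np.isnan(col)]
            k = self.schema.n_levels(j)
            if obs.size and (
                np.any(obs != np.floor(obs)) or obs.min() < 0 or obs.max() >= k
            ):
                raise ValueError(
                    f"column {self.schema.names[j]!r} has codes outside its levels"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy(self) -> "Dataset":
        return Dataset(self.values.copy(), self.schema)

    # -- conversion ---------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: Schema | None = None) -> "Dataset":
        """Encode a DataFrame; kinds are inferred unless a schema is given.

        Inference: numeric dtypes are continuous, everything else categorical
        with levels = sorted distinct observed labels.
        """
        if schema is None:
            feats = []
            for name in df.columns:
                col = df[name]
                if pd.api.types.is_numeric_dtype(col) and not isinstance(
                    col.dtype, pd.CategoricalDtype
                ):
                    feats.append(Feature(str(name), "continuous"))
                else:
                    obs = col.dropna().astype(str)
                    levels = tuple(sorted(obs.unique()))
                    if not levels:
                        raise ValueError(f"column {name!r} is entirely missing")
                    feats.append(Feature(str(name), "categorical", levels))
            schema = Schema(feats)
        if list(df.columns.astype(str)) != list(schema.names):
            raise ValueError("DataFrame columns do not match schema names")
        n, p = df.shape
        X = np.empty((n, p), dtype=np.float64)
        for j, f in enumerate(schema):
            col = df.iloc[:, j]
            if f.is_categorical:
                code = {lev: i for i, lev in enumerate(f.levels)}
                out = np.full(n, np.nan)
                mask = col.notna().to_numpy()
                labels = col[col.notna()].astype(str)
                unknown = set(labels.unique()) - set(f.levels)
                if unknown:
                    raise ValueError(
                        f"column {f.name!r}: unknown categorical level(s) {sorted(unknown)}"
                    )
                out[mask] = [code[v] for v in labels]
                X[:, j] = out
            else:
                X[:, j] = pd.to_numeric(col, errors="raise").to_numpy(dtype=np.float64)
        return cls(X, schema)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {}
        for j, f in enumerate(self.schema):
            col = self.values[:, j]
            if f.is_categorical:
                out = pd.array(
                    [
                        f.levels[int(v)] if not np.isnan(v) else None
                        for v in col
                    ],
                    dtype="object",
                )
                cols[f.name] = out
            else:
                cols[f.name] = col
        return pd.DataFrame(cols)


def infer_schema_from_csv(path) -> Schema:
    df = _read_raw(path)
    return Dataset.from_dataframe(df).schema


def _read_raw(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        keep_default_na=False,
        na_values=["", MISSING_TOKEN],
        dtype=None,
        float_precision="round_trip",
    )
    if df.shape[0] == 0:
        raise ValueError("empty table")
    return df


def read_csv(path, schema: Schema | None = None) -> Dataset:
    """Read a CSV with header; empty fields and ``NA`` are missing markers."""
    df = _read_raw(path)
    if schema is not None:
        # Coerce label columns read as numeric back to strings for matching.
        for f in schema:
            if f.is_categorical and f.name in df.columns:
                col = df[f.name]
                df[f.name] = col.map(lambda v: _label(v) if pd.notna(v) else None)
    return Dataset.from_dataframe(df, schema)


def _label(v) -> str:
    if isinstance(v, float) and v == int(v):
        return str(int(v))
    return str(v)


def write_csv(data: Dataset, path, float_fmt: str = "%.17g") -> None:
    """Write a dataset back to CSV; missing cells become ``NA``."""
    df = data.to_dataframe()
    df.to_csv(path, index=False, na_rep=MISSING_TOKEN, float_format=float_fmt)


def check_no_all_missing(data: Dataset) -> None:
    all_missing = data.missing_mask.all(axis=0)
    if all_missing.any():
        bad = [data.schema.names[j] for j in np.flatnonzero(all_missing)]
        raise ValueError(f"column(s) entirely missing: {', '.join(bad)}")
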