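"""Complete-case mixed-type datasets and the transforms applied before fitting.

A :class:`MixedDataset` is a sample × variable table split into a continuous
block and a categorical block (level indices), with per-variable metadata in
:class:`VariableSpec`.  The model estimation requires a complete data matrix,
so every loader and constructor rejects missing entries outright.

Transform convention: log2 first (where requested), then per-variable
centering and scaling to standard units.  The (center, scale) pair estimated
on training data is recorded on each spec so the *same* affine map can be
applied to held-out data — test-set statistics are never used.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import one_hot

__all__ = [
    "VariableSpec",
    "MixedDataset",
    "load_dataset",
    "apply_transforms",
    "transform_like",
    "split_train_test",
    "count_variables",
]

LAYERS = ("clinical_chemistry", "demographic", "drug", "nmr", "other")


@dataclasses.dataclass
class VariableSpec:
    """Metadata for one variable: kind, categorical levels, layer, transform state."""

    name: str
    kind: str  # "continuous" | "categorical"
    levels: tuple[str, ...] = ()
    layer: str = "other"
    transform_log2: bool = False
    center: float | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"{self.name}: kind must be continuous or categorical")
        self.levels = tuple(str(l) for l in self.levels)
        if self.kind == "categorical":
            if len(self.levels) < 2:
                raise ValueError(f"{self.name}: categorical variables need >= 2 levels")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"{self.name}: duplicate level labels")
        elif self.levels:
            raise ValueError(f"{self.name}: continuous variables must not declare levels")
        if self.layer not in LAYERS:
            raise ValueError(f"{self.name}: unknown layer {self.layer!r}")
        if self.scale is not None and not self.scale > 0:
            raise ValueError(f"{self.name}: scale must be > 0")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


class MixedDataset:
    """Complete n × (p continuous + q categorical) dataset.

    ``specs`` fixes the global variable order; continuous and categorical
    values are stored in separate dense blocks in that relative order.
    """

    def __init__(
        self,
        specs: Sequence[VariableSpec],
        continuous_values: np.ndarray,
        categorical_values: np.ndarray,
        sample_ids: Sequence[str],
    ):
        self.specs = list(specs)
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        self.continuous_values = np.asarray(continuous_values, dtype=float)
        self.categorical_values = np.asarray(categorical_values, dtype=int)
        self.sample_ids = [str(s) for s in sample_ids]
        n = len(self.sample_ids)
        self.cont_specs = [s for s in self.specs if s.kind == "continuous"]
        self.cat_specs = [s for s in self.specs if s.kind == "categorical"]
        if self.continuous_values.shape != (n, len(self.cont_specs)):
            raise ValueError("continuous_values shape mismatch")
        if self.categorical_values.shape != (n, len(self.cat_specs)):
            raise ValueError("categorical_values shape mismatch")
        if self.continuous_values.size and not np.all(np.isfinite(self.continuous_values)):
            i, s = np.argwhere(~np.isfinite(self.continuous_values))[0]
            raise ValueError(
                f"missing/non-finite value at sample {self.sample_ids[i]!r}, "
                f"variable {self.cont_specs[s].name!r}"
            )
        for j, spec in enumerate(self.cat_specs):
            col = self.categorical_values[:, j]
            bad = np.where((col < 0) | (col >= spec.n_levels))[0]
            if bad.size:
                raise ValueError(
                    f"sample {self.sample_ids[bad[0]]!r}, variable {spec.name!r}: "
                    f"level index {col[bad[0]]} outside [0, {spec.n_levels})"
                )

    # ---- basic accessors ----------------------------------------------
    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def p(self) -> int:
        return len(self.cont_specs)

    @property
    def q(self) -> int:
        return len(self.cat_specs)

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(s.n_levels for s in self.cat_specs)

    def var_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def one_hot(self) -> np.ndarray:
        if not self.q:
            return np.zeros((self.n, 0))
        return one_hot(self.categorical_values, self.levels)

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def continuous_column(self, name: str) -> np.ndarray:
        idx = [s.name for s in self.cont_specs].index(name)
        return self.continuous_values[:, idx]

    def categorical_column(self, name: str) -> np.ndarray:
        idx = [s.name for s in self.cat_specs].index(name)
        return self.categorical_values[:, idx]

    def column(self, name: str) -> np.ndarray:
        """Numeric view of any variable (level indices for categoricals)."""
        s = self.spec(name)
        if s.kind == "continuous":
            return self.continuous_column(name)
        return self.categorical_column(name).astype(float)

    def take(self, rows: np.ndarray) -> "MixedDataset":
        rows = np.asarray(rows)
        return MixedDataset(
            [dataclasses.replace(s) for s in self.specs],
            self.continuous_values[rows],
            self.categorical_values[rows],
            [self.sample_ids[i] for i in rows],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(index=pd.Index(self.sample_ids, name="sample_id"))
        ci = ki = 0
        for s in self.specs:
            if s.kind == "continuous":
                df[s.name] = self.continuous_values[:, ci]
                ci += 1
            else:
                df[s.name] = [s.levels[v] for v in self.categorical_values[:, ki]]
                ki += 1
        return df

    def save(self, data_path: str | Path, meta_path: str | Path) -> None:
        sep_d = "\t" if str(data_path).endswith(".tsv") else ","
        sep_m = "\t" if str(meta_path).endswith(".tsv") else ","
        self.to_dataframe().to_csv(data_path, sep=sep_d)
        meta = pd.DataFrame(
            {
                "name": [s.name for s in self.specs],
                "kind": [s.kind for s in self.specs],
                "levels": ["|".join(s.levels) for s in self.specs],
                "layer": [s.layer for s in self.specs],
                "log2": [int(s.transform_log2) for s in self.specs],
            }
        )
        meta.to_csv(meta_path, sep=sep_m, index=False)


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def load_dataset(data_path: str | Path, meta_path: str | Path) -> MixedDataset:
    """Read data + metadata tables into a validated MixedDataset.

    The data table needs a header row and a sample-id column (``sample_id``
    if present, else the first column).  Variable order follows the metadata
    file.  Any missing cell, unknown level label, or variable present in one
    file but not the other is a hard error naming the offender.
    """
    meta = _read_table(meta_path)
    required = {"name", "kind"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata file must have columns {sorted(required)}")
    data = _read_table(data_path)
    id_col = "sample_id" if "sample_id" in data.columns else data.columns[0]
    sample_ids = data[id_col].astype(str).tolist()
    data = data.drop(columns=[id_col])

    specs: list[VariableSpec] = []
    for _, row in meta.iterrows():
        levels = ()
        if str(row["kind"]) == "categorical":
            raw = row.get("levels", "")
            if pd.isna(raw) or not str(raw):
                raise ValueError(f"variable {row['name']!r}: categorical without levels")
            levels = tuple(str(raw).split("|"))
        layer = str(row["layer"]) if "layer" in meta.columns and not pd.isna(row.get("layer")) else "other"
        log2 = bool(int(row["log2"])) if "log2" in meta.columns and not pd.isna(row.get("log2")) else False
        specs.append(VariableSpec(str(row["name"]), str(row["kind"]), levels, layer, log2))

    meta_names = [s.name for s in specs]
    missing_in_data = sorted(set(meta_names) - set(data.columns))
    extra_in_data = sorted(set(data.columns) - set(meta_names))
    if missing_in_data or extra_in_data:
        raise ValueError(
            f"variable sets differ: in metadata only {missing_in_data}, in data only {extra_in_data}"
        )

    n = len(sample_ids)
    X = np.zeros((n, sum(s.kind == "continuous" for s in specs)))
    Y = np.zeros((n, sum(s.kind == "categorical" for s in specs)), dtype=int)
    ci = ki = 0
    for s in specs:
        col = data[s.name]
        na = col.isna() | (col.astype(str).str.strip() == "")
        if na.any():
            i = int(np.argmax(na.values))
            raise ValueError(f"missing value at sample {sample_ids[i]!r}, variable {s.name!r}")
        if s.kind == "continuous":
            try:
                X[:, ci] = col.astype(float).values
            except ValueError as exc:
                raise ValueError(f"variable {s.name!r}: non-numeric value ({exc})") from None
            ci += 1
        else:
            lookup = {lab: i for i, lab in enumerate(s.levels)}
            vals = col.astype(str).values
            for i, v in enumerate(vals):
                if v not in lookup:
                    raise ValueError(
                        f"sample {sample_ids[i]!r}, variable {s.name!r}: "
                        f"level {v!r} not among declared levels {list(s.levels)}"
                    )
            Y[:, ki] = [lookup[v] for v in vals]
            ki += 1
    return MixedDataset(specs, X, Y, sample_ids)


def apply_transforms(
    d: MixedDataset,
    log2_vars: Iterable[str] = (),
    standardize: bool = True,
) -> MixedDataset:
    """Apply log2 (first) and standard-unit scaling, recording (center, scale).

    Standard deviation uses the n−1 denominator.  The estimated affine map is
    stored on each continuous VariableSpec so :func:`transform_like` can
    replay it on held-out data.
    """
    log2_vars = set(log2_vars)
    cont_names = {s.name for s in d.cont_specs}
    unknown = log2_vars - cont_names
    if unknown:
        raise ValueError(f"log2 requested for non-continuous/unknown variables: {sorted(unknown)}")
    X = d.continuous_values.copy()
    specs = [dataclasses.replace(s) for s in d.specs]
    cont = [s for s in specs if s.kind == "continuous"]
    for i, s in enumerate(cont):
        if s.name in log2_vars or s.transform_log2:
            if np.any(X[:, i] <= 0):
                bad = int(np.argmax(X[:, i] <= 0))
                raise ValueError(
                    f"log2 transform of {s.name!r}: non-positive value at sample "
                    f"{d.sample_ids[bad]!r}"
                )
            X[:, i] = np.log2(X[:, i])
            s.transform_log2 = True
        if standardize:
            c = float(X[:, i].mean())
            sd = float(X[:, i].std(ddof=1))
            if not sd > 0:
                raise ValueError(f"variable {s.name!r} is constant; cannot standardize")
            X[:, i] = (X[:, i] - c) / sd
            s.center, s.scale = c, sd
    return MixedDataset(specs, X, d.categorical_values.copy(), d.sample_ids)


def transform_like(d: MixedDataset, reference: MixedDataset | Sequence[VariableSpec]) -> MixedDataset:
    """Apply the transforms *stored* on reference specs to a raw dataset."""
    ref_specs = reference.specs if isinstance(reference, MixedDataset) else list(reference)
    by_name = {s.name: s for s in ref_specs}
    X = d.continuous_values.copy()
    specs = []
    ci = 0
    for s in d.specs:
        r = by_name.get(s.name)
        if r is None:
            raise ValueError(f"variable {s.name!r} not present in reference specs")
        if s.kind == "continuous":
            if r.transform_log2:
                if np.any(X[:, ci] <= 0):
                    raise ValueError(f"log2 transform of {s.name!r}: non-positive value")
                X[:, ci] = np.log2(X[:, ci])
            if r.center is not None:
                X[:, ci] = (X[:, ci] - r.center) / r.scale
            ci += 1
        specs.append(dataclasses.replace(r))
    return MixedDataset(specs, X, d.categorical_values.copy(), d.sample_ids)


def split_train_test(
    d: MixedDataset, train_fraction: float, seed: int
) -> tuple[MixedDataset, MixedDataset]:
    """Disjoint random row partition; training size floor(fraction · n).

    The floor is taken with a tiny tolerance so exact rational fractions
    survive floating point (2/3 of 3705 gives 2470, not 2469).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if d.n < 3:
        raise ValueError("need at least 3 samples to split")
    n_train = int(math.floor(train_fraction * d.n + 1e-9))
    n_train = min(max(n_train, 1), d.n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(d.n)
    return d.take(np.sort(perm[:n_train])), d.take(np.sort(perm[n_train:]))


def count_variables(specs: Sequence[VariableSpec]) -> tuple[int, int, int]:
    """(total, n_continuous, n_discrete) over a spec list."""
    nc = sum(s.kind == "continuous" for s in specs)
    nd = sum(s.kind == "categorical" for s in specs)
    return nc + nd, nc, nd
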