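"""Tabular survival datasets with explicit missingness.

The central container couples a mixed-type feature matrix (continuous,
binary, categorical-as-codes) with a per-row survival outcome
(``time_at_risk`` in days, ``event`` in {0, 1}).  Missing feature cells are
held as NaN; the survival outcome is always fully observed.  A
:class:`MissingnessMask` is the binary indicator grid R where ``R[i, j] = 1``
means cell (i, j) is hidden.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

SURVIVAL_COLUMNS = ("time_at_risk", "event")

#: tokens accepted as a missing cell on read (case-insensitive)
NA_TOKENS = ["", "NA", "na", "Na", "nA", "n.a.", "N.A.", "n.a", "N.A"]

KINDS = ("continuous", "binary", "categorical")


class SchemaError(ValueError):
    """Raised when a file or frame does not match the declared schema."""


@dataclass(frozen=True)
class ColumnSpec:
    """One feature column: its name, kind and (for categoricals) labels."""

    name: str
    kind: str
    categories: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown column kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical" and not self.categories:
            raise SchemaError(f"categorical column {self.name!r} needs categories")


@dataclass
class TabularDataset:
    """Feature matrix + survival outcome + missingness, with a fixed schema.

    Parameters
    ----------
    features : pandas.DataFrame
        n x p float frame; NaN marks a missing cell.  Categorical columns
        hold integer codes into their :class:`ColumnSpec` label list.
    survival : pandas.DataFrame or None
        Two columns ``time_at_risk`` (non-negative) and ``event`` ({0, 1}),
        never missing.  ``None`` for feature-only intermediates (e.g. sampled
        covariates before a survival simulation step).
    schema : sequence of ColumnSpec
        Ordered; must match ``features.columns``.
    meta : dict
        Provenance: generator label, seeds, augmentation markers.
    """

    features: pd.DataFrame
    survival: pd.DataFrame | None
    schema: list[ColumnSpec]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.features.shape[1] < 1 or self.features.shape[0] < 1:
            raise SchemaError("dataset needs at least one row and one feature")
        names = [c.name for c in self.schema]
        if names != list(self.features.columns):
            raise SchemaError(f"schema columns {names} != frame columns "
                              f"{list(self.features.columns)}")
        self.features = self.features.astype(float)
        for col in self.schema:
            if col.kind == "binary":
                vals = self.features[col.name].dropna().to_numpy()
                if not np.isin(vals, (0.0, 1.0)).all():
                    raise SchemaError(f"binary column {col.name!r} has values "
                                      "outside {0, 1}")
        if self.survival is not None:
            missing = [c for c in SURVIVAL_COLUMNS if c not in self.survival.columns]
            if missing:
                raise SchemaError(f"survival frame lacks columns {missing}")
            self.survival = self.survival[list(SURVIVAL_COLUMNS)].astype(float)
            if len(self.survival) != len(self.features):
                raise SchemaError("survival and features row counts differ")
            if self.survival.isna().any().any():
                raise SchemaError("survival columns must never be missing")
            if (self.survival["time_at_risk"] < 0).any():
                raise SchemaError("time_at_risk must be non-negative")
            ev = self.survival["event"].to_numpy()
            if not np.isin(ev, (0.0, 1.0)).all():
                raise SchemaError("event indicator must be 0/1")

    # -- basic views ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def p(self) -> int:
        return self.features.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def kind_of(self, name: str) -> str:
        for col in self.schema:
            if col.name == name:
                return col.kind
        raise KeyError(name)

    def is_missing(self) -> pd.DataFrame:
        return self.features.isna()

    def copy(self) -> "TabularDataset":
        return TabularDataset(
            features=self.features.copy(),
            survival=None if self.survival is None else self.survival.copy(),
            schema=list(self.schema),
            meta=dict(self.meta),
        )

    def with_features(self, features: pd.DataFrame) -> "TabularDataset":
        """Same outcome/schema/meta with a replaced feature frame."""
        out = dataclasses.replace(self, features=features.copy())
        return out

    def equals(self, other: "TabularDataset") -> bool:
        same_surv = (self.survival is None) == (other.survival is None)
        if same_surv and self.survival is not None:
            same_surv = self.survival.equals(other.survival)
        return (
            self.schema == other.schema
            and self.features.equals(other.features)
            and same_surv
        )


@dataclass
class MissingnessMask:
    """Binary hide-indicator grid aligned to a dataset's feature columns."""

    grid: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        if not np.isin(self.grid, (0, 1)).all():
            raise ValueError("mask entries must be 0/1")
        if self.grid.shape[1] != len(self.column_names):
            raise ValueError("mask width does not match its column names")
        self.grid = self.grid.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def column_means(self) -> pd.Series:
        return pd.Series(self.grid.mean(axis=0), index=self.column_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.grid, columns=self.column_names)


# -- mask algebra ---------------------------------------------------------

def extract_mask(dataset: TabularDataset) -> MissingnessMask:
    """R[i, j] = 1 exactly where cell (i, j) of the dataset is hidden."""
    return MissingnessMask(
        grid=dataset.features.isna().to_numpy().astype(np.int8),
        column_names=dataset.feature_names,
    )


def apply_mask(dataset: TabularDataset, mask: MissingnessMask) -> TabularDataset:
    """Hide the union of already-missing cells and ``mask == 1`` cells.

    Observed cells outside the mask are carried over unchanged; survival
    columns are never maskable.
    """
    if mask.shape != dataset.features.shape:
        raise ValueError(f"mask shape {mask.shape} != data shape "
                         f"{dataset.features.shape}")
    if mask.column_names != dataset.feature_names:
        if set(mask.column_names) & set(SURVIVAL_COLUMNS):
            raise ValueError("mask may not target survival columns")
        raise ValueError("mask columns do not match dataset feature columns")
    values = dataset.features.to_numpy(copy=True)
    values[mask.grid.astype(bool)] = np.nan
    out = dataset.copy()
    out.features = pd.DataFrame(values, columns=dataset.feature_names,
                                index=dataset.features.index)
    return out


# -- CSV / YAML I/O -------------------------------------------------------

def save_schema(schema: Sequence[ColumnSpec], path) -> None:
    doc = {c.name: ({"kind": c.kind, "categories": list(c.categories)}
                    if c.categories else c.kind)
           for c in schema}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_schema(path) -> list[ColumnSpec]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    schema = []
    for name, val in doc.items():
        if isinstance(val, str):
            schema.append(ColumnSpec(name, val))
        else:
            schema.append(ColumnSpec(name, val["kind"],
                                     tuple(val.get("categories") or ()) or None))
    return schema


def read_table(path, schema: Sequence[ColumnSpec]) -> TabularDataset:
    """Read a CSV (header row, ``NA``/``n.a.``/empty as missing) into a dataset.

    The file must contain every schema column plus the two survival columns.
    """
    frame = pd.read_csv(path, na_values=NA_TOKENS, keep_default_na=False)
    names = [c.name for c in schema]
    for col in SURVIVAL_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"file {path} lacks survival column {col!r}")
    missing_cols = [n for n in names if n not in frame.columns]
    if missing_cols:
        raise SchemaError(f"file {path} lacks feature columns {missing_cols}")
    feats = frame[names]
    for col in schema:
        if col.kind == "continuous":
            coerced = pd.to_numeric(feats[col.name], errors="coerce")
            bad = coerced.isna() & feats[col.name].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"non-numeric value in continuous column {col.name!r}, "
                    f"row {row}: {feats[col.name].iloc[row]!r}")
    feats = feats.apply(pd.to_numeric)
    surv = frame[list(SURVIVAL_COLUMNS)].apply(pd.to_numeric)
    if surv.isna().any().any():
        raise SchemaError("survival columns contain missing or non-numeric cells")
    return TabularDataset(features=feats, survival=surv, schema=list(schema),
                          meta={"source": str(path)})


def write_table(dataset: TabularDataset, path) -> str:
    """Write dataset to CSV with ``NA`` at missing cells; lossless round-trip."""
    if dataset.p < 1:
        raise SchemaError("refusing to write a dataset without feature columns")
    if dataset.survival is None:
        raise SchemaError("dataset has no survival outcome to write")
    frame = pd.concat([dataset.features, dataset.survival], axis=1)
    frame.to_csv(path, index=False, na_rep="NA")
    return str(path)


def write_mask(mask: MissingnessMask, path) -> str:
    mask.to_frame().to_csv(path, index=False)
    return str(path)


def read_mask(path) -> MissingnessMask:
    frame = pd.read_csv(path)
    return MissingnessMask(grid=frame.to_numpy(), column_names=list(frame.columns))


def make_schema(names: Iterable[str], kinds: Iterable[str] | str) -> list[ColumnSpec]:
    """Convenience: build a schema from parallel name/kind lists."""
    names = list(names)
    if isinstance(kinds, str):
        kinds = [kinds] * len(names)
    return [ColumnSpec(n, k) for n, k in zip(names, kinds, strict=True)]
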