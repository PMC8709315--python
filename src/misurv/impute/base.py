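"""Shared multiple-imputation protocol: result container, config, dispatch.

Every engine maps an incomplete :class:`~misurv.dataset.TabularDataset` to M
completed copies plus (for chained-equation engines) per-sweep traces of the
mean imputed value of each incomplete column, which feed the Gelman-Rubin
convergence diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..dataset import TabularDataset


@dataclass
class ImputerConfig:
    """Tuning knobs of all engines (each engine reads its own section)."""

    # chained equations
    iterations: int = 10
    pmm_donors: int = 5
    # bootstrap EM
    em_tol: float = 1e-6
    em_max_iter: int = 300
    em_ridge: float = 1e-8
    # iterative random forest
    rf_trees: int = 50
    rf_max_iter: int = 10
    # iterative PCA
    pca_grid: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    pca_cv_folds: int = 5
    pca_tol: float = 1e-7
    pca_max_iter: int = 500
    # GAIN
    gain_hint_rate: float = 0.9
    gain_alpha: float = 10.0
    gain_epochs: int = 200
    gain_batch: int = 128
    gain_lr: float = 5e-3
    # attentive tabular network
    tabnet_steps: int = 3
    tabnet_width: int = 8
    tabnet_sparsity: float = 1e-3
    tabnet_epochs: int = 100
    tabnet_batch: int = 256
    tabnet_lr: float = 0.02
    tabnet_lr_step: int = 10
    tabnet_lr_gamma: float = 0.9
    tabnet_patience: int = 10
    tabnet_val_fraction: float = 0.2
    tabnet_min_obs: int = 25

    def __post_init__(self):
        for name in ("iterations", "pmm_donors", "rf_trees", "rf_max_iter",
                     "gain_epochs", "gain_batch", "tabnet_steps",
                     "tabnet_width", "tabnet_epochs", "tabnet_batch",
                     "tabnet_lr_step", "tabnet_patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("gain_hint_rate", "tabnet_val_fraction"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")


TRACE_COLUMNS = ("chain", "iteration", "column", "mean_imputed")


def empty_traces() -> pd.DataFrame:
    return pd.DataFrame(columns=list(TRACE_COLUMNS))


@dataclass
class MultipleImputation:
    """M completed datasets from one imputation engine."""

    completed: list[TabularDataset]
    imputer_id: str
    traces: pd.DataFrame = field(default_factory=empty_traces)
    seed: int = 0
    M: int = 5

    def __post_init__(self):
        if len(self.completed) != self.M:
            raise ValueError("M does not match the number of completed copies")
        ref = self.completed[0]
        for ds in self.completed[1:]:
            if ds.feature_names != ref.feature_names or len(ds.features) != len(
                    ref.features):
                raise ValueError("completed copies disagree on schema/rows")

    @property
    def poolable(self) -> bool:
        return self.M >= 2


def check_input(dataset: TabularDataset) -> None:
    fully_missing = dataset.features.columns[dataset.features.isna().all()]
    if len(fully_missing):
        raise ValueError(
            f"column(s) entirely missing, cannot impute: {list(fully_missing)}")


def passthrough(dataset: TabularDataset, imputer_id: str, M: int,
                seed: int) -> MultipleImputation:
    """Complete input: every engine returns M identical copies."""
    return MultipleImputation(completed=[dataset.copy() for _ in range(M)],
                              imputer_id=imputer_id, seed=seed, M=M)


def restore_observed(completed_values: np.ndarray,
                     dataset: TabularDataset) -> pd.DataFrame:
    """Overwrite observed cells with the original values, verbatim."""
    orig = dataset.features.to_numpy()
    obs = ~np.isnan(orig)
    out = np.asarray(completed_values, dtype=float).copy()
    out[obs] = orig[obs]
    return pd.DataFrame(out, columns=dataset.feature_names,
                        index=dataset.features.index)


def finish_copy(dataset: TabularDataset, values: np.ndarray) -> TabularDataset:
    feats = restore_observed(values, dataset)
    return TabularDataset(feats, None if dataset.survival is None
                          else dataset.survival.copy(),
                          list(dataset.schema), dict(dataset.meta))


def snap_to_observed_categories(values: np.ndarray, dataset: TabularDataset
                                ) -> np.ndarray:
    """Project binary/categorical columns onto their observed value sets."""
    out = values.copy()
    for j, col in enumerate(dataset.schema):
        if col.kind == "continuous":
            continue
        observed = np.unique(dataset.features[col.name].dropna().to_numpy())
        if len(observed) == 0:
            continue
        dist = np.abs(out[:, j][:, None] - observed[None, :])
        out[:, j] = observed[np.argmin(dist, axis=1)]
    return out


def visit_order(dataset: TabularDataset) -> list[str]:
    """Incomplete columns sorted by increasing missing fraction."""
    frac = dataset.features.isna().mean()
    cols = [c for c in dataset.feature_names if frac[c] > 0]
    return sorted(cols, key=lambda c: (frac[c], dataset.feature_names.index(c)))


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31, deterministic in ``seed``."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


# registry filled by the engine modules
ENGINES: dict[str, object] = {}


def register(name: str):
    def deco(fn):
        ENGINES[name] = fn
        return fn
    return deco


def impute(dataset: TabularDataset, method: str,
           config: ImputerConfig | None = None, M: int = 5,
           seed: int = 0) -> MultipleImputation:
    """Dispatch to one of the six engines by id.

    Engine ids: ``pmm``, ``em``, ``rf``, ``pca``, ``gain``, ``mitabnet``.
    A complete input short-circuits to M identical copies for every engine.
    """
    from . import em, forest, gain, pca, pmm, tabnet  # noqa: F401  (register)
    if method not in ENGINES:
        raise KeyError(f"unknown imputation method {method!r}; "
                       f"available: {sorted(ENGINES)}")
    check_input(dataset)
    config = config or ImputerConfig()
    if not dataset.features.isna().any().any():
        return passthrough(dataset, method, M, seed)
    return ENGINES[method](dataset, config, M, seed)
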