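"""Iterative random-forest imputation (missForest scheme), M seeds deep.

Initialise missing cells with column means (modes for categoricals); then
cycle through incomplete columns in order of increasing missingness, fitting
a random forest of each column on all others over its observed rows and
predicting its missing rows.  Iteration stops the first time the difference
statistic between successive imputations increases (the imputation *before*
the increase is returned) or at the iteration cap.  Multiple imputations are
M independent runs with distinct seeds.
"""

from __future__ import annotations

import numpy as np

from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from ..dataset import TabularDataset
from .base import (ImputerConfig, MultipleImputation, finish_copy, register,
                   spawn_seeds, visit_order)


def _diff_stat(new: np.ndarray, old: np.ndarray, cont: np.ndarray,
               cat: np.ndarray) -> float:
    """missForest difference: normalised squared change (continuous) plus
    disagreement rate (categorical)."""
    stat = 0.0
    if cont.any():
        denom = float((new[:, cont] ** 2).sum())
        stat += float(((new[:, cont] - old[:, cont]) ** 2).sum()) / max(denom,
                                                                        1e-12)
    if cat.any():
        stat += float((new[:, cat] != old[:, cat]).mean())
    return stat


def _single_run(dataset: TabularDataset, config: ImputerConfig, seed: int
                ) -> np.ndarray:
    rng = np.random.default_rng(seed)
    X = dataset.features.to_numpy(copy=True)
    miss = np.isnan(X)
    names = dataset.feature_names
    kinds = {c.name: c.kind for c in dataset.schema}
    cont = np.array([kinds[c] == "continuous" for c in names])
    cat = ~cont
    # mean / mode start
    for j, c in enumerate(names):
        col = X[:, j]
        if not miss[:, j].any():
            continue
        obs = col[~miss[:, j]]
        if cont[j]:
            col[miss[:, j]] = obs.mean()
        else:
            vals, counts = np.unique(obs, return_counts=True)
            col[miss[:, j]] = vals[np.argmax(counts)]
    order = [names.index(c) for c in visit_order(dataset)]
    prev = X.copy()
    prev_stat = np.inf
    for _ in range(config.rf_max_iter):
        for j in order:
            others = np.delete(np.arange(X.shape[1]), j)
            obs = ~miss[:, j]
            rs = int(rng.integers(0, 2 ** 31 - 1))
            if cont[j]:
                model = RandomForestRegressor(n_estimators=config.rf_trees,
                                              random_state=rs, n_jobs=1)
            else:
                model = RandomForestClassifier(n_estimators=config.rf_trees,
                                               random_state=rs, n_jobs=1)
            model.fit(X[np.ix_(obs, others)], X[obs, j])
            X[miss[:, j], j] = model.predict(X[np.ix_(miss[:, j], others)])
        stat = _diff_stat(X, prev, cont & miss.any(axis=0),
                          cat & miss.any(axis=0))
        if stat >= prev_stat:
            return prev        # last imputation before the criterion rose
        prev, prev_stat = X.copy(), stat
    return X


@register("rf")
def rf_iterative(dataset: TabularDataset, config: ImputerConfig, M: int,
                 seed: int) -> MultipleImputation:
    seeds = spawn_seeds(seed, M)
    completed = [finish_copy(dataset, _single_run(dataset, config, s))
                 for s in seeds]
    return MultipleImputation(completed=completed, imputer_id="rf",
                              seed=seed, M=M)
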