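"""Bootstrap-EM multiple imputation under a joint multivariate normal.

Each of the M imputations resamples rows with replacement, runs EM to the
maximum-likelihood mean/covariance of the resampled incomplete data, and then
draws the original dataset's missing cells from the conditional normal given
the observed cells under those resample-specific parameters.  Binary and
categorical columns ride along as numeric and are snapped to the nearest
observed category afterwards.
"""

from __future__ import annotations

import numpy as np

from .._mvnem import conditional_normal_draw, em_mvn
from ..dataset import TabularDataset
from .base import (ImputerConfig, MultipleImputation, finish_copy, register,
                   snap_to_observed_categories, spawn_seeds)


@register("em")
def em_bootstrap(dataset: TabularDataset, config: ImputerConfig, M: int,
                 seed: int) -> MultipleImputation:
    seeds = spawn_seeds(seed, M)
    X = dataset.features.to_numpy(dtype=float)
    n = len(X)
    completed = []
    for m in range(M):
        rng = np.random.default_rng(seeds[m])
        boot = X[rng.integers(0, n, size=n)]
        # a bootstrap resample can drop every observed value of a column;
        # redraw a few times before giving up
        for _ in range(20):
            if not np.isnan(boot).all(axis=0).any():
                break
            boot = X[rng.integers(0, n, size=n)]
        mu, sigma, _, _ = em_mvn(boot, max_iter=config.em_max_iter,
                                 tol=config.em_tol, ridge=config.em_ridge,
                                 raise_on_nonconvergence=True)
        filled = np.vstack([conditional_normal_draw(row, mu, sigma, rng)
                            for row in X])
        filled = snap_to_observed_categories(filled, dataset)
        completed.append(finish_copy(dataset, filled))
    return MultipleImputation(completed=completed, imputer_id="em",
                              seed=seed, M=M)
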