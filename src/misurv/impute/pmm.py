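"""Predictive mean matching within chained equations (Gibbs-style sampler).

Each chain initialises missing cells with random draws from the observed
values of their column, then sweeps the incomplete columns (in order of
increasing missingness).  Per column a Bayesian-perturbed linear model of the
column on all other columns is fitted on the observed rows; missing rows are
matched to a small pool of observed donors with the closest predicted mean
and imputed with the donor's *observed* value — so imputations always belong
to the column's observed support.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ..dataset import TabularDataset
from .base import (ImputerConfig, MultipleImputation, TRACE_COLUMNS,
                   finish_copy, register, spawn_seeds, visit_order)


def _bayes_linear_draw(Z: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                       ridge: float = 1e-6):
    """OLS fit plus a posterior-style perturbation draw of (beta, sigma2)."""
    n, q = Z.shape
    G = Z.T @ Z
    G[np.diag_indices_from(G)] += ridge * (np.trace(G) / q + 1.0)
    Ginv = np.linalg.inv(G)
    beta_hat = Ginv @ (Z.T @ y)
    resid = y - Z @ beta_hat
    dof = max(n - q, 1)
    sigma2_hat = float(resid @ resid) / dof
    sigma2_star = sigma2_hat * dof / max(rng.chisquare(dof), 1e-12)
    L = np.linalg.cholesky((Ginv + Ginv.T) / 2 +
                           1e-12 * np.eye(q))
    beta_star = beta_hat + np.sqrt(sigma2_star) * (L @ rng.standard_normal(q))
    return beta_hat, beta_star


def _pmm_column(X: np.ndarray, j: int, miss_j: np.ndarray, donors: int,
                rng: np.random.Generator) -> np.ndarray:
    """Impute column j of the current completed matrix by donor matching."""
    obs = ~miss_j
    others = np.delete(np.arange(X.shape[1]), j)
    Z = np.column_stack([np.ones(X.shape[0]), X[:, others]])
    y_obs = X[obs, j]
    beta_hat, beta_star = _bayes_linear_draw(Z[obs], y_obs, rng)
    yhat_obs = Z[obs] @ beta_hat
    yhat_mis = Z[miss_j] @ beta_star
    d = min(donors, obs.sum())
    if d < donors:
        warnings.warn(f"donor pool shrunk to {d} (few observed rows)")
    # nearest-predicted-mean donors via a sorted window (avoids the full
    # n_mis x n_obs distance matrix)
    order = np.argsort(yhat_obs, kind="stable")
    ys = yhat_obs[order]
    n_obs = len(ys)
    pos = np.searchsorted(ys, yhat_mis)
    lo = np.clip(pos - d, 0, max(n_obs - 2 * d, 0))
    window = lo[:, None] + np.arange(2 * d)[None, :]
    window = np.minimum(window, n_obs - 1)
    dist = np.abs(ys[window] - yhat_mis[:, None])
    pool = np.argpartition(dist, d - 1, axis=1)[:, :d]
    rows = np.arange(len(yhat_mis))
    pick = window[rows[:, None], pool][rows, rng.integers(0, d,
                                                          size=len(yhat_mis))]
    return y_obs[order[pick]]


def _run_chain(dataset: TabularDataset, config: ImputerConfig, chain: int,
               seed: int):
    rng = np.random.default_rng(seed)
    X = dataset.features.to_numpy(copy=True)
    miss = np.isnan(X)
    names = dataset.feature_names
    order = visit_order(dataset)
    idx = {c: names.index(c) for c in order}
    # step 1: random draws from the observed values of each column
    for c in order:
        j = idx[c]
        obs_vals = X[~miss[:, j], j]
        X[miss[:, j], j] = rng.choice(obs_vals, size=miss[:, j].sum(),
                                      replace=True)
    rows = []
    for it in range(config.iterations):
        for c in order:
            j = idx[c]
            X[miss[:, j], j] = _pmm_column(X, j, miss[:, j],
                                           config.pmm_donors, rng)
            rows.append((chain, it, c, float(X[miss[:, j], j].mean())))
    return X, rows


@register("pmm")
def pmm_mice(dataset: TabularDataset, config: ImputerConfig, M: int,
             seed: int) -> MultipleImputation:
    seeds = spawn_seeds(seed, M)
    completed, trace_rows = [], []
    for m in range(M):
        X, rows = _run_chain(dataset, config, m, seeds[m])
        completed.append(finish_copy(dataset, X))
        trace_rows.extend(rows)
    traces = pd.DataFrame(trace_rows, columns=list(TRACE_COLUMNS))
    return MultipleImputation(completed=completed, imputer_id="pmm",
                              traces=traces, seed=seed, M=M)
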