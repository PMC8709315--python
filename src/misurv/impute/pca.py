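"""Regularised iterative PCA imputation with bootstrap multiple imputations.

Mixed-data factorial style: every column is centred and scaled by its
observed standard deviation (for 0/1 indicators this is the two-level
factorial scaling), missing cells start at the column mean, and the
algorithm alternates a low-rank truncated SVD with shrunken singular values
and re-prediction of the missing cells until the fitted values stabilise.
The number of components is chosen by cell-wise K-fold cross-validation.
Multiple imputations re-estimate the model on nonparametric row bootstraps
and add residual noise to the imputed cells.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..dataset import TabularDataset
from .base import (ImputerConfig, MultipleImputation, finish_copy, register,
                   snap_to_observed_categories, spawn_seeds)


def _scale_params(X: np.ndarray):
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd[sd < 1e-12] = 1.0
    return mu, sd


def _shrunken_fit(Z: np.ndarray, ncomp: int, obs: np.ndarray) -> np.ndarray:
    """Low-rank reconstruction with regularised (shrunken) singular values.

    The noise level driving the shrinkage is estimated from the observed-cell
    residuals of the plain rank-``ncomp`` fit, so it vanishes (and the fit
    becomes exact) on noise-free low-rank data.
    """
    if ncomp == 0:
        return np.zeros_like(Z)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    plain = (U[:, :ncomp] * s[:ncomp]) @ Vt[:ncomp]
    resid = (Z - plain)[obs]
    sigma2 = float((resid ** 2).mean()) if resid.size else 0.0
    sigma2_total = sigma2 * Z.shape[0]       # per-singular-value scale
    s_shrunk = np.maximum((s[:ncomp] ** 2 - sigma2_total)
                          / np.maximum(s[:ncomp], 1e-12), 0.0)
    return (U[:, :ncomp] * s_shrunk) @ Vt[:ncomp]


def iterative_pca_impute(X: np.ndarray, ncomp: int, tol: float = 1e-7,
                         max_iter: int = 500):
    """Complete an incomplete matrix by regularised iterative PCA.

    Returns ``(completed, model)`` where ``model`` carries the column
    means/scales, the rank, the loadings of the final fit and the residual
    standard deviation on observed cells (in scaled units).
    """
    X = np.asarray(X, dtype=float)
    miss = np.isnan(X)
    mu, sd = _scale_params(X)
    Z = (X - mu) / sd
    Z[miss] = 0.0
    obs = ~miss
    prev_fit = np.zeros_like(Z)
    center = np.zeros(X.shape[1])
    for _ in range(max_iter):
        # the column center is re-estimated from the completed matrix each
        # sweep; a fixed observed-cell center leaves a rank-breaking offset
        center = Z.mean(axis=0)
        fit = center + _shrunken_fit(Z - center, ncomp, obs)
        Z[miss] = fit[miss]
        delta = np.abs(fit - prev_fit).max()
        prev_fit = fit
        if delta < tol:
            break
    if ncomp > 0:
        _, _, Vt = np.linalg.svd(Z - center, full_matrices=False)
        V = Vt[:ncomp].T
    else:
        V = np.zeros((X.shape[1], 0))
    resid = (Z - prev_fit)[~miss]
    model = {"mu": mu, "sd": sd, "ncomp": ncomp, "V": V, "center": center,
             "resid_sd": float(np.sqrt(np.mean(resid ** 2))) if resid.size
             else 0.0}
    return Z * sd + mu, model


def choose_ncomp(X: np.ndarray, grid, folds: int, rng: np.random.Generator,
                 tol: float = 1e-5, max_iter: int = 200) -> int:
    """Cell-wise K-fold CV: hide observed cells, impute, score squared error."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    grid = sorted({g for g in grid if g <= min(n, p) - 1})
    if not grid:
        grid = [0]
    obs_idx = np.argwhere(~np.isnan(X))
    fold_of = rng.integers(0, folds, size=len(obs_idx))
    errors = {g: 0.0 for g in grid}
    for f in range(folds):
        hide = obs_idx[fold_of == f]
        if len(hide) == 0:
            continue
        Xf = X.copy()
        Xf[hide[:, 0], hide[:, 1]] = np.nan
        if np.isnan(Xf).all(axis=0).any():
            continue
        for g in grid:
            comp, _ = iterative_pca_impute(Xf, g, tol=tol, max_iter=max_iter)
            err = comp[hide[:, 0], hide[:, 1]] - X[hide[:, 0], hide[:, 1]]
            errors[g] += float((err ** 2).sum())
    return min(grid, key=lambda g: errors[g])


@register("pca")
def pca_iterative(dataset: TabularDataset, config: ImputerConfig, M: int,
                  seed: int) -> MultipleImputation:
    X = dataset.features.to_numpy(dtype=float)
    n, p = X.shape
    grid = [g for g in config.pca_grid if g <= p - 1]
    if len(grid) < len(config.pca_grid):
        warnings.warn("component grid truncated to p - 1")
        grid = grid or [0]
    seeds = spawn_seeds(seed, M + 1)
    rng = np.random.default_rng(seeds[-1])
    ncomp = choose_ncomp(X, grid, config.pca_cv_folds, rng)
    miss = np.isnan(X)
    completed = []
    for m in range(M):
        rng_m = np.random.default_rng(seeds[m])
        boot = X[rng_m.integers(0, n, size=n)]
        for _ in range(20):
            if not np.isnan(boot).all(axis=0).any():
                break
            boot = X[rng_m.integers(0, n, size=n)]
        _, model = iterative_pca_impute(boot, ncomp, tol=config.pca_tol,
                                        max_iter=config.pca_max_iter)
        Z = (X - model["mu"]) / model["sd"]
        center = model["center"]
        Z[miss] = center[np.nonzero(miss)[1]]
        V = model["V"]
        for _ in range(50):
            fit = center + ((Z - center) @ V) @ V.T if V.shape[1] \
                else np.broadcast_to(center, Z.shape)
            new = fit[miss]
            converged = np.abs(new - Z[miss]).max() < config.pca_tol
            Z[miss] = new
            if converged:
                break
        Z[miss] += model["resid_sd"] * rng_m.standard_normal(int(miss.sum()))
        filled = Z * model["sd"] + model["mu"]
        filled = snap_to_observed_categories(filled, dataset)
        completed.append(finish_copy(dataset, filled))
    return MultipleImputation(completed=completed, imputer_id="pca",
                              seed=seed, M=M)
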