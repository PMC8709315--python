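"""EM estimation of a multivariate normal from incomplete data.

Shared machinery for the bootstrap-EM imputer and the MCAR test: maximum
likelihood mean/covariance of an n x p matrix with NaN cells, computed by
sweeping unique missingness patterns (vectorised per pattern).
"""

from __future__ import annotations

import warnings

import numpy as np


class EMConvergenceError(RuntimeError):
    def __init__(self, msg, trace):
        super().__init__(msg)
        self.trace = trace


def _pattern_groups(miss: np.ndarray):
    """Group row indices by identical missingness pattern."""
    view = np.ascontiguousarray(miss).view(
        np.dtype((np.void, miss.dtype.itemsize * miss.shape[1])))
    _, inverse = np.unique(view.ravel(), return_inverse=True)
    groups = {}
    for g in np.unique(inverse):
        groups[g] = np.flatnonzero(inverse == g)
    return [(miss[idx[0]], idx) for idx in groups.values()]


def em_mvn(X: np.ndarray, max_iter: int = 200, tol: float = 1e-6,
           ridge: float = 1e-8, raise_on_nonconvergence: bool = True):
    """ML mean and covariance of an incomplete-data multivariate normal.

    E-step fills conditional expectations E[x_mis | x_obs] and adds the
    conditional covariance to the second-moment accumulator; M-step updates
    (mu, Sigma).  Iterates until the observed-data log-likelihood changes by
    less than ``tol`` (relative).  Near-singular observed blocks get a ridge
    bump with a warning.

    Returns
    -------
    mu : (p,) ndarray
    sigma : (p, p) ndarray
    n_iter : int
    loglik : list of float, observed-data log-likelihood per iteration
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    miss = np.isnan(X)
    if miss.all(axis=0).any():
        raise ValueError("a column is entirely missing; EM cannot identify it")

    # start from available-case moments
    mu = np.nanmean(X, axis=0)
    Xc = np.where(miss, mu, X) - mu
    sigma = Xc.T @ Xc / max(n - 1, 1)
    sigma[np.diag_indices_from(sigma)] += ridge

    patterns = _pattern_groups(miss)
    loglik: list[float] = []
    for it in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        ll = 0.0
        for pat, idx in patterns:
            obs = ~pat
            Xg = X[idx]
            k = obs.sum()
            if k == 0:
                # nothing observed: contribution is the prior moments
                sum_x += len(idx) * mu
                sum_xx += len(idx) * (sigma + np.outer(mu, mu))
                continue
            Soo = sigma[np.ix_(obs, obs)]
            try:
                Loo = np.linalg.cholesky(Soo)
            except np.linalg.LinAlgError:
                warnings.warn("singular observed block; ridge-regularised")
                Soo = Soo + 1e-6 * np.eye(k)
                Loo = np.linalg.cholesky(Soo)
            dev = Xg[:, obs] - mu[obs]
            half = np.linalg.solve(Loo, dev.T)          # k x m
            ll += (-0.5 * (half ** 2).sum()
                   - len(idx) * (np.log(np.diag(Loo)).sum()
                                 + 0.5 * k * np.log(2 * np.pi)))
            filled = Xg.copy()
            cond_cov_full = np.zeros((p, p))
            if pat.any():
                Smo = sigma[np.ix_(pat, obs)]
                coef = np.linalg.solve(Loo.T, np.linalg.solve(Loo, Smo.T)).T
                filled[:, pat] = mu[pat] + dev @ coef.T
                cond = sigma[np.ix_(pat, pat)] - coef @ Smo.T
                cond_cov_full[np.ix_(pat, pat)] = cond
            sum_x += filled.sum(axis=0)
            sum_xx += filled.T @ filled + len(idx) * cond_cov_full
        mu_new = sum_x / n
        sigma_new = sum_xx / n - np.outer(mu_new, mu_new)
        sigma_new = (sigma_new + sigma_new.T) / 2
        sigma_new[np.diag_indices_from(sigma_new)] += ridge
        mu, sigma = mu_new, sigma_new
        loglik.append(ll)
        if it > 0 and abs(loglik[-1] - loglik[-2]) < tol * (abs(loglik[-2]) + 1):
            return mu, sigma, it + 1, loglik
    if raise_on_nonconvergence:
        raise EMConvergenceError(
            f"EM did not converge in {max_iter} iterations", loglik)
    return mu, sigma, max_iter, loglik


def conditional_normal_draw(x_row: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
                            rng: np.random.Generator) -> np.ndarray:
    """Draw missing entries of one row from N(mu, sigma) given its observed ones."""
    miss = np.isnan(x_row)
    out = x_row.copy()
    if not miss.any():
        return out
    obs = ~miss
    if not obs.any():
        out[:] = rng.multivariate_normal(mu, sigma, method="cholesky")
        return out
    Soo = sigma[np.ix_(obs, obs)]
    Smo = sigma[np.ix_(miss, obs)]
    coef = np.linalg.solve(Soo, Smo.T).T
    cond_mu = mu[miss] + coef @ (x_row[obs] - mu[obs])
    cond_cov = sigma[np.ix_(miss, miss)] - coef @ Smo.T
    cond_cov = (cond_cov + cond_cov.T) / 2
    w, V = np.linalg.eigh(cond_cov)
    w = np.clip(w, 0, None)
    z = rng.standard_normal(miss.sum())
    out[miss] = cond_mu + V @ (np.sqrt(w) * z)
    return out
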