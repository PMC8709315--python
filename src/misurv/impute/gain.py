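"""Generative adversarial imputation (generator vs. mask-predicting critic).

The generator receives the min-max-normalised data with missing entries
replaced by small uniform noise, together with the observedness matrix, and
emits a completed matrix.  The discriminator receives the completed matrix
plus a hint matrix (a fraction of the true observedness revealed at random)
and predicts, cell-wise, which entries were observed.  The discriminator
minimises cross-entropy on the observedness; the generator minimises the
fooling loss on imputed cells plus ``alpha`` times a reconstruction loss on
observed cells.  M imputations are drawn after training with M independent
noise inputs; observed cells are restored verbatim.
"""

from __future__ import annotations

import numpy as np

from ..dataset import TabularDataset
from ._nn import Adam, Sigmoid, mlp
from .base import (ImputerConfig, MultipleImputation, finish_copy, register,
                   snap_to_observed_categories, spawn_seeds)

_EPS = 1e-8


class GainDivergenceError(RuntimeError):
    """Loss became non-finite; retry with a smaller learning rate."""


def _normalise(X):
    lo = np.nanmin(X, axis=0)
    hi = np.nanmax(X, axis=0)
    span = np.where(hi - lo < 1e-12, 1.0, hi - lo)
    return (X - lo) / span, lo, span


@register("gain")
def gain_train_impute(dataset: TabularDataset, config: ImputerConfig, M: int,
                      seed: int) -> MultipleImputation:
    X_raw = dataset.features.to_numpy(dtype=float)
    n, p = X_raw.shape
    if n < config.gain_batch:
        batch = max(2, n)
    else:
        batch = config.gain_batch
    Xn, lo, span = _normalise(X_raw)
    m = (~np.isnan(Xn)).astype(float)            # 1 = observed
    Xn = np.nan_to_num(Xn)
    rng = np.random.default_rng(spawn_seeds(seed, 1)[0])

    G = mlp(rng, [2 * p, p, p, p], out_activation=Sigmoid())
    D = mlp(rng, [2 * p, p, p, p], out_activation=Sigmoid())
    optG = Adam(G.params, G.grads, lr=config.gain_lr)
    optD = Adam(D.params, D.grads, lr=config.gain_lr)

    n_batches = max(1, n // batch)
    for epoch in range(config.gain_epochs):
        perm = rng.permutation(n)
        for bi in range(n_batches):
            idx = perm[bi * batch:(bi + 1) * batch]
            xb, mb = Xn[idx], m[idx]
            z = rng.uniform(0, 0.01, size=xb.shape)
            x_tilde = mb * xb + (1 - mb) * z
            b = (rng.uniform(size=xb.shape) < config.gain_hint_rate)
            hint = b * mb + 0.5 * (1 - b)

            # --- discriminator update
            G.zero_grads()
            x_hat = G.forward(np.concatenate([x_tilde, mb], axis=1))
            x_comb = mb * xb + (1 - mb) * x_hat
            D.zero_grads()
            d_prob = D.forward(np.concatenate([x_comb, hint], axis=1))
            d_loss = -np.mean(mb * np.log(d_prob + _EPS)
                              + (1 - mb) * np.log(1 - d_prob + _EPS))
            if not np.isfinite(d_loss):
                raise GainDivergenceError(
                    "discriminator loss diverged; lower gain_lr")
            g_out = -(mb / (d_prob + _EPS)
                      - (1 - mb) / (1 - d_prob + _EPS)) / d_prob.size
            D.backward(g_out)
            optD.step()

            # --- generator update (fresh forward through both nets)
            G.zero_grads()
            x_hat = G.forward(np.concatenate([x_tilde, mb], axis=1))
            x_comb = mb * xb + (1 - mb) * x_hat
            D.zero_grads()
            d_prob = D.forward(np.concatenate([x_comb, hint], axis=1))
            fool = -np.mean((1 - mb) * np.log(d_prob + _EPS))
            recon = np.sum(mb * (xb - x_hat) ** 2) / max(mb.sum(), 1.0)
            g_loss = fool + config.gain_alpha * recon
            if not np.isfinite(g_loss):
                raise GainDivergenceError(
                    "generator loss diverged; lower gain_lr")
            d_in_grad = D.backward(
                -((1 - mb) / (d_prob + _EPS)) / d_prob.size)
            g_from_d = d_in_grad[:, :p] * (1 - mb)
            g_recon = config.gain_alpha * (-2.0 * mb * (xb - x_hat)
                                           / max(mb.sum(), 1.0))
            G.backward(g_from_d + g_recon)
            optG.step()

    seeds = spawn_seeds(seed + 1, M)
    completed = []
    for sm in seeds:
        rng_m = np.random.default_rng(sm)
        z = rng_m.uniform(0, 0.01, size=Xn.shape)
        x_tilde = m * Xn + (1 - m) * z
        x_hat = G.forward(np.concatenate([x_tilde, m], axis=1))
        filled = (m * Xn + (1 - m) * x_hat) * span + lo
        filled = snap_to_observed_categories(filled, dataset)
        completed.append(finish_copy(dataset, filled))
    return MultipleImputation(completed=completed, imputer_id="gain",
                              seed=seed, M=M)
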