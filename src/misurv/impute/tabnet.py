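"""Chained-equations multiple imputation with an attentive tabular network.

Each chain starts by filling every missing cell with a random draw from the
observed values of its column.  Sweeps then cycle through the incomplete
columns; per column the rows with an observed target are split 80:20 into
train/validation sets and a small attentive tabular network is trained to
predict the column from all other columns.  The network runs a fixed number
of sequential decision steps — feature-transformer block, attentive
soft feature mask, feature-transformer block — whose outputs are summed into
a linear head; the loss is mean squared error for continuous targets and
cross-entropy for binary/categorical ones, plus an entropy sparsity penalty
on the attention masks.  Optimisation uses Adam with a step-decay learning
rate and early stopping on the validation loss.  The trained network's plain
predictions overwrite the missing cells; multiplicity comes from M
independent chains with distinct random initial fills.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ..dataset import TabularDataset
from ._nn import Adam, _glorot, softmax
from .base import (ImputerConfig, MultipleImputation, TRACE_COLUMNS,
                   finish_copy, register, spawn_seeds, visit_order)

_EPS = 1e-9


class AttentiveTabularNet:
    """Sequential-attention tabular network with a linear head.

    Step i: h1 = relu(X W1 + b1); attention a = softmax(h1 Wa + ba) over the
    p input features; masked input m = a * X; h2 = relu(m W2 + b2).  The step
    outputs h2 are summed and mapped by a linear head to one regression
    output or K class logits.
    """

    def __init__(self, rng, p, n_steps=3, width=8, n_out=1,
                 sparsity=1e-3):
        self.p, self.n_steps, self.width = p, n_steps, width
        self.n_out, self.sparsity = n_out, sparsity
        self.steps = []
        for _ in range(n_steps):
            self.steps.append({
                "W1": _glorot(rng, p, width), "b1": np.zeros(width),
                "Wa": _glorot(rng, width, p), "ba": np.zeros(p),
                "W2": _glorot(rng, p, width), "b2": np.zeros(width),
            })
        self.Wh = _glorot(rng, width, n_out)
        self.bh = np.zeros(n_out)
        self._zero_grads()

    # -- parameter plumbing ------------------------------------------------
    def parameters(self):
        out = []
        for s in self.steps:
            out.extend([s["W1"], s["b1"], s["Wa"], s["ba"], s["W2"], s["b2"]])
        out.extend([self.Wh, self.bh])
        return out

    def gradients(self):
        out = []
        for g in self._step_grads:
            out.extend([g["W1"], g["b1"], g["Wa"], g["ba"], g["W2"], g["b2"]])
        out.extend([self.gWh, self.gbh])
        return out

    def _zero_grads(self):
        self._step_grads = [
            {k: np.zeros_like(v) for k, v in s.items()} for s in self.steps]
        self.gWh = np.zeros_like(self.Wh)
        self.gbh = np.zeros_like(self.bh)

    def get_weights(self):
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights):
        for p, w in zip(self.parameters(), weights):
            p[...] = w

    # -- forward / backward ------------------------------------------------
    def forward(self, X):
        self._X = X
        self._cache = []
        agg = np.zeros((X.shape[0], self.width))
        for s in self.steps:
            h1p = X @ s["W1"] + s["b1"]
            h1 = np.maximum(h1p, 0.0)
            logits = h1 @ s["Wa"] + s["ba"]
            a = softmax(logits, axis=1)
            mx = a * X
            h2p = mx @ s["W2"] + s["b2"]
            h2 = np.maximum(h2p, 0.0)
            agg += h2
            self._cache.append((h1p, h1, a, mx, h2p))
        self._agg = agg
        return agg @ self.Wh + self.bh

    def attention_penalty(self):
        """Mean attention entropy across steps and rows, times the weight."""
        ent = 0.0
        for (_, _, a, _, _) in self._cache:
            ent += float(-(a * np.log(a + _EPS)).sum(axis=1).mean())
        return self.sparsity * ent / self.n_steps

    def backward(self, d_out):
        """Accumulate gradients of loss + sparsity penalty; call after forward."""
        self._zero_grads()
        X = self._X
        B = X.shape[0]
        self.gWh += self._agg.T @ d_out
        self.gbh += d_out.sum(axis=0)
        d_agg = d_out @ self.Wh.T
        pen_scale = self.sparsity / (self.n_steps * B)
        for s, g, (h1p, h1, a, mx, h2p) in zip(self.steps, self._step_grads,
                                               self._cache):
            dh2 = d_agg * (h2p > 0)
            g["W2"] += mx.T @ dh2
            g["b2"] += dh2.sum(axis=0)
            dmx = dh2 @ s["W2"].T
            da = dmx * X
            da += pen_scale * (-(np.log(a + _EPS) + 1.0))
            dlogits = a * (da - (da * a).sum(axis=1, keepdims=True))
            g["Wa"] += h1.T @ dlogits
            g["ba"] += dlogits.sum(axis=0)
            dh1 = (dlogits @ s["Wa"].T) * (h1p > 0)
            g["W1"] += X.T @ dh1
            g["b1"] += dh1.sum(axis=0)


def _loss_and_grad(out, y, kind):
    """(loss, d_loss/d_out) for MSE (continuous) or cross-entropy targets."""
    B = out.shape[0]
    if kind == "continuous":
        resid = out[:, 0] - y
        loss = float((resid ** 2).mean())
        d = np.zeros_like(out)
        d[:, 0] = 2.0 * resid / B
        return loss, d
    probs = softmax(out, axis=1)
    yi = y.astype(int)
    loss = float(-np.log(probs[np.arange(B), yi] + _EPS).mean())
    d = probs.copy()
    d[np.arange(B), yi] -= 1.0
    return loss, d / B


def train_tabnet(X_tr, y_tr, X_val, y_val, kind, n_out, config: ImputerConfig,
                 rng: np.random.Generator) -> AttentiveTabularNet:
    net = AttentiveTabularNet(rng, X_tr.shape[1], config.tabnet_steps,
                              config.tabnet_width, n_out,
                              config.tabnet_sparsity)
    opt = Adam(net.parameters(), net.gradients(), lr=config.tabnet_lr)
    best_val, best_w, wait = np.inf, net.get_weights(), 0
    n = len(X_tr)
    batch = min(config.tabnet_batch, n)
    for epoch in range(config.tabnet_epochs):
        lr = config.tabnet_lr * config.tabnet_lr_gamma ** (
            epoch // config.tabnet_lr_step)
        perm = rng.permutation(n)
        for bi in range(max(1, n // batch)):
            idx = perm[bi * batch:(bi + 1) * batch]
            if len(idx) == 0:
                continue
            out = net.forward(X_tr[idx])
            _, d = _loss_and_grad(out, y_tr[idx], kind)
            net.backward(d)
            # Adam holds references to the freshly zeroed+filled grads
            opt.grads = net.gradients()
            opt.step(lr=lr)
        val_out = net.forward(X_val)
        val_loss, _ = _loss_and_grad(val_out, y_val, kind)
        if val_loss < best_val - 1e-9:
            best_val, best_w, wait = val_loss, net.get_weights(), 0
        else:
            wait += 1
            if wait >= config.tabnet_patience:
                break
    net.set_weights(best_w)
    return net


def _fit_predict_column(X, j, miss_j, kind, config, rng):
    """Train on rows with observed target, predict the missing rows."""
    obs = ~miss_j
    others = np.delete(np.arange(X.shape[1]), j)
    Z = X[:, others]
    mu, sd = Z[obs].mean(axis=0), Z[obs].std(axis=0)
    sd[sd < 1e-12] = 1.0
    Zs = (Z - mu) / sd
    y = X[obs, j]
    classes = np.unique(y)
    if len(classes) == 1:
        warnings.warn("target constant among observed rows; imputing constant")
        return np.full(int(miss_j.sum()), classes[0])
    n_obs = int(obs.sum())
    n_val = max(1, int(round(config.tabnet_val_fraction * n_obs)))
    if n_obs - n_val < 1:
        raise ValueError("validation split leaves no training rows")
    perm = rng.permutation(n_obs)
    tr, va = perm[n_val:], perm[:n_val]
    Zo = Zs[obs]
    if kind == "continuous":
        y_mu, y_sd = y.mean(), max(y.std(), 1e-12)
        ys = (y - y_mu) / y_sd
        net = train_tabnet(Zo[tr], ys[tr], Zo[va], ys[va], kind, 1, config,
                           rng)
        pred = net.forward(Zs[miss_j])[:, 0] * y_sd + y_mu
        return pred
    code = {v: i for i, v in enumerate(classes)}
    yi = np.array([code[v] for v in y])
    net = train_tabnet(Zo[tr], yi[tr], Zo[va], yi[va], "categorical",
                       len(classes), config, rng)
    logits = net.forward(Zs[miss_j])
    return classes[np.argmax(logits, axis=1)]


def _run_chain(dataset: TabularDataset, config: ImputerConfig, chain: int,
               seed: int):
    rng = np.random.default_rng(seed)
    X = dataset.features.to_numpy(copy=True)
    miss = np.isnan(X)
    names = dataset.feature_names
    kinds = {c.name: c.kind for c in dataset.schema}
    order = visit_order(dataset)
    for c in order:
        j = names.index(c)
        if (~miss[:, j]).sum() < config.tabnet_min_obs:
            raise ValueError(
                f"column {c!r} has fewer than {config.tabnet_min_obs} "
                "observed rows; cannot form the 80:20 split")
        obs_vals = X[~miss[:, j], j]
        X[miss[:, j], j] = rng.choice(obs_vals, size=int(miss[:, j].sum()),
                                      replace=True)
    rows = []
    for it in range(config.iterations):
        for c in order:
            j = names.index(c)
            X[miss[:, j], j] = _fit_predict_column(
                X, j, miss[:, j], kinds[c], config, rng)
            rows.append((chain, it, c, float(X[miss[:, j], j].mean())))
    return X, rows


@register("mitabnet")
def mitabnet_mice(dataset: TabularDataset, config: ImputerConfig, M: int,
                  seed: int) -> MultipleImputation:
    seeds = spawn_seeds(seed, M)
    completed, trace_rows = [], []
    for m in range(M):
        X, rows = _run_chain(dataset, config, m, seeds[m])
        completed.append(finish_copy(dataset, X))
        trace_rows.extend(rows)
    traces = pd.DataFrame(trace_rows, columns=list(TRACE_COLUMNS))
    return MultipleImputation(completed=completed, imputer_id="mitabnet",
                              traces=traces, seed=seed, M=M)
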