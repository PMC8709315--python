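"""Controlled missingness: mask bootstrap, weighted MAR amputation, MCAR test.

Amputation deliberately hides cells of a complete (or partially complete)
dataset under a specified mechanism so imputation methods can be benchmarked
against known truth.  Two mechanisms are provided:

* ``mask_bootstrap``: resample an existing missingness pattern — each
  originally-observed cell is hidden with probability ``p_flip`` and each
  originally-missing cell with probability ``1 - p_flip`` (``p_flip = 0.5``
  degenerates to MCAR; 0.25 keeps the new mask correlated with the original).
* ``mar_weighted``: multivariate missingness-at-random via a scaled softmax
  of weighted sums of each row's observed predictors — rows with low weighted
  scores are more likely to lose the target cell, and the per-column hide
  probabilities average to the requested missingness proportion.

Little's test checks the MCAR hypothesis by comparing per-pattern means with
EM maximum-likelihood estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._mvnem import em_mvn
from .dataset import MissingnessMask, TabularDataset, apply_mask, extract_mask


@dataclass
class AmputationSpec:
    """Configuration of one amputation mechanism.

    ``p_m`` is the target per-column missingness proportion (scalar or a
    per-target dict); ``weights`` maps predictor column names to the w_j of
    the weighted-sum score (unlisted predictors get weight 0).
    """

    mechanism: str = "mar_weighted"
    p_flip: float = 0.25
    p_m: float | dict[str, float] = 0.3
    weights: dict[str, float] = field(default_factory=dict)
    targets: list[str] = field(default_factory=list)
    seed: int = 0
    #: rescale each target's weighted score to this standard deviation before
    #: the softmax (None keeps raw scores).  The scaled softmax is otherwise
    #: so heavy-tailed that per-row probabilities clip at 1 and the realized
    #: column missingness undershoots p_m badly.
    score_sd: float | None = 0.5

    def __post_init__(self):
        if not (0.0 <= self.p_flip <= 1.0):
            raise ValueError("p_flip must be in [0, 1]")
        pm_vals = (self.p_m.values() if isinstance(self.p_m, dict)
                   else [self.p_m])
        for v in pm_vals:
            if not (0.0 <= v < 1.0):
                raise ValueError("p_m must be in [0, 1)")
        for w in self.weights.values():
            if not np.isfinite(w):
                raise ValueError("weights must be finite")

    def p_m_for(self, column: str) -> float:
        if isinstance(self.p_m, dict):
            return self.p_m[column]
        return self.p_m


def mask_bootstrap_bernoulli(original_mask: MissingnessMask,
                             spec: AmputationSpec) -> MissingnessMask:
    """Bernoulli bootstrap of an existing missingness pattern.

    Cells observed in the original pattern flip to hidden with probability
    ``p_flip``; originally-hidden cells stay hidden with probability
    ``1 - p_flip``.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=original_mask.grid.shape)
    orig = original_mask.grid.astype(bool)
    prob = np.where(orig, 1.0 - spec.p_flip, spec.p_flip)
    return MissingnessMask(grid=(u < prob).astype(np.int8),
                           column_names=list(original_mask.column_names))


def mar_hide_probabilities(dataset: TabularDataset, target: str,
                           spec: AmputationSpec) -> np.ndarray:
    """Per-row hide probability for one target: p_m * N * softmax(-score).

    The score of row n is ``sum_{j != target} w_j * m_j(n) * x_j(n)`` where
    ``m_j(n)`` indicates that predictor j is currently observed for row n.
    The softmax is computed max-shifted; probabilities exceeding 1 are clipped
    with a warning (their mass is reported).
    """
    X = dataset.features
    score = np.zeros(dataset.n)
    for col, w in spec.weights.items():
        if col == target or w == 0 or col not in X.columns:
            continue
        x = X[col].to_numpy()
        m = ~np.isnan(x)
        score += np.where(m, w * np.nan_to_num(x), 0.0)
    if spec.score_sd is not None:
        sd = score.std()
        if sd > 1e-12:
            score = score * (spec.score_sd / sd)
    z = -score
    z = z - z.max()
    ez = np.exp(z)
    probs = spec.p_m_for(target) * dataset.n * ez / ez.sum()
    clipped = probs > 1.0
    if clipped.any():
        warnings.warn(
            f"MAR amputation of {target!r}: clipped probability mass "
            f"{float((probs[clipped] - 1.0).sum()):.4f} over "
            f"{int(clipped.sum())} rows")
        probs = np.minimum(probs, 1.0)
    return probs


def ampute_mar_weighted(dataset: TabularDataset, spec: AmputationSpec
                        ) -> tuple[TabularDataset, MissingnessMask]:
    """Hide cells of the target columns under the weighted-MAR mechanism.

    Targets are processed in the given order; observedness of predictors is
    evaluated against the current state, so later targets condition on
    earlier amputation.  Rows where a target is already missing are skipped
    with a warning.  Returns the amputated dataset and the mask of *newly*
    hidden cells.
    """
    current = dataset.copy()
    new_grid = np.zeros(dataset.features.shape, dtype=np.int8)
    rng = np.random.default_rng(spec.seed)
    col_index = {c: i for i, c in enumerate(dataset.feature_names)}
    for target in spec.targets:
        if target not in col_index:
            raise KeyError(f"unknown amputation target {target!r}")
        already = current.features[target].isna().to_numpy()
        if already.any():
            warnings.warn(f"target {target!r} already missing in "
                          f"{int(already.sum())} rows; skipping those")
        probs = mar_hide_probabilities(current, target, spec)
        hide = (rng.uniform(size=dataset.n) < probs) & ~already
        new_grid[hide, col_index[target]] = 1
        vals = current.features[target].to_numpy(copy=True)
        vals[hide] = np.nan
        current.features[target] = vals
    mask = MissingnessMask(grid=new_grid, column_names=dataset.feature_names)
    return current, mask


def mcar_mask(shape: tuple[int, int], column_names: list[str], p: float,
              seed: int = 0) -> MissingnessMask:
    """Plain MCAR mask: every cell hidden independently with probability p."""
    rng = np.random.default_rng(seed)
    return MissingnessMask(grid=(rng.uniform(size=shape) < p).astype(np.int8),
                           column_names=column_names)


def little_mcar_test(dataset: TabularDataset) -> tuple[float, int, float]:
    """Little's chi-square test of the MCAR hypothesis.

    Computes EM maximum-likelihood mean/covariance of the incomplete feature
    matrix, then the statistic

        d2 = sum_j n_j (ybar_j - mu_j)' Sigma_j^{-1} (ybar_j - mu_j)

    over missingness patterns j, where ybar_j and the ML estimates are
    restricted to the pattern's observed variables; df = sum_j p_j - p.

    Returns ``(statistic, df, p_value)``.
    """
    X = dataset.features.to_numpy(dtype=float)
    miss = np.isnan(X)
    keep = ~miss.all(axis=1)
    X, miss = X[keep], miss[keep]
    patterns = np.unique(miss, axis=0)
    if len(patterns) < 2:
        raise ValueError("Little's test needs at least two missingness "
                         "patterns (found one)")
    mu, sigma, _, _ = em_mvn(X, raise_on_nonconvergence=False)
    d2 = 0.0
    df = -X.shape[1]
    for pat in patterns:
        rows = (miss == pat).all(axis=1)
        obs = ~pat
        nj = int(rows.sum())
        ybar = X[np.ix_(rows, obs)].mean(axis=0)
        dev = ybar - mu[obs]
        Sjj = sigma[np.ix_(obs, obs)]
        d2 += nj * float(dev @ np.linalg.solve(Sjj, dev))
        df += int(obs.sum())
    p_value = float(stats.chi2.sf(d2, df)) if df > 0 else float("nan")
    return float(d2), int(df), p_value


__all__ = [
    "AmputationSpec", "mask_bootstrap_bernoulli", "ampute_mar_weighted",
    "mar_hide_probabilities", "mcar_mask", "little_mcar_test",
]
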