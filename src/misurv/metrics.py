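"""Evaluation metrics for imputation benchmarking.

Accuracy (root mean squared error on amputated cells), inferential quality
(percentage bias, confidence-interval coverage and width of Rubin-pooled Cox
coefficients) and sampler convergence (the Gelman-Rubin potential scale
reduction factor on chained-equation traces).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .dataset import MissingnessMask, TabularDataset
from .survival import PooledFit


def rmse_masked(imputed: TabularDataset, truth: TabularDataset,
                mask: MissingnessMask) -> tuple[float, pd.Series]:
    """RMSE of imputed vs. true values over the masked cells.

    Returns the overall value and a per-column breakdown (NaN for columns
    with no masked cells).  Binary columns are scored as 0/1 numeric.
    """
    grid = mask.grid.astype(bool)
    if not grid.any():
        raise ValueError("mask is empty; RMSE undefined")
    X_imp = imputed.features.to_numpy(dtype=float)
    X_true = truth.features.to_numpy(dtype=float)
    if X_imp.shape != X_true.shape or X_imp.shape != grid.shape:
        raise ValueError("imputed/truth/mask shapes disagree")
    if np.isnan(X_true[grid]).any():
        raise ValueError("truth is missing at masked cells")
    sq = (X_imp - X_true) ** 2
    overall = float(np.sqrt(sq[grid].mean()))
    per_col = {}
    for j, name in enumerate(mask.column_names):
        sel = grid[:, j]
        per_col[name] = float(np.sqrt(sq[sel, j].mean())) if sel.any() else np.nan
    return overall, pd.Series(per_col)


def percentage_bias(pooled_beta: pd.Series, truth_beta: pd.Series) -> float:
    """100 * sum_p |beta_bar_p - beta_hat_p| / sum_p |beta_hat_p|."""
    if isinstance(pooled_beta, PooledFit):
        pooled_beta = pooled_beta.beta_bar
    truth = truth_beta.reindex(pooled_beta.index)
    if truth.isna().any():
        raise ValueError("feature sets of pooled and truth estimates differ")
    denom = float(np.abs(truth.to_numpy()).sum())
    if denom == 0:
        raise ValueError("all-zero truth coefficients: bias undefined")
    num = float(np.abs(pooled_beta.to_numpy() - truth.to_numpy()).sum())
    return 100.0 * num / denom


def coverage_rate(intervals: list[pd.DataFrame], truth_beta: pd.Series) -> float:
    """Fraction of replicate CIs containing the reference coefficients.

    Per replicate, the per-coefficient cover indicators are averaged; the
    replicate values are then averaged again, matching a scalar-per-cell
    report.
    """
    if not intervals:
        raise ValueError("need at least one replicate interval")
    vals = []
    for ci in intervals:
        truth = truth_beta.reindex(ci.index).to_numpy()
        inside = (ci["lower"].to_numpy() <= truth) & (truth <= ci["upper"].to_numpy())
        vals.append(inside.mean())
    return float(np.mean(vals))


def interval_width_mean(intervals: list[pd.DataFrame]) -> float:
    """Mean of (upper - lower) over replicates and coefficients."""
    widths = [float((ci["upper"] - ci["lower"]).mean()) for ci in intervals]
    return float(np.mean(widths))


def rhat_diagnostic(traces: pd.DataFrame, burn_in_fraction: float = 0.5
                    ) -> pd.Series:
    """Potential scale reduction factor per imputed column.

    Expects the chained-equation trace table (chain, iteration, column,
    mean_imputed).  The first ``burn_in_fraction`` of each chain is dropped;
    the classic factor sqrt(((n-1)/n * W + B/n) / W) is computed from the
    remaining per-iteration means.  If every chain has zero within-chain
    variance the value is defined as 1 (with a warning).
    """
    if traces.empty:
        raise ValueError("no traces recorded")
    out = {}
    for col, sub in traces.groupby("column", sort=False):
        wide = sub.pivot_table(index="iteration", columns="chain",
                               values="mean_imputed")
        n_iter = len(wide)
        if wide.shape[1] < 2 or n_iter < 4:
            raise ValueError("R-hat needs >= 2 chains and >= 4 iterations")
        keep = wide.iloc[int(np.floor(n_iter * burn_in_fraction)):]
        arr = keep.to_numpy()          # n x m
        n = arr.shape[0]
        W = arr.var(axis=0, ddof=1).mean()
        B = n * arr.mean(axis=0).var(ddof=1)
        if W <= 0:
            if B <= 0:
                warnings.warn(f"zero within-chain variance for {col!r}; "
                              "R-hat defined as 1")
                out[col] = 1.0
                continue
            out[col] = np.inf
            continue
        out[col] = float(np.sqrt(((n - 1) / n * W + B / n) / W))
    return pd.Series(out)
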