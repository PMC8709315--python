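"""Cox proportional-hazards analysis and Rubin's-rules pooling.

The analysis model throughout is the multivariate Cox model

    h_i(t) = h0(t) exp(mu_i),    mu_i = sum_p beta_p x_ip,

fitted by partial likelihood with Efron's tie correction.  Imputation models
are strengthened by adding the marginal Nelson-Aalen cumulative hazard and
the event indicator as fully-observed predictors; those two columns never
enter the Cox feature set.  Estimates from M completed datasets are combined
with Rubin's rules: pooled point estimate, within/between-imputation
variances, total variance and t-based confidence intervals with the adjusted
degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .dataset import ColumnSpec, SchemaError, TabularDataset

#: names of the imputation-only predictor columns added by augmentation
AUGMENT_COLUMNS = ("na_cumhaz", "event_obs")


class CoxSeparationError(RuntimeError):
    """Monotone partial likelihood (separation); consider a ridge penalty."""


@dataclass
class CoxFit:
    """Point estimates and covariance of one Cox partial-likelihood fit."""

    beta: pd.Series
    cov: pd.DataFrame
    n: int
    events: int
    ties_method: str = "efron"

    def __post_init__(self):
        if not np.isfinite(self.beta.to_numpy()).all():
            raise ValueError("non-finite Cox coefficients")
        C = self.cov.to_numpy()
        if not np.allclose(C, C.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")

    @property
    def variances(self) -> pd.Series:
        return pd.Series(np.diag(self.cov.to_numpy()), index=self.beta.index)


@dataclass
class PooledFit:
    """Rubin-pooled Cox estimates across M imputations (per-coefficient)."""

    beta_bar: pd.Series
    sigma_w: pd.Series
    sigma_b: pd.Series
    M: int
    df: pd.Series | None = None
    ci: pd.DataFrame | None = None
    alpha: float | None = None

    @property
    def total_var(self) -> pd.Series:
        return self.sigma_w + (1.0 + 1.0 / self.M) * self.sigma_b

    def __post_init__(self):
        if (self.sigma_b < -1e-12).any():
            raise ValueError("between-imputation variance must be >= 0")


def nelson_aalen_hazard(dataset: TabularDataset) -> np.ndarray:
    """Per-row Nelson-Aalen cumulative hazard H(time_at_risk).

    H(t) = sum_{event times t_i <= t} d_i / n_i with d_i events and n_i at
    risk at t_i.
    """
    if dataset.survival is None:
        raise SchemaError("dataset has no survival outcome")
    t = dataset.survival["time_at_risk"].to_numpy()
    e = dataset.survival["event"].to_numpy()
    if (t < 0).any():
        raise ValueError("negative time_at_risk")
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    n = len(ts)
    uniq, start = np.unique(ts, return_index=True)
    H = np.zeros(len(uniq))
    acc = 0.0
    for k, u in enumerate(uniq):
        at_risk = n - start[k]
        stop = start[k + 1] if k + 1 < len(uniq) else n
        d = es[start[k]:stop].sum()
        acc += d / at_risk
        H[k] = acc
    return H[np.searchsorted(uniq, t)]


def augment_imputation_predictors(dataset: TabularDataset) -> TabularDataset:
    """Append the cumulative hazard and event indicator as complete predictors.

    The two columns (``na_cumhaz``, ``event_obs``) support the imputation
    models only; downstream Cox fits must exclude them (they are recorded in
    ``meta['augmented']`` and never imputed — they have no missing cells).
    """
    for name in AUGMENT_COLUMNS:
        if name in dataset.feature_names:
            raise SchemaError(f"column {name!r} already present")
    H = nelson_aalen_hazard(dataset)
    feats = dataset.features.assign(**{
        AUGMENT_COLUMNS[0]: H,
        AUGMENT_COLUMNS[1]: dataset.survival["event"].to_numpy(),
    })
    schema = dataset.schema + [ColumnSpec(AUGMENT_COLUMNS[0], "continuous"),
                               ColumnSpec(AUGMENT_COLUMNS[1], "binary")]
    meta = {**dataset.meta, "augmented": list(AUGMENT_COLUMNS)}
    return TabularDataset(feats, dataset.survival, schema, meta)


def strip_augmentation(dataset: TabularDataset) -> TabularDataset:
    """Drop augmentation columns added by :func:`augment_imputation_predictors`."""
    aug = [c for c in AUGMENT_COLUMNS if c in dataset.feature_names]
    if not aug:
        return dataset
    feats = dataset.features.drop(columns=aug)
    schema = [c for c in dataset.schema if c.name not in aug]
    meta = {k: v for k, v in dataset.meta.items() if k != "augmented"}
    return TabularDataset(feats, dataset.survival, schema, meta)


def cox_fit_efron(dataset: TabularDataset, features: list[str] | None = None
                  ) -> CoxFit:
    """Fit the Cox model by Efron partial likelihood on the given features."""
    if dataset.survival is None:
        raise SchemaError("dataset has no survival outcome")
    if features is None:
        features = [c for c in dataset.feature_names if c not in AUGMENT_COLUMNS]
    sub = dataset.features[features]
    if sub.isna().any().any():
        raise ValueError("Cox fit requires complete feature columns")
    events = int(dataset.survival["event"].sum())
    if events == 0:
        raise ValueError("no events in dataset; Cox model undefined")
    frame = pd.concat([sub.reset_index(drop=True),
                       dataset.survival.reset_index(drop=True)], axis=1)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(frame, duration_col="time_at_risk", event_col="event")
    except ConvergenceError as err:
        raise CoxSeparationError(
            "Cox partial likelihood did not converge (possible separation); "
            "consider penalization or removing degenerate columns") from err
    beta = cph.params_.copy()
    beta.index = [str(i) for i in beta.index]
    cov = cph.variance_matrix_.copy()
    cov.index = list(beta.index)
    cov.columns = list(beta.index)
    return CoxFit(beta=beta, cov=cov, n=dataset.n, events=events)


def rubin_pool(fits: list[CoxFit]) -> PooledFit:
    """Combine M Cox fits: pooled mean, within- and between-imputation variance.

    beta_bar = mean_m beta_m; sigma_w = mean_m Var_m (per coefficient);
    sigma_b = sum_m (beta_m - beta_bar)^2 / (M - 1);
    total variance = sigma_w + (1 + 1/M) sigma_b.
    """
    M = len(fits)
    if M < 2:
        raise ValueError("Rubin pooling needs at least two fits")
    idx = fits[0].beta.index
    for f in fits[1:]:
        if list(f.beta.index) != list(idx):
            raise ValueError("fits have mismatched feature sets")
    betas = np.vstack([f.beta.to_numpy() for f in fits])
    variances = np.vstack([f.variances.to_numpy() for f in fits])
    beta_bar = betas.mean(axis=0)
    sigma_w = variances.mean(axis=0)
    sigma_b = ((betas - beta_bar) ** 2).sum(axis=0) / (M - 1)
    return PooledFit(
        beta_bar=pd.Series(beta_bar, index=idx),
        sigma_w=pd.Series(sigma_w, index=idx),
        sigma_b=pd.Series(sigma_b, index=idx),
        M=M,
    )


def rubin_df(pooled: PooledFit) -> pd.Series:
    """Adjusted Rubin degrees of freedom: (M-1)(1 + sigma_w/((1+1/M) sigma_b))^2.

    Infinite when sigma_b = 0 (no missing-data information loss).
    """
    M = pooled.M
    with np.errstate(divide="ignore"):
        ratio = pooled.sigma_w / ((1.0 + 1.0 / M) * pooled.sigma_b)
    df = (M - 1) * (1.0 + ratio) ** 2
    df[pooled.sigma_b <= 0] = np.inf
    return df


def pooled_interval(pooled: PooledFit, alpha: float = 0.05) -> PooledFit:
    """Attach t-based confidence intervals beta_bar +/- t_{df,1-a/2} sqrt(sigma)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    df = rubin_df(pooled)
    se = np.sqrt(pooled.total_var.to_numpy())
    q = np.where(np.isinf(df.to_numpy()),
                 stats.norm.ppf(1.0 - alpha / 2.0),
                 stats.t.ppf(1.0 - alpha / 2.0, np.maximum(df.to_numpy(), 1e-9)))
    lower = pooled.beta_bar.to_numpy() - q * se
    upper = pooled.beta_bar.to_numpy() + q * se
    ci = pd.DataFrame({"lower": lower, "upper": upper},
                      index=pooled.beta_bar.index)
    return replace(pooled, df=df, ci=ci, alpha=alpha)
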