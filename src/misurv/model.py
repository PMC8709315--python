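"""Model/Results front end: Cox proportional hazards under multiple imputation.

:class:`MICoxPH` bundles the full inferential pipeline — hazard-augmented
imputation predictors, one of the six multiple-imputation engines, per-copy
Cox fits with Efron ties, Rubin's-rules pooling — behind a statsmodels-style
``Model.fit() -> Results`` interface.

Example
-------
>>> model = MICoxPH(dataset, imputer="pmm")
>>> res = model.fit(M=5, seed=7)
>>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import TabularDataset
from .impute import ImputerConfig, MultipleImputation, impute
from .metrics import rhat_diagnostic
from .survival import (AUGMENT_COLUMNS, CoxFit, PooledFit,
                       augment_imputation_predictors, cox_fit_efron,
                       pooled_interval, rubin_pool)


class MICoxPH:
    """Cox PH model on an incomplete dataset, analysed by multiple imputation.

    Parameters
    ----------
    dataset : TabularDataset
        Features with missing cells plus a complete survival outcome.
    features : list of str, optional
        Covariates of the Cox model (default: all non-augmentation features).
    imputer : str
        Engine id: ``pmm``, ``em``, ``rf``, ``pca``, ``gain`` or ``mitabnet``.
    config : ImputerConfig, optional
    augment : bool
        Add the Nelson-Aalen cumulative hazard and event indicator as
        imputation-only predictors (default True).
    """

    def __init__(self, dataset: TabularDataset, features: list[str] | None = None,
                 imputer: str = "pmm", config: ImputerConfig | None = None,
                 augment: bool = True):
        self.dataset = dataset
        self.features = features or [c for c in dataset.feature_names
                                     if c not in AUGMENT_COLUMNS]
        self.imputer = imputer
        self.config = config or ImputerConfig()
        self.augment = augment

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, schema, **kwargs) -> "MICoxPH":
        """Build from a flat DataFrame holding features + time_at_risk/event."""
        from .dataset import SURVIVAL_COLUMNS
        names = [c.name for c in schema]
        ds = TabularDataset(features=frame[names],
                            survival=frame[list(SURVIVAL_COLUMNS)],
                            schema=list(schema))
        return cls(ds, **kwargs)

    def fit(self, M: int = 5, seed: int = 0, alpha: float = 0.05
            ) -> "MICoxPHResults":
        data = (augment_imputation_predictors(self.dataset) if self.augment
                else self.dataset)
        mi = impute(data, self.imputer, self.config, M=M, seed=seed)
        fits = [cox_fit_efron(c, self.features) for c in mi.completed]
        pooled = pooled_interval(rubin_pool(fits), alpha=alpha)
        return MICoxPHResults(self, mi, fits, pooled)


class MICoxPHResults:
    """Pooled estimates, uncertainties and diagnostics of a fitted MICoxPH."""

    def __init__(self, model: MICoxPH, mi: MultipleImputation,
                 fits: list[CoxFit], pooled: PooledFit):
        self.model = model
        self.imputations = mi
        self.fits = fits
        self.pooled = pooled

    # -- statsmodels-flavoured accessors ----------------------------------
    @property
    def params(self) -> pd.Series:
        return self.pooled.beta_bar

    @property
    def bse(self) -> pd.Series:
        return np.sqrt(self.pooled.total_var)

    @property
    def df(self) -> pd.Series:
        return self.pooled.df

    def conf_int(self) -> pd.DataFrame:
        return self.pooled.ci

    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def rhat(self) -> pd.Series | None:
        """Convergence diagnostic; None for engines without chain traces."""
        if self.imputations.traces.empty:
            return None
        return rhat_diagnostic(self.imputations.traces)

    def summary(self) -> str:
        lvl = int(round(100 * (1 - (self.pooled.alpha or 0.05))))
        lines = [
            "Cox PH via multiple imputation (Rubin's rules)",
            "=" * 62,
            f"imputer: {self.imputations.imputer_id}   M: {self.pooled.M}   "
            f"n: {self.fits[0].n}   events: {self.fits[0].events}",
            "-" * 62,
            f"{'coef':>10} {'beta':>9} {'se':>8} {'df':>8} "
            f"{f'[{lvl}% CI]':>18}",
        ]
        for name in self.params.index:
            df = self.df[name]
            df_s = "inf" if np.isinf(df) else f"{df:.1f}"
            lines.append(
                f"{name:>10} {self.params[name]:>9.4f} {self.bse[name]:>8.4f} "
                f"{df_s:>8} [{self.pooled.ci.loc[name, 'lower']:>7.4f}, "
                f"{self.pooled.ci.loc[name, 'upper']:>7.4f}]")
        lines.append("-" * 62)
        rhat = self.rhat()
        if rhat is not None:
            lines.append("R-hat: " + ", ".join(
                f"{k}={v:.3f}" for k, v in rhat.items()))
        return "\n".join(lines)
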