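"""Nelson-Aalen, Cox/Efron fitting and Rubin's-rules pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.optimize import minimize

import misurv as ms
from misurv.dataset import TabularDataset, make_schema
from misurv.survival import (AUGMENT_COLUMNS, CoxFit, rubin_df,
                             strip_augmentation)

from conftest import make_mvn_dataset


def _surv_ds(times, events, x=None):
    n = len(times)
    feats = pd.DataFrame({"x": x if x is not None else np.zeros(n)})
    surv = pd.DataFrame({"time_at_risk": times, "event": events})
    return TabularDataset(feats, surv, make_schema(["x"], "continuous"))


# -- Nelson-Aalen ---------------------------------------------------------

def test_nelson_aalen_hand_example():
    ds = _surv_ds([1.0, 2.0, 3.0], [1.0, 1.0, 0.0])
    H = ms.nelson_aalen_hazard(ds)
    assert np.allclose(H, [1 / 3, 1 / 3 + 1 / 2, 1 / 3 + 1 / 2])


def test_nelson_aalen_no_events_and_monotone():
    ds = _surv_ds([5.0, 1.0, 3.0], [0.0, 0.0, 0.0])
    assert np.allclose(ms.nelson_aalen_hazard(ds), 0.0)
    ds2 = make_mvn_dataset(n=200, seed=4)
    H = ms.nelson_aalen_hazard(ds2)
    order = np.argsort(ds2.survival["time_at_risk"].to_numpy())
    assert np.all(np.diff(H[order]) >= -1e-12)


def test_augmentation_composition_and_exclusion():
    ds = make_mvn_dataset(n=300, p=3, seed=6)
    aug = ms.augment_imputation_predictors(ds)
    assert aug.p == ds.p + 2
    assert not aug.features[list(AUGMENT_COLUMNS)].isna().any().any()
    assert np.allclose(aug.features[AUGMENT_COLUMNS[0]],
                       ms.nelson_aalen_hazard(ds))
    # hazard tracks time-at-risk on continuous times
    r = np.corrcoef(aug.features[AUGMENT_COLUMNS[0]],
                    ds.survival["time_at_risk"])[0, 1]
    assert r > 0.9
    # augmentation columns are excluded from the default Cox feature set
    fit = ms.cox_fit_efron(aug)
    assert set(fit.beta.index) == {"x0", "x1", "x2"}
    assert strip_augmentation(aug).feature_names == ds.feature_names
    with pytest.raises(Exception, match="already present"):
        ms.augment_imputation_predictors(aug)


# -- Cox / Efron ----------------------------------------------------------

def test_cox_symmetric_groups_give_zero_beta():
    times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    events = [1.0, 0.0, 1.0, 1.0, 0.0, 1.0]
    x = [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]
    fit = ms.cox_fit_efron(_surv_ds(times, events, x))
    assert abs(fit.beta["x"]) < 1e-6


def _exact_partial_loglik(beta, times, events, x):
    """Untied exact Cox partial likelihood (independent oracle)."""
    order = np.argsort(times)
    t, e, xv = (np.asarray(a)[order] for a in (times, events, x))
    ll = 0.0
    for i in range(len(t)):
        if e[i] == 1:
            risk = xv[i:] * beta
            ll += xv[i] * beta - np.log(np.sum(np.exp(risk)))
    return ll


def test_cox_matches_bruteforce_partial_likelihood():
    """On untied data Efron equals the exact partial likelihood, which we
    maximise directly with a generic optimiser."""
    times = [3.0, 1.0, 4.0, 2.0, 6.0, 5.0]
    events = [1.0, 1.0, 0.0, 1.0, 1.0, 0.0]
    x = [0.5, -1.0, 0.3, 1.2, -0.7, 0.1]
    fit = ms.cox_fit_efron(_surv_ds(times, events, x))
    res = minimize(lambda b: -_exact_partial_loglik(b[0], times, events, x),
                   x0=[0.0], method="BFGS", tol=1e-12)
    assert abs(fit.beta["x"] - res.x[0]) < 1e-5


def test_cox_recovers_simulated_effect():
    spec = ms.calibrate_scm(0.3, 2000, seed=0)
    ds = ms.make_scm_survival_dataset(
        spec, 10_000, seed=1, survival_spec=ms.SurvivalSpec(betas={"A1": 0.5}))
    fit = ms.cox_fit_efron(ds)
    se = np.sqrt(fit.variances["A1"])
    assert abs(fit.beta["A1"] - 0.5) < 3 * se


def test_cox_errors():
    with pytest.raises(ValueError, match="events"):
        ms.cox_fit_efron(_surv_ds([1.0, 2.0], [0.0, 0.0], [0.0, 1.0]))


# -- Rubin's rules --------------------------------------------------------

def _scalar_fit(beta, var):
    return CoxFit(beta=pd.Series({"x": beta}),
                  cov=pd.DataFrame({"x": [var]}, index=["x"]),
                  n=10, events=5)


def test_rubin_hand_oracle():
    """beta = (1, 3), per-fit variance 0.5: pooled mean 2, sigma_b = 2,
    total variance 3.5, adjusted df 1.3611."""
    pooled = ms.rubin_pool([_scalar_fit(1.0, 0.5), _scalar_fit(3.0, 0.5)])
    assert pooled.beta_bar["x"] == 2.0
    assert pooled.sigma_w["x"] == 0.5
    assert pooled.sigma_b["x"] == 2.0
    assert pooled.total_var["x"] == 0.5 + 1.5 * 2.0
    with_ci = ms.pooled_interval(pooled, alpha=0.05)
    df = with_ci.df["x"]
    assert np.isclose(df, (1 + 0.5 / 3.0) ** 2)
    q = stats.t.ppf(0.975, df)
    assert np.allclose(
        [with_ci.ci.loc["x", "lower"], with_ci.ci.loc["x", "upper"]],
        [2.0 - q * np.sqrt(3.5), 2.0 + q * np.sqrt(3.5)])


def test_rubin_identical_fits_and_permutation():
    fits = [_scalar_fit(1.3, 0.4)] * 3
    pooled = ms.rubin_pool(fits)
    assert pooled.sigma_b["x"] == 0.0
    assert pooled.total_var["x"] == pooled.sigma_w["x"]
    a = ms.rubin_pool([_scalar_fit(1.0, 0.2), _scalar_fit(2.0, 0.3)])
    b = ms.rubin_pool([_scalar_fit(2.0, 0.3), _scalar_fit(1.0, 0.2)])
    assert a.beta_bar.equals(b.beta_bar) and a.sigma_b.equals(b.sigma_b)


def test_zero_between_variance_gives_z_interval():
    pooled = ms.rubin_pool([_scalar_fit(1.0, 0.4)] * 4)
    out = ms.pooled_interval(pooled, alpha=0.05)
    assert np.isinf(out.df["x"])
    z = stats.norm.ppf(0.975)
    assert np.isclose(out.ci.loc["x", "upper"], 1.0 + z * np.sqrt(0.4))


def test_interval_width_shrinks_with_M():
    widths = []
    for M in (2, 3, 5, 10):
        fits = [_scalar_fit(b, 0.5) for b in np.linspace(0, 2, M)]
        pooled = ms.rubin_pool(fits)
        # hold sigma_w / sigma_b fixed, vary only the 1 + 1/M factor
        pooled.sigma_b["x"] = 1.0
        pooled.sigma_w["x"] = 0.5
        widths.append(float(pooled.total_var["x"]))
    assert all(np.diff(widths) < 0)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.lists(st.tuples(st.floats(-3, 3), st.floats(0.01, 2)),
                min_size=2, max_size=8))
def test_total_variance_dominance(fitvals):
    fits = [_scalar_fit(b, v) for b, v in fitvals]
    pooled = ms.rubin_pool(fits)
    M = len(fits)
    assert pooled.total_var["x"] >= pooled.sigma_w["x"] - 1e-12
    assert pooled.total_var["x"] >= (1 + 1 / M) * pooled.sigma_b["x"] - 1e-12


def test_rubin_requires_two_matching_fits():
    with pytest.raises(ValueError):
        ms.rubin_pool([_scalar_fit(1.0, 0.5)])
    other = CoxFit(beta=pd.Series({"y": 1.0}),
                   cov=pd.DataFrame({"y": [0.5]}, index=["y"]), n=5, events=3)
    with pytest.raises(ValueError, match="mismatch"):
        ms.rubin_pool([_scalar_fit(1.0, 0.5), other])
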