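import numpy as np
import pandas as pd
import pytest

from misurv.dataset import TabularDataset, make_schema


def make_mvn_dataset(n=200, p=4, rho=0.5, seed=0, with_survival=True,
                     miss_frac=0.0, miss_cols=None):
    """Equicorrelated Gaussian features, optional exponential survival and
    MCAR missingness — the workhorse synthetic input for unit tests."""
    rng = np.random.default_rng(seed)
    cov = np.full((p, p), rho)
    np.fill_diagonal(cov, 1.0)
    X = rng.multivariate_normal(np.zeros(p), cov, size=n, method="cholesky")
    names = [f"x{j}" for j in range(p)]
    feats = pd.DataFrame(X, columns=names)
    surv = None
    if with_survival:
        t = rng.exponential(100.0, size=n)
        e = (rng.uniform(size=n) < 0.7).astype(float)
        surv = pd.DataFrame({"time_at_risk": t, "event": e})
    ds = TabularDataset(feats, surv, make_schema(names, "continuous"))
    if miss_frac > 0:
        cols = miss_cols if miss_cols is not None else names
        vals = ds.features.to_numpy()
        for c in cols:
            j = names.index(c)
            hide = rng.uniform(size=n) < miss_frac
            # keep at least one observed cell
            hide[rng.integers(0, n)] = False
            vals[hide, j] = np.nan
        ds.features = pd.DataFrame(vals, columns=names)
    return ds


@pytest.fixture
def mvn_complete():
    return make_mvn_dataset(n=120, p=3, rho=0.6, seed=3)


@pytest.fixture
def mvn_incomplete():
    return make_mvn_dataset(n=250, p=4, rho=0.6, seed=5, miss_frac=0.25)
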