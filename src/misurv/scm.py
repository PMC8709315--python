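"""Synthetic survival data from a linear-Gaussian structural causal model.

Two latent variables A and B (A causes B) drive six observable manifests:
A1..A3 load on A, B1..B3 load on B, and B1 additionally receives a direct
path from A.  A single common loading, calibrated by bisection against the
sampled mean absolute pairwise correlation, moves the manifest correlation
level between a high-correlation regime (rho ~ 0.8) and a low-correlation
regime (rho ~ 0.2).  Survival times follow a proportional-hazards model on
the manifests, simulated by inverse-transform sampling from the baseline
cumulative hazard, with independent exponential censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import ColumnSpec, TabularDataset, extract_mask, make_schema

MANIFESTS = ("A1", "A2", "A3", "B1", "B2", "B3")

#: Biomarker panel emulated by the binary fixture: positive rate among tested
#: patients and unknown (missing) rate in the cohort.
BIOMARKER_POSITIVE_RATE = {
    "ALK": 971 / (971 + 27_612),
    "EGFR": 5_196 / (5_196 + 25_928),
    "KRAS": 4_778 / (4_778 + 12_247),
    "BRAF": 847 / (847 + 15_579),
    "PDL1": 6_052 / (6_052 + 11_301),
}
BIOMARKER_MISSING_RATE = {
    "ALK": 0.1836,
    "EGFR": 0.1110,
    "KRAS": 0.5137,
    "BRAF": 0.5308,
    "PDL1": 0.5044,
}


@dataclass(frozen=True)
class ScmSpec:
    """Coefficients of the two-latent SCM.

    ``loadings_a``/``loadings_b`` map the latents onto their three manifests;
    ``cross_ab1`` is the direct A -> B1 path; ``noise_sd`` is the standard
    deviation of the independent noise on every manifest; ``latent_b_noise_sd``
    keeps B from being collinear with A.
    """

    b_on_a: float = 1.0
    loadings_a: tuple[float, float, float] = (1.0, 1.0, 1.0)
    loadings_b: tuple[float, float, float] = (1.0, 1.0, 1.0)
    cross_ab1: float = 0.3
    noise_sd: float = 1.0
    latent_b_noise_sd: float = 0.5
    target_rho: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0 or self.latent_b_noise_sd <= 0:
            raise ValueError("noise standard deviations must be positive")
        if self.target_rho is not None and not (0 < self.target_rho < 1):
            raise ValueError("target_rho must lie in (0, 1)")


@dataclass(frozen=True)
class SurvivalSpec:
    """Proportional-hazards simulation parameters.

    ``betas`` are log-hazard coefficients per feature column; the baseline
    hazard is exponential (``shape == 1``) or Weibull (H0(t) = rate * t^shape).
    ``censoring_rate`` parameterises an independent exponential censoring time
    (0 disables censoring).  The default baseline rate puts the baseline
    median event time at ~365 days; the default censoring rate yields ~30%
    censoring when covariate effects are absent.
    """

    betas: dict[str, float] = field(default_factory=dict)
    baseline_rate: float = np.log(2) / 365.0
    baseline_shape: float = 1.0
    censoring_rate: float = (3.0 / 7.0) * np.log(2) / 365.0
    seed: int = 0

    def __post_init__(self):
        if self.baseline_rate <= 0 or self.baseline_shape <= 0:
            raise ValueError("baseline rate and shape must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be non-negative")


def _manifest_sds(spec: ScmSpec) -> np.ndarray:
    """Theoretical standard deviation of each manifest (for standardisation)."""
    var_a = 1.0
    var_b = spec.b_on_a ** 2 * var_a + spec.latent_b_noise_sd ** 2
    cov_ab = spec.b_on_a * var_a
    sds = []
    for k, la in enumerate(spec.loadings_a):
        sds.append(np.sqrt(la ** 2 * var_a + spec.noise_sd ** 2))
    for k, lb in enumerate(spec.loadings_b):
        var = lb ** 2 * var_b + spec.noise_sd ** 2
        if k == 0:
            var += spec.cross_ab1 ** 2 * var_a + 2 * spec.cross_ab1 * lb * cov_ab
        sds.append(np.sqrt(var))
    return np.asarray(sds)


def sample_scm_features(spec: ScmSpec, n: int, *, seed: int | None = None,
                        standardize: bool = True) -> TabularDataset:
    """Draw n rows of the six manifests; latents are not emitted.

    Manifests are scaled by their model-implied standard deviation by default
    so hazard coefficients are comparable across correlation regimes
    (correlations are scale-invariant).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    A = rng.standard_normal(n)
    B = spec.b_on_a * A + spec.latent_b_noise_sd * rng.standard_normal(n)
    cols = {}
    for k, name in enumerate(("A1", "A2", "A3")):
        cols[name] = spec.loadings_a[k] * A + spec.noise_sd * rng.standard_normal(n)
    for k, name in enumerate(("B1", "B2", "B3")):
        cols[name] = spec.loadings_b[k] * B + spec.noise_sd * rng.standard_normal(n)
    cols["B1"] = cols["B1"] + spec.cross_ab1 * A
    frame = pd.DataFrame(cols, columns=list(MANIFESTS))
    if standardize:
        frame = frame / _manifest_sds(spec)
    return TabularDataset(
        features=frame, survival=None,
        schema=make_schema(MANIFESTS, "continuous"),
        meta={"generator": "scm", "seed": int(seed if seed is not None else spec.seed),
              "target_rho": spec.target_rho},
    )


def mean_abs_correlation(dataset: TabularDataset) -> float:
    """Mean absolute off-diagonal Pearson correlation of the features."""
    corr = dataset.features.corr().to_numpy()
    iu = np.triu_indices_from(corr, k=1)
    return float(np.abs(corr[iu]).mean())


def calibrate_scm(target_rho: float, n_probe: int = 10_000, seed: int = 0,
                  tol: float = 0.01, max_iter: int = 60) -> ScmSpec:
    """Find a common loading whose sampled mean |corr| hits ``target_rho``.

    One-dimensional and monotone: all six loadings share a value c with unit
    manifest noise, and c is bisected against the mean absolute pairwise
    correlation measured on a fixed probe sample (deterministic given seed).
    """
    if not (0 < target_rho < 1):
        raise ValueError("target_rho must be in (0, 1)")

    def measured(c: float) -> float:
        spec = ScmSpec(loadings_a=(c, c, c), loadings_b=(c, c, c),
                       target_rho=target_rho, seed=seed)
        return mean_abs_correlation(sample_scm_features(spec, n_probe, seed=seed))

    lo, hi = 1e-3, 50.0
    if measured(hi) < target_rho - 0.05:
        raise ValueError(f"target_rho={target_rho} unattainable for this SCM")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        val = measured(mid)
        if abs(val - target_rho) < tol:
            lo = hi = mid
            break
        if val < target_rho:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    return ScmSpec(loadings_a=(c, c, c), loadings_b=(c, c, c),
                   target_rho=target_rho, seed=seed)


def _inverse_cumhaz(u: np.ndarray, mu: np.ndarray, spec: SurvivalSpec) -> np.ndarray:
    """T = H0^{-1}( -log U / exp(mu) ) for the configured baseline family."""
    target = -np.log(u) / np.exp(mu)
    t = target / spec.baseline_rate
    if spec.baseline_shape != 1.0:
        t = t ** (1.0 / spec.baseline_shape)
    return t


def simulate_survival_ph(features: TabularDataset, spec: SurvivalSpec,
                         *, seed: int | None = None) -> TabularDataset:
    """Attach inverse-transform survival times to a complete feature table.

    Per row the prognostic index is mu = sum_j beta_j x_j; the latent event
    time solves H0(T) exp(mu) = -log U with U ~ Uniform(0,1); censoring is an
    independent exponential; ``time_at_risk = min(T, C)``,
    ``event = 1{T <= C}``.
    """
    if features.is_missing().any().any():
        raise ValueError("survival simulation needs complete features")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    X = features.features.to_numpy()
    beta = np.array([spec.betas.get(c, 0.0) for c in features.feature_names])
    mu = X @ beta
    u = rng.uniform(size=len(X))
    T = _inverse_cumhaz(u, mu, spec)
    if spec.censoring_rate > 0:
        C = rng.exponential(1.0 / spec.censoring_rate, size=len(X))
    else:
        C = np.full(len(X), np.inf)
    surv = pd.DataFrame({
        "time_at_risk": np.minimum(T, C),
        "event": (T <= C).astype(float),
    })
    out = features.copy()
    out.survival = surv
    out.meta = {**features.meta, "survival_seed": int(seed if seed is not None
                                                      else spec.seed)}
    return TabularDataset(out.features, surv, out.schema, out.meta)


DEFAULT_SCM_BETAS = {"A1": 0.5, "A2": -0.5, "A3": 0.5,
                     "B1": -0.5, "B2": 0.5, "B3": -0.5}


def make_scm_survival_dataset(spec: ScmSpec, n: int, seed: int,
                              betas: dict[str, float] | None = None,
                              survival_spec: SurvivalSpec | None = None
                              ) -> TabularDataset:
    """Features + survival in one call; the standard synthetic benchmark unit."""
    ss = np.random.SeedSequence(seed).spawn(2)
    feat_seed, surv_seed = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss)
    feats = sample_scm_features(spec, n, seed=feat_seed)
    if survival_spec is None:
        survival_spec = SurvivalSpec(betas=dict(betas or DEFAULT_SCM_BETAS))
    return simulate_survival_ph(feats, survival_spec, seed=surv_seed)


# -- binary biomarker fixture --------------------------------------------

def _gaussian_copula_binary(rng, n, rates, rho):
    """Correlated binaries by thresholding an equicorrelated Gaussian."""
    p = len(rates)
    cov = np.full((p, p), rho)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(p), cov, size=n, method="cholesky")
    from scipy.stats import norm
    cuts = norm.ppf(1.0 - np.asarray(rates))
    return (z > cuts).astype(float)


def generate_flatiron_like(n: int, seed: int = 0,
                           betas: dict[str, float] | None = None
                           ) -> TabularDataset:
    """Synthetic stand-in for an NSCLC biomarker cohort (synthetic fixture).

    Five binary biomarker columns with realistic positive rates, weak pairwise
    dependence, proportional-hazards survival, and a missing-at-random pattern
    whose per-column missingness depends on the observed biomarkers and the
    Nelson-Aalen cumulative hazard — so an MCAR test rejects.  Missingness is
    already applied; recover the mask with :func:`~misurv.dataset.extract_mask`.
    """
    from .amputate import AmputationSpec, ampute_mar_weighted
    from .survival import nelson_aalen_hazard

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(BIOMARKER_POSITIVE_RATE)
    X = _gaussian_copula_binary(rng, n,
                                [BIOMARKER_POSITIVE_RATE[b] for b in names],
                                rho=0.12)
    feats = pd.DataFrame(X, columns=names)
    complete = TabularDataset(feats, None, make_schema(names, "binary"),
                              meta={"generator": "flatiron_like", "seed": seed})
    if betas is None:
        betas = {"ALK": -0.4, "EGFR": -0.5, "KRAS": 0.3,
                 "BRAF": 0.2, "PDL1": -0.2}
    complete = simulate_survival_ph(
        complete, SurvivalSpec(betas=betas), seed=seed + 1)

    # MAR mask: missingness of each biomarker driven by the other biomarkers
    # and by the cumulative-hazard summary of the outcome.
    hazard = nelson_aalen_hazard(complete)
    aug = complete.copy()
    aug.features = aug.features.assign(_H=(hazard - hazard.mean())
                                       / (hazard.std() + 1e-12))
    aug = TabularDataset(aug.features, complete.survival,
                         complete.schema + [ColumnSpec("_H", "continuous")],
                         complete.meta)
    spec = AmputationSpec(
        mechanism="mar_weighted",
        p_m={b: BIOMARKER_MISSING_RATE[b] for b in names},
        weights={**{b: 0.8 for b in names}, "_H": 0.8},
        targets=names,
        seed=seed + 2,
    )
    amputed, _mask = ampute_mar_weighted(aug, spec)
    feats_out = amputed.features[names]
    return TabularDataset(feats_out, complete.survival, complete.schema,
                          {**complete.meta, "mar": True})
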