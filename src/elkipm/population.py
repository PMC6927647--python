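"""State-space population model for harvested elk herds.

Process layer (latent, per district u and year t; harvest h is data):

* calves        N^c_t  ~ Poisson(tau_t N^af_{t-1} - h^c_t)
* adult females N^af_t ~ Poisson(phi_a (delta N^c_{t-1} + N^af_{t-1} - h^af_t))
* adult males   N^am_t ~ Poisson(phi_a ((1-delta) N^c_{t-1} + N^am_{t-1} - h^am_t))

with per capita recruitment on the logit scale,
``logit(tau_{t,u}) = alpha + zeta_t + x_{t,u}' beta`` (standardized covariates,
year random effects zeta_t ~ Normal(0, sigma_zeta^2), hierarchical shrinkage
beta_j ~ Normal(0, sigma_beta^2)), and delta (female fraction of calves)
fixed at 0.5.  Poisson means are floored at a small eps because large calf
harvest can push the subtraction non-positive.

Observation layer (surveyed district-years only):

* total count ~ Poisson(N_total exp(gamma)),  gamma ~ Normal(0, sigma_count^2)
  (log-normal observation-level overdispersion, median multiplier 1);
* classified class counts ~ Multinomial(pi, classified_total) with pi equal to
  the latent class shares; classification-missing years keep only the count
  terms.

Initial abundances get discrete-uniform priors on [h_next, 10000] per class
(left-truncated at the next year's harvest); phi_a ~ Beta(1,1); alpha ~
Normal(0,1); the three standard deviations get Uniform(0, 10) priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

from .data import (
    CovariateTable,
    DataValidationError,
    DesignSpec,
    HarvestRecord,
    SurveyObservation,
    build_design_matrix,
    standardize,
)
from .draws import MCMCConfig, PosteriorDraws, hpd_interval, summarize_samples

__all__ = [
    "PriorConfig",
    "LatentStates",
    "ProcessParameters",
    "PopulationData",
    "recruitment_rate",
    "expected_transition",
    "log_process_density",
    "log_observation_density",
    "log_prior",
    "joint_log_density",
    "fit",
    "derive_lambda",
    "predict_recruitment",
]


def invlogit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def poisson_logpmf(y, mu):
    """Poisson log-pmf, valid for real-valued y >= 0 (continuous relaxation
    of the latent states uses the same expression)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return xlogy(y, mu) - mu - gammaln(y + 1.0)


@dataclass(frozen=True)
class PriorConfig:
    """Hyperprior settings: Normal(0, alpha_sd^2) intercept, Uniform(0, bound)
    on each standard deviation, per-class discrete-uniform initial abundances
    on [h_next, n_max], and the Poisson-mean floor eps."""

    alpha_sd: float = 1.0
    sigma_zeta_bound: float = 10.0
    sigma_beta_bound: float = 10.0
    sigma_count_bound: float = 10.0
    n_max: int = 10_000
    eps: float = 1e-3


@dataclass
class LatentStates:
    """Latent abundances per district-year: (U, T) arrays per class."""

    n_calves: np.ndarray
    n_adult_females: np.ndarray
    n_adult_males: np.ndarray

    def __post_init__(self) -> None:
        self.n_calves = np.asarray(self.n_calves, dtype=float)
        self.n_adult_females = np.asarray(self.n_adult_females, dtype=float)
        self.n_adult_males = np.asarray(self.n_adult_males, dtype=float)

    @property
    def n_total(self) -> np.ndarray:
        return self.n_calves + self.n_adult_females + self.n_adult_males


@dataclass
class ProcessParameters:
    """All non-latent unknowns of the population model."""

    alpha: float
    beta: np.ndarray               # (P,)
    zeta: np.ndarray               # (T-1,) transition-year effects
    phi_a: float
    sigma_zeta: float
    sigma_beta: float
    sigma_count: float
    gamma: np.ndarray              # (U, T); used at observed sites only
    delta: float = 0.5

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.zeta = np.asarray(self.zeta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)


@dataclass
class PopulationData:
    """A fitted-ready study: aligned district x year arrays for harvest,
    design matrix and the two observation layers."""

    districts: list[str]
    years: list[int]
    h_calves: np.ndarray           # (U, T)
    h_adult_females: np.ndarray
    h_adult_males: np.ndarray
    X: np.ndarray                  # (U, T, P); X[:, 0, :] is zero (unused)
    design_names: list[str]
    obs_mask: np.ndarray           # (U, T) bool: total count observed
    counts: np.ndarray             # (U, T)
    cls_mask: np.ndarray           # (U, T) bool: classification observed
    y_calves: np.ndarray
    y_adult_females: np.ndarray
    y_adult_males: np.ndarray

    @property
    def n_districts(self) -> int:
        return len(self.districts)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_terms(self) -> int:
        return self.X.shape[2]

    @property
    def cls_total(self) -> np.ndarray:
        return self.y_calves + self.y_adult_females + self.y_adult_males

    @classmethod
    def from_tables(
        cls,
        surveys: list[SurveyObservation],
        harvest: list[HarvestRecord],
        covariates: CovariateTable,
        design: DesignSpec,
        years: list[int] | None = None,
    ) -> "PopulationData":
        """Assemble the model arrays from the three input tables.

        The modelled window defaults to the contiguous span of harvest years;
        harvest must be present for every district-year in it, and the design
        matrix must be computable for every transition year.
        """
        districts = sorted({h.district for h in harvest})
        if years is None:
            all_years = sorted({h.year for h in harvest})
            years = list(range(all_years[0], all_years[-1] + 1))
        U, T = len(districts), len(years)
        d_idx = {d: i for i, d in enumerate(districts)}
        y_idx = {y: i for i, y in enumerate(years)}

        hc = np.full((U, T), -1.0)
        haf = np.full((U, T), -1.0)
        ham = np.full((U, T), -1.0)
        for h in harvest:
            if h.year not in y_idx:
                continue
            ui, ti = d_idx[h.district], y_idx[h.year]
            hc[ui, ti], haf[ui, ti], ham[ui, ti] = (
                h.h_calves, h.h_adult_females, h.h_adult_males)
        if (hc < 0).any():
            ui, ti = np.argwhere(hc < 0)[0]
            raise DataValidationError(
                f"harvest missing for {districts[ui]}/{years[ti]}"
            )

        std = standardize(covariates)
        design_df = build_design_matrix(std, design, years=years[1:])
        P = len(design)
        X = np.zeros((U, T, P))
        for (d, y), row in design_df.iterrows():
            if d in d_idx and y in y_idx:
                X[d_idx[d], y_idx[y], :] = row.to_numpy(dtype=float)

        obs_mask = np.zeros((U, T), dtype=bool)
        counts = np.zeros((U, T))
        cls_mask = np.zeros((U, T), dtype=bool)
        yc = np.zeros((U, T))
        yaf = np.zeros((U, T))
        yam = np.zeros((U, T))
        for s in surveys:
            if s.district not in d_idx or s.year not in y_idx:
                raise DataValidationError(
                    f"survey {s.district}/{s.year} outside the modelled window"
                )
            ui, ti = d_idx[s.district], y_idx[s.year]
            if s.total_count is None:
                continue
            obs_mask[ui, ti] = True
            counts[ui, ti] = s.total_count
            if s.has_classification:
                cls_mask[ui, ti] = True
                yc[ui, ti] = s.count_calves
                yaf[ui, ti] = s.count_adult_females
                yam[ui, ti] = s.count_adult_males
        return cls(
            districts=districts, years=years,
            h_calves=hc, h_adult_females=haf, h_adult_males=ham,
            X=X, design_names=design.names,
            obs_mask=obs_mask, counts=counts, cls_mask=cls_mask,
            y_calves=yc, y_adult_females=yaf, y_adult_males=yam,
        )

    def recruitment_tau(self, params: ProcessParameters) -> np.ndarray:
        """tau_{u,t} for transition years (column 0 is NaN)."""
        xb = np.einsum("utp,p->ut", self.X[:, 1:, :], params.beta)
        tau = np.full((self.n_districts, self.n_years), np.nan)
        tau[:, 1:] = invlogit(params.alpha + params.zeta[None, :] + xb)
        return tau


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def recruitment_rate(alpha, zeta_t, x_row, beta) -> float:
    """Per capita recruitment tau = invlogit(alpha + zeta_t + x'beta)."""
    x_row = np.asarray(x_row, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if x_row.shape != beta.shape:
        raise ValueError("covariate row and beta must have the same length")
    return float(invlogit(alpha + zeta_t + x_row @ beta))


def expected_transition(prev, harvest, phi_a: float, delta: float, tau: float):
    """Expected next-year class abundances (un-guarded; flooring at eps is the
    density's job).  ``prev`` and ``harvest`` are (calves, adult females,
    adult males) triples."""
    nc, naf, nam = prev
    hc, haf, ham = harvest
    e_calves = tau * naf - hc
    e_af = phi_a * (delta * nc + naf - haf)
    e_am = phi_a * ((1.0 - delta) * nc + nam - ham)
    return e_calves, e_af, e_am


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def _initial_log_prior(n0, h1, n_max: int, discrete: bool) -> np.ndarray:
    """Discrete (or continuous) uniform on [h1, n_max] per class; -inf outside."""
    width = (n_max - h1 + 1.0) if discrete else np.maximum(n_max - h1, 1e-12)
    lp = -np.log(width) * np.ones_like(np.asarray(n0, dtype=float))
    bad = (n0 < h1) | (n0 > n_max)
    if discrete:
        bad |= np.asarray(n0, dtype=float) % 1 != 0
    return np.where(bad, -np.inf, lp)


def log_process_density(
    latents: LatentStates,
    data: PopulationData,
    params: ProcessParameters,
    priors: PriorConfig = PriorConfig(),
    discrete: bool = True,
) -> float:
    """Initial-state priors plus the Poisson transition terms for t > first.

    Latent values below the initial-state truncation bound give -inf.
    """
    tau = data.recruitment_tau(params)
    nc, naf, nam = latents.n_calves, latents.n_adult_females, latents.n_adult_males
    lp = 0.0
    lp += np.sum(_initial_log_prior(nc[:, 0], data.h_calves[:, 1], priors.n_max, discrete))
    lp += np.sum(_initial_log_prior(naf[:, 0], data.h_adult_females[:, 1],
                                    priors.n_max, discrete))
    lp += np.sum(_initial_log_prior(nam[:, 0], data.h_adult_males[:, 1],
                                    priors.n_max, discrete))
    e_c, e_af, e_am = expected_transition(
        (nc[:, :-1], naf[:, :-1], nam[:, :-1]),
        (data.h_calves[:, 1:], data.h_adult_females[:, 1:], data.h_adult_males[:, 1:]),
        params.phi_a, params.delta, tau[:, 1:],
    )
    lp += np.sum(poisson_logpmf(nc[:, 1:], np.maximum(priors.eps, e_c)))
    lp += np.sum(poisson_logpmf(naf[:, 1:], np.maximum(priors.eps, e_af)))
    lp += np.sum(poisson_logpmf(nam[:, 1:], np.maximum(priors.eps, e_am)))
    return float(lp)


def log_observation_density(
    data: PopulationData,
    latents: LatentStates,
    params: ProcessParameters,
) -> float:
    """Count layer (overdispersed Poisson + Normal term for gamma) plus the
    multinomial classification layer where a classification exists."""
    ntot = latents.n_total
    lp = 0.0
    obs = data.obs_mask
    mu = ntot[obs] * np.exp(params.gamma[obs])
    y = data.counts[obs]
    with np.errstate(divide="ignore", invalid="ignore"):
        count_terms = xlogy(y, mu) - mu - gammaln(y + 1.0)
    lp += float(np.sum(count_terms))
    sigma = params.sigma_count
    lp += float(np.sum(
        -0.5 * np.log(2 * np.pi * sigma**2) - params.gamma[obs] ** 2 / (2 * sigma**2)
    ))
    cm = data.cls_mask
    if cm.any():
        n = data.cls_total[cm]
        with np.errstate(divide="ignore", invalid="ignore"):
            mult = (
                gammaln(n + 1.0)
                - gammaln(data.y_calves[cm] + 1.0)
                - gammaln(data.y_adult_females[cm] + 1.0)
                - gammaln(data.y_adult_males[cm] + 1.0)
                + xlogy(data.y_calves[cm], latents.n_calves[cm])
                + xlogy(data.y_adult_females[cm], latents.n_adult_females[cm])
                + xlogy(data.y_adult_males[cm], latents.n_adult_males[cm])
                - xlogy(n, ntot[cm])
            )
        lp += float(np.sum(mult))
    return lp


def log_prior(params: ProcessParameters, priors: PriorConfig = PriorConfig()) -> float:
    """Parameter priors: Beta(1,1) on phi_a, Normal(0, alpha_sd^2) on alpha,
    hierarchical Normal(0, sigma_beta^2) on each beta_j, Normal(0,
    sigma_zeta^2) on each zeta_t, Uniform(0, bound) on the three sds."""
    if not (0.0 < params.phi_a < 1.0):
        return -np.inf
    for sd, bound in (
        (params.sigma_zeta, priors.sigma_zeta_bound),
        (params.sigma_beta, priors.sigma_beta_bound),
        (params.sigma_count, priors.sigma_count_bound),
    ):
        if not (0.0 < sd < bound):
            return -np.inf
    lp = 0.0  # Beta(1,1) contributes log 1
    lp += -0.5 * np.log(2 * np.pi * priors.alpha_sd**2) \
        - params.alpha**2 / (2 * priors.alpha_sd**2)
    for sd, bound in (
        (params.sigma_zeta, priors.sigma_zeta_bound),
        (params.sigma_beta, priors.sigma_beta_bound),
        (params.sigma_count, priors.sigma_count_bound),
    ):
        lp += -np.log(bound)
    v_b = params.sigma_beta**2
    lp += float(np.sum(-0.5 * np.log(2 * np.pi * v_b) - params.beta**2 / (2 * v_b)))
    v_z = params.sigma_zeta**2
    lp += float(np.sum(-0.5 * np.log(2 * np.pi * v_z) - params.zeta**2 / (2 * v_z)))
    return float(lp)


def joint_log_density(
    latents: LatentStates,
    data: PopulationData,
    params: ProcessParameters,
    priors: PriorConfig = PriorConfig(),
    discrete: bool = True,
) -> float:
    """log prior + log process + log observation."""
    lp = log_prior(params, priors)
    if not np.isfinite(lp):
        return -np.inf
    lp += log_process_density(latents, data, params, priors, discrete=discrete)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_observation_density(data, latents, params)


# ---------------------------------------------------------------------------
# fitting and derived quantities
# ---------------------------------------------------------------------------

def fit(
    data: PopulationData,
    config: MCMCConfig | None = None,
    seed: int = 0,
    priors: PriorConfig = PriorConfig(),
    backend: str = "integer",
    adapt_interval: int = 50,
) -> PosteriorDraws:
    """Posterior sampling by Metropolis-within-Gibbs.

    Latent abundances are updated as non-negative integers with symmetric
    geometric-step random walks (``backend='integer'``) or as positive reals
    under the same densities (``backend='relaxed'``); scalar parameters use
    adaptive random-walk updates (adaptation frozen at the end of burn-in).
    When the study carries no observed surveys the joint factorises as
    prior x process and is sampled exactly by ancestral simulation.

    Returns draws for alpha, beta, zeta, phi_a, the sds, gamma and all latent
    abundances, with split-R-hat/ESS available via
    ``diagnostics.convergence_report``.
    """
    from .sampler import PopulationSampler  # deferred: keeps import graph flat

    config = config or MCMCConfig.population_default()
    sampler = PopulationSampler(data, priors=priors, config=config,
                                seed=seed, backend=backend,
                                adapt_interval=adapt_interval)
    return sampler.run()


def derive_lambda(
    draws: PosteriorDraws,
    data: PopulationData,
    district: str | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Posterior of the finite annual growth rate lambda_t = N_total(t) /
    N_total(t-1) for one district (or the region when ``district`` is None).

    Returns (samples with shape (n_draws, T-1), summary table).  Draws with a
    zero denominator are flagged missing (NaN).
    """
    ntot = (draws.stacked("n_calves") + draws.stacked("n_adult_females")
            + draws.stacked("n_adult_males"))   # (S, U, T)
    if district is not None:
        ui = data.districts.index(district)
        totals = ntot[:, ui, :]
    else:
        totals = ntot.sum(axis=1)
    prev = totals[:, :-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(prev > 0, totals[:, 1:] / prev, np.nan)
    rows = []
    for j, year in enumerate(data.years[1:]):
        col = lam[:, j]
        col = col[np.isfinite(col)]
        rows.append({"year": year, **summarize_samples(col)})
    return lam, pd.DataFrame(rows)


def predict_recruitment(
    draws: PosteriorDraws,
    profile,
    include_year_effect: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Posterior of tau at a covariate profile (standardized units):
    invlogit(alpha + x'beta), with zeta at zero for an average year or a
    fresh Normal(0, sigma_zeta) draw per sample when ``include_year_effect``
    (a new-year prediction).  Differences of profiles are just differences of
    these arrays because draws are aligned."""
    profile = np.asarray(profile, dtype=float)
    beta = draws.stacked("beta")
    if profile.shape[0] != beta.shape[1]:
        raise ValueError("profile length must match the design")
    eta = draws.stacked("alpha") + beta @ profile
    if include_year_effect:
        rng = rng or np.random.default_rng()
        eta = eta + rng.normal(0.0, draws.stacked("sigma_zeta"))
    return invlogit(eta)
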