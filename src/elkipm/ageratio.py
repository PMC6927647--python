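"""Gaussian linear model of observed calves:100-adult-females ratios.

The traditional analysis the state-space model is compared against: the
observed spring age ratio for district u in year t is modelled as

    ratio_{t,u} ~ Normal(mu_{t,u}, sigma_ageratio^2)
    mu_{t,u} = alpha + zeta_t + x_{t,u}' beta + beta_harvest * h^af_{t,u}

with an identity link, year random effects zeta_t ~ Normal(0, sigma_zeta^2),
a common shrinkage prior Normal(0, sigma_beta^2) over all regression
coefficients including the (standardized) adult-female harvest term, and a
diffuse Normal(0, 100) intercept.  The model is unconstrained: negative
predicted ratios are possible.

District-years without a classification are dropped (with a logged count);
only the population model can carry them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    HARVEST_TERM,
    CovariateTable,
    DataValidationError,
    DesignSpec,
    HarvestRecord,
    SurveyObservation,
    Term,
    build_design_matrix,
    observed_age_ratio,
    standardize,
)
from .draws import MCMCConfig, PosteriorDraws

__all__ = [
    "AgeRatioPriors",
    "AgeRatioParameters",
    "AgeRatioData",
    "expected_ratio",
    "log_density",
    "fit",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgeRatioPriors:
    """Intercept Normal(0, alpha_sd^2) with alpha_sd = 10 (variance 100);
    Uniform(0, bound) on the sds.  The residual-sd bound is wider than the
    other models' because the ratio scale admits much larger residual
    spread."""

    alpha_sd: float = 10.0
    sigma_zeta_bound: float = 10.0
    sigma_beta_bound: float = 10.0
    sigma_ratio_bound: float = 20.0


@dataclass
class AgeRatioParameters:
    alpha: float
    beta: np.ndarray           # all regression coefficients, harvest term last
    zeta: np.ndarray           # (T,) one effect per calendar year
    sigma_zeta: float
    sigma_ageratio: float
    sigma_beta: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.zeta = np.asarray(self.zeta, dtype=float)


@dataclass
class AgeRatioData:
    """Classification-complete district-years with their design rows."""

    districts: list[str]
    years: list[int]
    ratio: np.ndarray          # (n,)
    X: np.ndarray              # (n, P) including the harvest column if present
    design_names: list[str]
    year_index: np.ndarray     # (n,) index into ``years``
    row_district: list[str]

    @property
    def n_rows(self) -> int:
        return len(self.ratio)

    @property
    def n_terms(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_tables(
        cls,
        surveys: list[SurveyObservation],
        harvest: list[HarvestRecord],
        covariates: CovariateTable,
        design: DesignSpec,
        years: list[int] | None = None,
    ) -> "AgeRatioData":
        """Assemble the regression table.  The adult-female harvest covariate
        (term name ``adult_female_harvest``) is standardized over the rows of
        the harvest table inside the modelled window, like every other
        covariate."""
        if years is None:
            all_years = sorted({h.year for h in harvest})
            years = list(range(all_years[0], all_years[-1] + 1))
        haf = {(h.district, h.year): h.h_adult_females for h in harvest}
        uses_harvest = any(
            cov == HARVEST_TERM for t in design.terms for cov, _ in t.factors
        )
        extra = None
        if uses_harvest:
            vals = np.array([v for (d, y), v in haf.items() if y in years], dtype=float)
            mean, sd = float(vals.mean()), float(vals.std(ddof=1))
            if sd == 0:
                raise DataValidationError("adult-female harvest has zero variance")
            extra = {HARVEST_TERM: pd.Series(
                {k: (v - mean) / sd for k, v in haf.items()}
            )}
        std = standardize(covariates)
        # unlike the population model (whose first year has no transition),
        # a first-year ratio is usable as long as its lagged covariates exist
        design_df = build_design_matrix(std, design, years=years, extra=extra)

        rows, ratios, yidx, row_d = [], [], [], []
        dropped = 0
        for s in surveys:
            r = observed_age_ratio(s)
            if not np.isfinite(r):
                dropped += 1
                continue
            if s.year not in years:
                dropped += 1
                continue
            rows.append(design_df.loc[(s.district, s.year)].to_numpy(dtype=float))
            ratios.append(r)
            yidx.append(years.index(s.year))
            row_d.append(s.district)
        if dropped:
            logger.info("age-ratio model dropped %d rows without usable ratios",
                        dropped)
        if not rows:
            raise DataValidationError("no classification-complete rows")
        districts = sorted({d for d in row_d})
        return cls(
            districts=districts, years=list(years),
            ratio=np.asarray(ratios, dtype=float),
            X=np.vstack(rows), design_names=design.names,
            year_index=np.asarray(yidx, dtype=int), row_district=row_d,
        )


def expected_ratio(params: AgeRatioParameters, x_row, h_af: float,
                   zeta_t: float = 0.0) -> float:
    """mu = alpha + zeta_t + x'beta + beta_harvest * h_af, where the harvest
    coefficient is the last entry of ``params.beta`` and ``x_row`` carries
    the remaining covariate terms."""
    x_row = np.asarray(x_row, dtype=float)
    if x_row.shape[0] != params.beta.shape[0] - 1:
        raise ValueError("covariate row must match beta (excluding the harvest term)")
    return float(params.alpha + zeta_t + x_row @ params.beta[:-1]
                 + params.beta[-1] * h_af)


def log_density(data: AgeRatioData, params: AgeRatioParameters,
                priors: AgeRatioPriors = AgeRatioPriors()) -> float:
    """Gaussian likelihood over the classification-complete rows plus all
    priors (shrinkage over every regression coefficient, year effects,
    uniform sd priors)."""
    if not (0.0 < params.sigma_ageratio < priors.sigma_ratio_bound):
        return -np.inf
    if not (0.0 < params.sigma_zeta < priors.sigma_zeta_bound):
        return -np.inf
    if not (0.0 < params.sigma_beta < priors.sigma_beta_bound):
        return -np.inf
    mu = (params.alpha + params.zeta[data.year_index]
          + data.X @ params.beta)
    v = params.sigma_ageratio**2
    lp = float(np.sum(-0.5 * np.log(2 * np.pi * v) - (data.ratio - mu) ** 2 / (2 * v)))
    lp += -0.5 * np.log(2 * np.pi * priors.alpha_sd**2) \
        - params.alpha**2 / (2 * priors.alpha_sd**2)
    vb = params.sigma_beta**2
    lp += float(np.sum(-0.5 * np.log(2 * np.pi * vb) - params.beta**2 / (2 * vb)))
    vz = params.sigma_zeta**2
    lp += float(np.sum(-0.5 * np.log(2 * np.pi * vz) - params.zeta**2 / (2 * vz)))
    for bound in (priors.sigma_ratio_bound, priors.sigma_zeta_bound,
                  priors.sigma_beta_bound):
        lp += -np.log(bound)
    return lp


def fit(
    data: AgeRatioData,
    config: MCMCConfig | None = None,
    seed: int = 0,
    priors: AgeRatioPriors = AgeRatioPriors(),
) -> PosteriorDraws:
    """Gibbs sampling with conjugate normal blocks for (alpha, beta) and the
    year effects, and random-walk Metropolis steps for the three sds.

    Returns draws with the same container/summary interface as the
    population-model fit.
    """
    config = config or MCMCConfig.ageratio_default()
    rng = np.random.default_rng(seed)
    n, P = data.n_rows, data.n_terms
    T = len(data.years)
    C, K = config.chains, config.kept_per_chain

    A = np.hstack([np.ones((n, 1)), data.X])        # (n, P+1), intercept first
    AtA = A.T @ A
    Aty = A.T @ data.ratio
    M = np.zeros((n, T))
    M[np.arange(n), data.year_index] = 1.0
    AtM = A.T @ M                                    # (P+1, T)
    n_per_year = M.sum(axis=0)                       # (T,)
    Mty = M.T @ data.ratio

    # state (vectorized over chains)
    theta = np.zeros((C, P + 1))
    theta[:, 0] = rng.normal(np.mean(data.ratio), 2.0, size=C)
    zeta = np.zeros((C, T))
    s_ratio = rng.uniform(2.0, 10.0, size=C)
    s_zeta = rng.uniform(0.5, 3.0, size=C)
    s_beta = rng.uniform(0.5, 3.0, size=C)
    sc_sd = np.full((C, 3), 0.4)

    out = {
        "alpha": np.empty((C, K)),
        "beta": np.empty((C, K, P)),
        "zeta": np.empty((C, K, T)),
        "sigma_zeta": np.empty((C, K)),
        "sigma_ageratio": np.empty((C, K)),
        "sigma_beta": np.empty((C, K)),
    }
    eye = np.eye(P + 1)
    kept = 0
    for it in range(config.iterations):
        # -- (alpha, beta) block: conjugate multivariate normal
        prior_prec = np.empty((C, P + 1))
        prior_prec[:, 0] = 1.0 / priors.alpha_sd**2
        prior_prec[:, 1:] = (1.0 / s_beta**2)[:, None]
        Lam = AtA[None] / (s_ratio**2)[:, None, None] + np.einsum(
            "ij,cj->cij", eye, prior_prec)
        b = (Aty[None] - np.einsum("pt,ct->cp", AtM, zeta)) / (s_ratio**2)[:, None]
        Lchol = np.linalg.cholesky(Lam)
        mean = np.linalg.solve(Lam, b[:, :, None])[:, :, 0]
        z = rng.standard_normal((C, P + 1))
        # theta = mean + L^{-T} z
        pert = np.linalg.solve(np.transpose(Lchol, (0, 2, 1)), z[:, :, None])[:, :, 0]
        theta = mean + pert

        # -- year effects: independent conjugate normals
        resid_sum = Mty[None] - np.einsum("pt,cp->ct", AtM, theta)
        prec = n_per_year[None] / (s_ratio**2)[:, None] + (1.0 / s_zeta**2)[:, None]
        zmean = (resid_sum / (s_ratio**2)[:, None]) / prec
        zeta = zmean + rng.standard_normal((C, T)) / np.sqrt(prec)

        # -- sds: random-walk Metropolis
        mu_rows = theta @ A.T + zeta[:, data.year_index]
        ss = ((data.ratio[None] - mu_rows) ** 2).sum(axis=1)
        for k, (attr_idx, ssq, m, bound) in enumerate((
            (0, ss, n, priors.sigma_ratio_bound),
            (1, (zeta**2).sum(axis=1), T, priors.sigma_zeta_bound),
            (2, (theta[:, 1:] ** 2).sum(axis=1), P, priors.sigma_beta_bound),
        )):
            cur = (s_ratio, s_zeta, s_beta)[attr_idx]
            prop = cur + rng.normal(0.0, sc_sd[:, k])
            okp = (prop > 0) & (prop < bound)
            safe = np.where(okp, prop, cur)
            d = -m * (np.log(safe) - np.log(cur)) - 0.5 * ssq * (1 / safe**2 - 1 / cur**2)
            acc = okp & (np.log(rng.random(C)) < d)
            new = np.where(acc, safe, cur)
            if attr_idx == 0:
                s_ratio = new
            elif attr_idx == 1:
                s_zeta = new
            else:
                s_beta = new

        if it >= config.burnin and (it - config.burnin) % config.thin == config.thin - 1 \
                and kept < K:
            out["alpha"][:, kept] = theta[:, 0]
            out["beta"][:, kept] = theta[:, 1:]
            out["zeta"][:, kept] = zeta
            out["sigma_zeta"][:, kept] = s_zeta
            out["sigma_ageratio"][:, kept] = s_ratio
            out["sigma_beta"][:, kept] = s_beta
            kept += 1

    coords = {"beta": list(data.design_names), "zeta": [int(y) for y in data.years]}
    meta = {"model": "ageratio", "n_rows": n, "kept": kept}
    return PosteriorDraws(data=out, config=config, coords=coords, meta=meta)
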