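"""Posterior-predictive goodness-of-fit and convergence reporting.

Discrepancy measures follow the fitted models' own checks: an omnibus
sum-of-squared residuals for the Gaussian age-ratio model, the Freeman-Tukey
statistic sum((sqrt(y) - sqrt(E))^2) for the total counts, and the sample
variance of classified calf counts for the recruitment signal.  One-sided
Bayesian p-values are the fraction of kept draws whose replicated-data
discrepancy exceeds the observed-data discrepancy (ties counted as 1/2,
which keeps degenerate checks at p = 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .ageratio import AgeRatioData
from .draws import PosteriorDraws
from .population import PopulationData

__all__ = [
    "PpcResult",
    "discrepancy_ssq",
    "discrepancy_freeman_tukey",
    "discrepancy_calf_variance",
    "posterior_predictive_check",
    "split_rhat",
    "convergence_report",
]


def discrepancy_ssq(values, expected) -> float:
    """Sum of squared residuals sum((y_i - E_i)^2)."""
    y = np.asarray(values, dtype=float)
    e = np.asarray(expected, dtype=float)
    if y.shape != e.shape:
        raise ValueError("values and expected must have the same length")
    return float(np.sum((y - e) ** 2))


def discrepancy_freeman_tukey(counts, expected) -> float:
    """Freeman-Tukey statistic sum((sqrt(y_i) - sqrt(E_i))^2)."""
    y = np.asarray(counts, dtype=float)
    e = np.asarray(expected, dtype=float)
    if y.shape != e.shape:
        raise ValueError("counts and expected must have the same length")
    if (y < 0).any():
        raise ValueError("negative count in Freeman-Tukey discrepancy")
    return float(np.sum((np.sqrt(y) - np.sqrt(e)) ** 2))


def discrepancy_calf_variance(calf_counts) -> float:
    """Sample variance (n-1 denominator) of classified calf counts."""
    y = np.asarray(calf_counts, dtype=float)
    if y.size < 2:
        raise ValueError("calf-variance discrepancy needs at least 2 values")
    return float(np.var(y, ddof=1))


@dataclass
class PpcResult:
    """Per-draw observed and replicated discrepancies and the one-sided
    Bayesian p-value (fraction of draws with replicated > observed; ties
    count 1/2)."""

    discrepancy: str
    observed: np.ndarray
    replicated: np.ndarray
    bayesian_p: float


def _bayes_p(rep: np.ndarray, obs: np.ndarray) -> float:
    return float(np.mean((rep > obs) + 0.5 * (rep == obs)))


def _thin_draws(arr: np.ndarray, max_draws: int) -> np.ndarray:
    """Stack chains and subsample evenly to at most ``max_draws`` draws."""
    flat = arr.reshape((-1,) + arr.shape[2:])
    if flat.shape[0] <= max_draws:
        return flat
    idx = np.linspace(0, flat.shape[0] - 1, max_draws).astype(int)
    return flat[idx]


def posterior_predictive_check(
    draws: PosteriorDraws,
    data,
    discrepancy: str,
    rng: np.random.Generator | None = None,
    regenerate_gamma: bool = True,
    max_draws: int = 1000,
) -> PpcResult:
    """Replicate the observation layer once per kept draw and compare
    discrepancies.

    Population-model checks (``data`` is a :class:`PopulationData`):
    ``freeman_tukey`` on the total counts (expected value conditional on the
    latent states, E = N_total exp(gamma)), and ``calf_variance`` on the
    classified calf counts (replicated from the multinomial layer with the
    observed classified totals).  With ``regenerate_gamma`` the replicated
    survey draws a fresh observation effect per site (a new-survey
    prediction); otherwise the fitted gamma is reused.

    Age-ratio checks (``data`` is an :class:`AgeRatioData`): ``ssq`` on the
    ratios against their conditional means.
    """
    rng = rng or np.random.default_rng()
    if isinstance(data, PopulationData):
        if discrepancy not in ("freeman_tukey", "calf_variance"):
            raise ValueError(
                f"discrepancy {discrepancy!r} not defined for the population model"
            )
        ntot = (_thin_draws(draws["n_calves"], max_draws)
                + _thin_draws(draws["n_adult_females"], max_draws)
                + _thin_draws(draws["n_adult_males"], max_draws)).astype(float)
        S = ntot.shape[0]
        obs_mask = data.obs_mask
        gamma_fit = _thin_draws(draws["gamma"], max_draws).astype(float)
        if regenerate_gamma:
            sig = _thin_draws(draws["sigma_count"], max_draws)
            gamma_rep = rng.normal(0.0, sig[:, None, None],
                                   size=(S,) + obs_mask.shape)
        else:
            gamma_rep = gamma_fit
        if discrepancy == "freeman_tukey":
            e_obs = ntot[:, obs_mask] * np.exp(gamma_fit[:, obs_mask])
            e_rep = ntot[:, obs_mask] * np.exp(gamma_rep[:, obs_mask])
            y_obs = data.counts[obs_mask]
            y_rep = rng.poisson(e_rep)
            d_obs = np.sum((np.sqrt(y_obs[None]) - np.sqrt(e_obs)) ** 2, axis=1)
            d_rep = np.sum((np.sqrt(y_rep) - np.sqrt(e_rep)) ** 2, axis=1)
        else:
            cm = data.cls_mask
            if cm.sum() < 2:
                raise ValueError("calf-variance check needs >= 2 classified sites")
            nc = _thin_draws(draws["n_calves"], max_draws).astype(float)
            pi_c = np.where(ntot[:, cm] > 0, nc[:, cm] / np.maximum(ntot[:, cm], 1e-12),
                            0.0)
            n_cls = data.cls_total[cm].astype(int)
            y_rep = rng.binomial(n_cls[None].repeat(S, 0), np.clip(pi_c, 0.0, 1.0))
            d_obs = np.full(S, discrepancy_calf_variance(data.y_calves[cm]))
            d_rep = np.var(y_rep, axis=1, ddof=1)
    elif isinstance(data, AgeRatioData):
        if discrepancy != "ssq":
            raise ValueError(
                f"discrepancy {discrepancy!r} not defined for the age-ratio model"
            )
        alpha = _thin_draws(draws["alpha"], max_draws)
        beta = _thin_draws(draws["beta"], max_draws)
        zeta = _thin_draws(draws["zeta"], max_draws)
        sigma = _thin_draws(draws["sigma_ageratio"], max_draws)
        mu = alpha[:, None] + beta @ data.X.T + zeta[:, data.year_index]
        y_rep = rng.normal(mu, sigma[:, None])
        d_obs = np.sum((data.ratio[None] - mu) ** 2, axis=1)
        d_rep = np.sum((y_rep - mu) ** 2, axis=1)
    else:
        raise ValueError(f"unsupported data container {type(data).__name__}")
    return PpcResult(
        discrepancy=discrepancy,
        observed=d_obs,
        replicated=d_rep,
        bayesian_p=_bayes_p(d_rep, d_obs),
    )


# ---------------------------------------------------------------------------
# convergence
# ---------------------------------------------------------------------------

def split_rhat(samples: np.ndarray) -> float:
    """Classic split R-hat: chains halved, between/within variance ratio."""
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2:
        raise ValueError("split_rhat expects (chain, draw) samples")
    c, n = arr.shape
    if c < 1 or n < 4:
        return float("nan")
    half = n // 2
    seqs = np.concatenate([arr[:, :half], arr[:, half: 2 * half]], axis=0)
    m, n2 = seqs.shape
    w = np.mean(np.var(seqs, axis=1, ddof=1))
    b = n2 * np.var(np.mean(seqs, axis=1), ddof=1)
    if w == 0:
        return 1.0
    var_plus = (n2 - 1) / n2 * w + b / n2
    return float(np.sqrt(var_plus / w))


def convergence_report(draws: PosteriorDraws,
                       names: list[str] | None = None) -> pd.DataFrame:
    """Per-parameter split R-hat (own implementation) and effective sample
    size (bulk ESS via arviz).  With a single chain R-hat is unavailable and
    a warning is issued."""
    default = [n for n in ("alpha", "beta", "zeta", "phi_a", "sigma_zeta",
                           "sigma_beta", "sigma_count", "sigma_ageratio")
               if n in draws]
    names = names or default
    single = draws[names[0]].shape[0] < 2
    if single:
        warnings.warn("split R-hat needs at least two chains", stacklevel=2)
    rows = []
    for name in names:
        arr = draws[name]
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        labels = draws.coords.get(name)
        for j in range(flat.shape[2]):
            label = name if flat.shape[2] == 1 else (
                f"{name}[{labels[j]}]" if labels and j < len(labels) else f"{name}[{j}]"
            )
            chainwise = flat[:, :, j]
            rhat = float("nan") if single else split_rhat(chainwise)
            ess = float(az.ess(az.convert_to_dataset(chainwise[..., None]),
                               method="bulk")["x"].values.item())
            rows.append({"parameter": label, "rhat": rhat, "ess": ess})
    return pd.DataFrame(rows)
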