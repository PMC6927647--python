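"""Metropolis-within-Gibbs sampler for the state-space population model.

All chains run simultaneously as a leading array axis.  Latent abundances are
updated site-by-site with symmetric random-walk proposals -- geometric step
sizes on the integers (the faithful backend) or Gaussian steps on positive
reals (the continuous relaxation; identical densities with the Poisson pmf
evaluated at real-valued states).  Within one sweep the latent updates are
organised as an even/odd-year checkerboard per class, which makes every
proposal in a batch conditionally independent of the others (no transition or
observation term links two states of the same class two years apart), so the
whole batch vectorises.

Scalar parameters (alpha, each beta_j, phi_a, the sds), the year effects and
the observation random effects use adaptive Gaussian random walks; proposal
scales adapt toward a 0.44 acceptance rate during burn-in only and are frozen
afterwards.

When the study has no observed surveys the posterior factorises as
prior x process and is sampled exactly by ancestral simulation (parameters
from their priors, latent states forward through the process equations).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, xlogy

from .draws import MCMCConfig, PosteriorDraws
from .population import (
    LatentStates,
    PopulationData,
    PriorConfig,
    ProcessParameters,
    invlogit,
    joint_log_density,
)

__all__ = ["PopulationSampler"]

_ACCEPT_TARGET = 0.44


def _plp(y, mu):
    """Poisson log-pmf (real-valued y allowed)."""
    return xlogy(y, mu) - mu - gammaln(y + 1.0)


def _plp_nc(y, mu):
    """Poisson log-pmf without the gammaln(y+1) term (cancels when only the
    mean changes)."""
    return xlogy(y, mu) - mu


class PopulationSampler:
    def __init__(
        self,
        data: PopulationData,
        priors: PriorConfig,
        config: MCMCConfig,
        seed: int = 0,
        backend: str = "integer",
        adapt_interval: int = 50,
    ) -> None:
        if backend not in ("integer", "relaxed"):
            raise ValueError("backend must be 'integer' or 'relaxed'")
        self.data = data
        self.priors = priors
        self.config = config
        self.backend = backend
        self.discrete = backend == "integer"
        self.adapt_interval = adapt_interval
        self.rng = np.random.default_rng(seed)

        self.U, self.T = data.n_districts, data.n_years
        self.P = data.n_terms
        self.C = config.chains
        self.eps = priors.eps
        self.delta = 0.5

        self.hc = data.h_calves.astype(float)
        self.haf = data.h_adult_females.astype(float)
        self.ham = data.h_adult_males.astype(float)
        self.hc1, self.haf1, self.ham1 = self.hc[:, 1:], self.haf[:, 1:], self.ham[:, 1:]
        self.X1 = data.X[:, 1:, :]
        self.obs = data.obs_mask
        self.cnt = data.counts.astype(float)
        self.cls = data.cls_mask
        self.yc = data.y_calves.astype(float)
        self.yaf = data.y_adult_females.astype(float)
        self.yam = data.y_adult_males.astype(float)
        self.ncls = self.yc + self.yaf + self.yam
        self.n_obs = int(self.obs.sum())

        self.t_parity = (np.arange(self.T) % 2 == 0), (np.arange(self.T) % 2 == 1)

    # -- initialization ----------------------------------------------------

    def _initial_latents(self):
        U, T, C = self.U, self.T, self.C
        ntot = np.zeros((U, T))
        share_c = np.full(U, 0.20)
        share_af = np.full(U, 0.55)
        for u in range(U):
            t_obs = np.nonzero(self.obs[u])[0]
            if t_obs.size:
                ntot[u] = np.interp(np.arange(T), t_obs,
                                    np.maximum(self.cnt[u, t_obs], 10.0))
            else:
                ntot[u] = 500.0
            t_cls = np.nonzero(self.cls[u] & (self.ncls[u] > 0))[0]
            if t_cls.size:
                share_c[u] = np.mean(self.yc[u, t_cls] / self.ncls[u, t_cls])
                share_af[u] = np.mean(self.yaf[u, t_cls] / self.ncls[u, t_cls])
        share_c = np.clip(share_c, 0.05, 0.6)
        share_af = np.clip(share_af, 0.2, 0.85)

        jitter = self.rng.uniform(0.85, 1.15, size=(C, U, T))
        base = ntot[None] * jitter
        Nc = np.round(base * share_c[None, :, None])
        Naf = np.round(base * share_af[None, :, None])
        Nam = np.round(base * (1.0 - share_c - share_af)[None, :, None])
        for arr, y in ((Nc, self.yc), (Naf, self.yaf), (Nam, self.yam)):
            arr[:] = np.maximum(arr, np.where(self.cls & (y > 0), np.maximum(y, 1.0), 1.0))
        # initial-year truncation bounds
        n_max = float(self.priors.n_max)
        Nc[:, :, 0] = np.clip(Nc[:, :, 0], self.hc[:, 1], n_max)
        Naf[:, :, 0] = np.clip(Naf[:, :, 0], self.haf[:, 1], n_max)
        Nam[:, :, 0] = np.clip(Nam[:, :, 0], self.ham[:, 1], n_max)
        if self.discrete:
            Nc, Naf, Nam = np.round(Nc), np.round(Naf), np.round(Nam)
        return Nc, Naf, Nam

    def _init_state(self) -> None:
        C, P, Tm1 = self.C, self.P, self.T - 1
        rng = self.rng
        for attempt in range(10):
            self.Nc, self.Naf, self.Nam = self._initial_latents()
            self.alpha = rng.uniform(np.log(0.1 / 0.9), np.log(0.5 / 0.5), size=C)
            self.beta = np.zeros((C, P))
            self.zeta = np.zeros((C, Tm1))
            self.phi = rng.uniform(0.5, 0.95, size=C)
            self.s_zeta = rng.uniform(0.2, 1.0, size=C)
            self.s_beta = rng.uniform(0.1, 0.5, size=C)
            self.s_count = rng.uniform(0.05, 0.5, size=C)
            self.gamma = np.zeros((C, self.U, self.T))
            if np.all(np.isfinite(self._chain_joints())):
                return
        raise RuntimeError("could not find a finite starting state")

    def _chain_joints(self) -> np.ndarray:
        out = np.empty(self.C)
        for c in range(self.C):
            params = ProcessParameters(
                alpha=float(self.alpha[c]), beta=self.beta[c], zeta=self.zeta[c],
                phi_a=float(self.phi[c]), sigma_zeta=float(self.s_zeta[c]),
                sigma_beta=float(self.s_beta[c]), sigma_count=float(self.s_count[c]),
                gamma=self.gamma[c], delta=self.delta,
            )
            latents = LatentStates(self.Nc[c], self.Naf[c], self.Nam[c])
            out[c] = joint_log_density(latents, self.data, params, self.priors,
                                       discrete=self.discrete)
        return out

    def _init_scales(self) -> None:
        C, U, T = self.C, self.U, self.T
        base = np.maximum(2.0, np.sqrt(np.maximum(self.Nc, 1.0)) * 0.5)
        self.sc_Nc = base.copy()
        self.sc_Naf = np.maximum(2.0, np.sqrt(np.maximum(self.Naf, 1.0)) * 0.5)
        self.sc_Nam = np.maximum(2.0, np.sqrt(np.maximum(self.Nam, 1.0)) * 0.5)
        self.sc_gamma = np.full((C, U, T), 0.1)
        self.sc_alpha = np.full(C, 0.05)
        self.sc_beta = np.full((C, self.P), 0.05)
        self.sc_zeta = np.full((C, T - 1), 0.1)
        self.sc_phi = np.full(C, 0.02)
        self.sc_szeta = np.full(C, 0.2)
        self.sc_sbeta = np.full(C, 0.2)
        self.sc_scount = np.full(C, 0.1)
        self._acc = {}
        self._props = {}

    # -- proposal helpers --------------------------------------------------

    def _latent_step(self, scale):
        if self.discrete:
            step = self.rng.geometric(np.minimum(1.0, 1.0 / scale))
            sign = self.rng.integers(0, 2, size=scale.shape) * 2 - 1
            return step * sign
        return self.rng.normal(0.0, scale)

    def _bump(self, key, acc, n=1):
        self._acc[key] = self._acc.get(key, 0.0) + acc
        self._props[key] = self._props.get(key, 0) + n

    # -- current-state caches ----------------------------------------------

    def _xb(self):
        return np.einsum("utp,cp->cut", self.X1, self.beta)

    def _tau1(self, xb=None):
        if xb is None:
            xb = self._xb()
        return invlogit(self.alpha[:, None, None] + self.zeta[:, None, :] + xb)

    def _mu_c(self, tau1, Naf):
        return np.maximum(self.eps, tau1 * Naf[:, :, :-1] - self.hc1)

    def _mu_af(self, Nc, Naf, phi):
        return np.maximum(self.eps, phi[:, None, None]
                          * (self.delta * Nc[:, :, :-1] + Naf[:, :, :-1] - self.haf1))

    def _mu_am(self, Nc, Nam, phi):
        return np.maximum(self.eps, phi[:, None, None]
                          * ((1 - self.delta) * Nc[:, :, :-1] + Nam[:, :, :-1] - self.ham1))

    # -- observation-layer delta for a single-class change -------------------

    def _obs_delta(self, class_cur, class_new, y_class):
        ntot = self.Nc + self.Naf + self.Nam
        ntot_new = ntot + (class_new - class_cur)
        eg = np.exp(self.gamma)
        with np.errstate(divide="ignore", invalid="ignore"):
            d_count = (xlogy(self.cnt, ntot_new) - xlogy(self.cnt, ntot)
                       - eg * (ntot_new - ntot))
            d_cls = (xlogy(y_class, class_new) - xlogy(y_class, class_cur)
                     - xlogy(self.ncls, ntot_new) + xlogy(self.ncls, ntot))
        out = np.where(self.obs, d_count, 0.0)
        out += np.where(self.cls, d_cls, 0.0)
        return out

    # -- latent updates ----------------------------------------------------

    def _update_calves(self, parity: int) -> None:
        mask = self.t_parity[parity]
        prop = self.Nc + self._latent_step(self.sc_Nc) * mask
        ok = prop >= 0
        ok[:, :, 0] &= (prop[:, :, 0] >= self.hc[:, 1]) & (prop[:, :, 0] <= self.priors.n_max)
        safe = np.where(ok, prop, self.Nc)

        tau1 = self._tau1()
        mu_c = self._mu_c(tau1, self.Naf)
        d = np.zeros_like(self.Nc)
        d[:, :, 1:] = _plp(safe[:, :, 1:], mu_c) - _plp(self.Nc[:, :, 1:], mu_c)
        mu_af_new = self._mu_af(safe, self.Naf, self.phi)
        mu_af_cur = self._mu_af(self.Nc, self.Naf, self.phi)
        d[:, :, :-1] += (_plp_nc(self.Naf[:, :, 1:], mu_af_new)
                         - _plp_nc(self.Naf[:, :, 1:], mu_af_cur))
        mu_am_new = self._mu_am(safe, self.Nam, self.phi)
        mu_am_cur = self._mu_am(self.Nc, self.Nam, self.phi)
        d[:, :, :-1] += (_plp_nc(self.Nam[:, :, 1:], mu_am_new)
                         - _plp_nc(self.Nam[:, :, 1:], mu_am_cur))
        d += self._obs_delta(self.Nc, safe, self.yc)

        logu = np.log(self.rng.random(size=self.Nc.shape))
        acc = mask & ok & (logu < d)
        self.Nc = np.where(acc, safe, self.Nc)
        self._bump("Nc", acc.astype(float))

    def _update_adult_females(self, parity: int) -> None:
        mask = self.t_parity[parity]
        prop = self.Naf + self._latent_step(self.sc_Naf) * mask
        ok = prop >= 0
        ok[:, :, 0] &= (prop[:, :, 0] >= self.haf[:, 1]) & (prop[:, :, 0] <= self.priors.n_max)
        safe = np.where(ok, prop, self.Naf)

        tau1 = self._tau1()
        mu_af_cur = self._mu_af(self.Nc, self.Naf, self.phi)
        d = np.zeros_like(self.Naf)
        d[:, :, 1:] = _plp(safe[:, :, 1:], mu_af_cur) - _plp(self.Naf[:, :, 1:], mu_af_cur)
        # feeding next year's calves (tau * N_af) and adult females
        mu_c_new = self._mu_c(tau1, safe)
        mu_c_cur = self._mu_c(tau1, self.Naf)
        d[:, :, :-1] += (_plp_nc(self.Nc[:, :, 1:], mu_c_new)
                         - _plp_nc(self.Nc[:, :, 1:], mu_c_cur))
        mu_af_new = self._mu_af(self.Nc, safe, self.phi)
        d[:, :, :-1] += (_plp_nc(self.Naf[:, :, 1:], mu_af_new)
                         - _plp_nc(self.Naf[:, :, 1:], mu_af_cur))
        d += self._obs_delta(self.Naf, safe, self.yaf)

        logu = np.log(self.rng.random(size=self.Naf.shape))
        acc = mask & ok & (logu < d)
        self.Naf = np.where(acc, safe, self.Naf)
        self._bump("Naf", acc.astype(float))

    def _update_adult_males(self, parity: int) -> None:
        mask = self.t_parity[parity]
        prop = self.Nam + self._latent_step(self.sc_Nam) * mask
        ok = prop >= 0
        ok[:, :, 0] &= (prop[:, :, 0] >= self.ham[:, 1]) & (prop[:, :, 0] <= self.priors.n_max)
        safe = np.where(ok, prop, self.Nam)

        mu_am_cur = self._mu_am(self.Nc, self.Nam, self.phi)
        d = np.zeros_like(self.Nam)
        d[:, :, 1:] = _plp(safe[:, :, 1:], mu_am_cur) - _plp(self.Nam[:, :, 1:], mu_am_cur)
        mu_am_new = self._mu_am(self.Nc, safe, self.phi)
        d[:, :, :-1] += (_plp_nc(self.Nam[:, :, 1:], mu_am_new)
                         - _plp_nc(self.Nam[:, :, 1:], mu_am_cur))
        d += self._obs_delta(self.Nam, safe, self.yam)

        logu = np.log(self.rng.random(size=self.Nam.shape))
        acc = mask & ok & (logu < d)
        self.Nam = np.where(acc, safe, self.Nam)
        self._bump("Nam", acc.astype(float))

    # -- parameter updates ---------------------------------------------------

    def _update_gamma(self) -> None:
        if self.n_obs == 0:
            return
        ntot = self.Nc + self.Naf + self.Nam
        prop = self.gamma + self.rng.normal(0.0, self.sc_gamma)
        v = self.s_count[:, None, None] ** 2
        d = (self.cnt * (prop - self.gamma)
             - ntot * (np.exp(prop) - np.exp(self.gamma))
             - (prop**2 - self.gamma**2) / (2 * v))
        logu = np.log(self.rng.random(size=prop.shape))
        acc = self.obs & (logu < d)
        self.gamma = np.where(acc, prop, self.gamma)
        self._bump("gamma", acc.astype(float))

    def _calf_ll(self, mu_c):
        return _plp_nc(self.Nc[:, :, 1:], mu_c).sum(axis=(1, 2))

    def _adult_ll(self, phi):
        mu_af = self._mu_af(self.Nc, self.Naf, phi)
        mu_am = self._mu_am(self.Nc, self.Nam, phi)
        return (_plp_nc(self.Naf[:, :, 1:], mu_af).sum(axis=(1, 2))
                + _plp_nc(self.Nam[:, :, 1:], mu_am).sum(axis=(1, 2)))

    def _update_alpha(self) -> None:
        xb = self._xb()
        cur = self._calf_ll(self._mu_c(self._tau1(xb), self.Naf))
        prop = self.alpha + self.rng.normal(0.0, self.sc_alpha)
        tau_new = invlogit(prop[:, None, None] + self.zeta[:, None, :] + xb)
        new = self._calf_ll(self._mu_c(tau_new, self.Naf))
        var = self.priors.alpha_sd**2
        d = new - cur - (prop**2 - self.alpha**2) / (2 * var)
        acc = np.log(self.rng.random(self.C)) < d
        self.alpha = np.where(acc, prop, self.alpha)
        self._bump("alpha", acc.astype(float))

    def _update_beta(self) -> None:
        xb = self._xb()
        base = self.alpha[:, None, None] + self.zeta[:, None, :]
        cur = self._calf_ll(self._mu_c(invlogit(base + xb), self.Naf))
        vb = self.s_beta**2
        for j in range(self.P):
            bj = self.beta[:, j]
            prop = bj + self.rng.normal(0.0, self.sc_beta[:, j])
            xb_new = xb + (prop - bj)[:, None, None] * self.X1[None, :, :, j]
            new = self._calf_ll(self._mu_c(invlogit(base + xb_new), self.Naf))
            d = new - cur - (prop**2 - bj**2) / (2 * vb)
            acc = np.log(self.rng.random(self.C)) < d
            self.beta[:, j] = np.where(acc, prop, bj)
            xb = np.where(acc[:, None, None], xb_new, xb)
            cur = np.where(acc, new, cur)
            self._bump(f"beta{j}", acc.astype(float))

    def _update_zeta(self) -> None:
        xb = self._xb()
        base = self.alpha[:, None, None] + xb
        mu_cur = self._mu_c(invlogit(base + self.zeta[:, None, :]), self.Naf)
        ll_cur = _plp_nc(self.Nc[:, :, 1:], mu_cur).sum(axis=1)   # (C, T-1)
        prop = self.zeta + self.rng.normal(0.0, self.sc_zeta)
        mu_new = self._mu_c(invlogit(base + prop[:, None, :]), self.Naf)
        ll_new = _plp_nc(self.Nc[:, :, 1:], mu_new).sum(axis=1)
        v = self.s_zeta[:, None] ** 2
        d = ll_new - ll_cur - (prop**2 - self.zeta**2) / (2 * v)
        acc = np.log(self.rng.random(size=prop.shape)) < d
        self.zeta = np.where(acc, prop, self.zeta)
        self._bump("zeta", acc.astype(float))

    def _recenter_alpha_zeta(self) -> None:
        """Exact Gibbs move along the alpha/zeta ridge: shifting alpha by eps
        and every zeta_t by -eps leaves all recruitment rates (hence the whole
        likelihood) unchanged, and the conditional of eps under the priors is
        Gaussian.  Without this move alpha mixes very slowly because only
        alpha + zeta_t is likelihood-identified."""
        Tm1 = self.T - 1
        prec = 1.0 / self.priors.alpha_sd**2 + Tm1 / self.s_zeta**2
        mean = (-self.alpha / self.priors.alpha_sd**2
                + self.zeta.sum(axis=1) / self.s_zeta**2) / prec
        eps = mean + self.rng.standard_normal(self.C) / np.sqrt(prec)
        self.alpha = self.alpha + eps
        self.zeta = self.zeta - eps[:, None]

    def _update_phi(self) -> None:
        prop = self.phi + self.rng.normal(0.0, self.sc_phi)
        ok = (prop > 0.0) & (prop < 1.0)
        safe = np.where(ok, prop, self.phi)
        d = self._adult_ll(safe) - self._adult_ll(self.phi)
        acc = ok & (np.log(self.rng.random(self.C)) < d)
        self.phi = np.where(acc, safe, self.phi)
        self._bump("phi", acc.astype(float))

    def _update_sd(self, name, values_sq_sum, n_terms, bound, scale_attr, attr):
        cur = getattr(self, attr)
        prop = cur + self.rng.normal(0.0, getattr(self, scale_attr))
        ok = (prop > 0.0) & (prop < bound)
        safe = np.where(ok, prop, cur)
        d = (-n_terms * (np.log(safe) - np.log(cur))
             - 0.5 * values_sq_sum * (1.0 / safe**2 - 1.0 / cur**2))
        acc = ok & (np.log(self.rng.random(self.C)) < d)
        setattr(self, attr, np.where(acc, safe, cur))
        self._bump(name, acc.astype(float))

    def _update_sds(self) -> None:
        self._update_sd("s_zeta", (self.zeta**2).sum(axis=1), self.T - 1,
                        self.priors.sigma_zeta_bound, "sc_szeta", "s_zeta")
        self._update_sd("s_beta", (self.beta**2).sum(axis=1), self.P,
                        self.priors.sigma_beta_bound, "sc_sbeta", "s_beta")
        if self.n_obs:
            gsq = (self.gamma**2 * self.obs).sum(axis=(1, 2))
            self._update_sd("s_count", gsq, self.n_obs,
                            self.priors.sigma_count_bound, "sc_scount", "s_count")

    # -- adaptation ----------------------------------------------------------

    def _adapt(self, batch: int) -> None:
        lr = min(0.3, 2.0 / np.sqrt(batch))
        n = self.adapt_interval

        def tune(scale, *keys, lo=1e-4, hi=50.0):
            rate = sum(self._acc.pop(k, 0.0) for k in keys) / (n * len(keys))
            for k in keys:
                self._props.pop(k, None)
            return np.clip(scale * np.exp(lr * (rate - _ACCEPT_TARGET)), lo, hi)

        self.sc_Nc = tune(self.sc_Nc, "Nc", lo=1.0, hi=500.0)
        self.sc_Naf = tune(self.sc_Naf, "Naf", lo=1.0, hi=500.0)
        self.sc_Nam = tune(self.sc_Nam, "Nam", lo=1.0, hi=500.0)
        if not self.discrete:
            self.sc_Nc = np.maximum(self.sc_Nc, 0.05)
            self.sc_Naf = np.maximum(self.sc_Naf, 0.05)
            self.sc_Nam = np.maximum(self.sc_Nam, 0.05)
        if self.n_obs:
            self.sc_gamma = tune(self.sc_gamma, "gamma", lo=1e-3, hi=5.0)
            self.sc_scount = tune(self.sc_scount, "s_count", lo=1e-3, hi=5.0)
        self.sc_alpha = tune(self.sc_alpha, "alpha", lo=1e-3, hi=2.0)
        for j in range(self.P):
            self.sc_beta[:, j] = tune(self.sc_beta[:, j], f"beta{j}", lo=1e-3, hi=2.0)
        self.sc_zeta = tune(self.sc_zeta, "zeta", lo=1e-3, hi=2.0)
        self.sc_phi = tune(self.sc_phi, "phi", lo=1e-4, hi=0.5)
        self.sc_szeta = tune(self.sc_szeta, "s_zeta", lo=1e-3, hi=5.0)
        self.sc_sbeta = tune(self.sc_sbeta, "s_beta", lo=1e-3, hi=5.0)

    # -- adaptation note: per-site latent/gamma rates are tracked per site
    # (arrays), scalar rates per chain; both go through the same tune().

    # -- main loops ----------------------------------------------------------

    def _sweep(self) -> None:
        for parity in (0, 1):
            self._update_calves(parity)
            self._update_adult_females(parity)
            self._update_adult_males(parity)
        self._update_gamma()
        self._update_alpha()
        self._update_beta()
        self._update_zeta()
        self._recenter_alpha_zeta()
        self._update_phi()
        self._update_sds()

    def run(self) -> PosteriorDraws:
        if self.n_obs == 0:
            return self._run_ancestral()
        self._init_state()
        self._init_scales()
        cfg = self.config
        K = cfg.kept_per_chain
        C, U, T, P = self.C, self.U, self.T, self.P
        out = {
            "alpha": np.empty((C, K)),
            "beta": np.empty((C, K, P)),
            "zeta": np.empty((C, K, T - 1)),
            "phi_a": np.empty((C, K)),
            "sigma_zeta": np.empty((C, K)),
            "sigma_beta": np.empty((C, K)),
            "sigma_count": np.empty((C, K)),
            "n_calves": np.empty((C, K, U, T), dtype=np.float32),
            "n_adult_females": np.empty((C, K, U, T), dtype=np.float32),
            "n_adult_males": np.empty((C, K, U, T), dtype=np.float32),
            "gamma": np.empty((C, K, U, T), dtype=np.float32),
        }
        kept = 0
        batch = 0
        for it in range(cfg.iterations):
            self._sweep()
            if it < cfg.burnin:
                if (it + 1) % self.adapt_interval == 0:
                    batch += 1
                    self._adapt(batch)
            else:
                if (it - cfg.burnin) % cfg.thin == cfg.thin - 1 and kept < K:
                    out["alpha"][:, kept] = self.alpha
                    out["beta"][:, kept] = self.beta
                    out["zeta"][:, kept] = self.zeta
                    out["phi_a"][:, kept] = self.phi
                    out["sigma_zeta"][:, kept] = self.s_zeta
                    out["sigma_beta"][:, kept] = self.s_beta
                    out["sigma_count"][:, kept] = self.s_count
                    out["n_calves"][:, kept] = self.Nc
                    out["n_adult_females"][:, kept] = self.Naf
                    out["n_adult_males"][:, kept] = self.Nam
                    out["gamma"][:, kept] = self.gamma
                    kept += 1
        coords = {
            "beta": list(self.data.design_names),
            "zeta": [int(y) for y in self.data.years[1:]],
        }
        meta = {"backend": self.backend, "districts": self.data.districts,
                "years": self.data.years, "kept": kept}
        return PosteriorDraws(data=out, config=cfg, coords=coords, meta=meta)

    # -- exact sampling when there is no observation layer --------------------

    def _run_ancestral(self) -> PosteriorDraws:
        cfg = self.config
        pri = self.priors
        K = cfg.kept_per_chain
        C, U, T, P = self.C, self.U, self.T, self.P
        rng = self.rng
        shape = (C, K)
        s_zeta = rng.uniform(0.0, pri.sigma_zeta_bound, size=shape)
        s_beta = rng.uniform(0.0, pri.sigma_beta_bound, size=shape)
        s_count = rng.uniform(0.0, pri.sigma_count_bound, size=shape)
        alpha = rng.normal(0.0, pri.alpha_sd, size=shape)
        phi = rng.uniform(0.0, 1.0, size=shape)
        beta = rng.normal(0.0, 1.0, size=shape + (P,)) * s_beta[..., None]
        zeta = rng.normal(0.0, 1.0, size=shape + (T - 1,)) * s_zeta[..., None]

        Nc = np.zeros(shape + (U, T))
        Naf = np.zeros_like(Nc)
        Nam = np.zeros_like(Nc)
        hi = pri.n_max + 1 if self.discrete else pri.n_max
        Nc[..., 0] = rng.integers(self.hc[:, 1][None, None], hi, size=shape + (U,))
        Naf[..., 0] = rng.integers(self.haf[:, 1][None, None], hi, size=shape + (U,))
        Nam[..., 0] = rng.integers(self.ham[:, 1][None, None], hi, size=shape + (U,))
        xb = np.einsum("utp,ckp->ckut", self.X1, beta)
        tau1 = invlogit(alpha[..., None, None] + zeta[..., None, :] + xb)
        for t in range(1, T):
            mu_c = np.maximum(pri.eps, tau1[..., t - 1] * Naf[..., t - 1] - self.hc[:, t])
            mu_af = np.maximum(pri.eps, phi[..., None]
                               * (0.5 * Nc[..., t - 1] + Naf[..., t - 1] - self.haf[:, t]))
            mu_am = np.maximum(pri.eps, phi[..., None]
                               * (0.5 * Nc[..., t - 1] + Nam[..., t - 1] - self.ham[:, t]))
            Nc[..., t] = rng.poisson(mu_c)
            Naf[..., t] = rng.poisson(mu_af)
            Nam[..., t] = rng.poisson(mu_am)
        out = {
            "alpha": alpha, "beta": beta, "zeta": zeta, "phi_a": phi,
            "sigma_zeta": s_zeta, "sigma_beta": s_beta, "sigma_count": s_count,
            "n_calves": Nc.astype(np.float32),
            "n_adult_females": Naf.astype(np.float32),
            "n_adult_males": Nam.astype(np.float32),
            "gamma": np.zeros(shape + (U, T), dtype=np.float32),
        }
        coords = {"beta": list(self.data.design_names),
                  "zeta": [int(y) for y in self.data.years[1:]]}
        meta = {"backend": self.backend, "districts": self.data.districts,
                "years": self.data.years, "kept": K, "exact": True}
        return PosteriorDraws(data=out, config=cfg, coords=coords, meta=meta)
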