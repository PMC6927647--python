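"""Population model: densities vs brute-force oracles, HPD, short fits."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

from elkipm import population as pm
from elkipm import simulate
from elkipm.data import DesignSpec
from elkipm.draws import MCMCConfig, hpd_interval, summarize_samples


# ---------------------------------------------------------------------------
# independent term-by-term oracle (pure python loops, scipy distributions)
# ---------------------------------------------------------------------------

def oracle_joint(latents, data, params, priors):
    """Brute-force joint log density: every pmf/pdf term added one by one."""
    lp = 0.0
    # parameter priors
    if not (0 < params.phi_a < 1):
        return -np.inf
    for sd, bound in ((params.sigma_zeta, priors.sigma_zeta_bound),
                      (params.sigma_beta, priors.sigma_beta_bound),
                      (params.sigma_count, priors.sigma_count_bound)):
        if not (0 < sd < bound):
            return -np.inf
        lp += stats.uniform.logpdf(sd, 0, bound)
    lp += stats.beta.logpdf(params.phi_a, 1, 1)
    lp += stats.norm.logpdf(params.alpha, 0, priors.alpha_sd)
    for b in params.beta:
        lp += stats.norm.logpdf(b, 0, params.sigma_beta)
    for z in params.zeta:
        lp += stats.norm.logpdf(z, 0, params.sigma_zeta)

    U, T = data.n_districts, data.n_years
    nc = latents.n_calves
    naf = latents.n_adult_females
    nam = latents.n_adult_males
    for u in range(U):
        for cls_arr, h_arr in ((nc, data.h_calves),
                               (naf, data.h_adult_females),
                               (nam, data.h_adult_males)):
            lo, hi = h_arr[u, 1], priors.n_max
            if not (lo <= cls_arr[u, 0] <= hi):
                return -np.inf
            lp += -np.log(hi - lo + 1)
        for t in range(1, T):
            tau = expit(params.alpha + params.zeta[t - 1]
                        + data.X[u, t] @ params.beta)
            mu_c = max(priors.eps, tau * naf[u, t - 1] - data.h_calves[u, t])
            mu_af = max(priors.eps, params.phi_a * (
                params.delta * nc[u, t - 1] + naf[u, t - 1]
                - data.h_adult_females[u, t]))
            mu_am = max(priors.eps, params.phi_a * (
                (1 - params.delta) * nc[u, t - 1] + nam[u, t - 1]
                - data.h_adult_males[u, t]))
            lp += stats.poisson.logpmf(nc[u, t], mu_c)
            lp += stats.poisson.logpmf(naf[u, t], mu_af)
            lp += stats.poisson.logpmf(nam[u, t], mu_am)
        for t in range(T):
            if not data.obs_mask[u, t]:
                continue
            ntot = nc[u, t] + naf[u, t] + nam[u, t]
            lp += stats.poisson.logpmf(data.counts[u, t],
                                       ntot * np.exp(params.gamma[u, t]))
            lp += stats.norm.logpdf(params.gamma[u, t], 0, params.sigma_count)
            if data.cls_mask[u, t]:
                ys = [data.y_calves[u, t], data.y_adult_females[u, t],
                      data.y_adult_males[u, t]]
                pis = [nc[u, t] / ntot, naf[u, t] / ntot, nam[u, t] / ntot]
                lp += stats.multinomial.logpmf(ys, int(sum(ys)), pis)
    return float(lp)


@pytest.fixture(scope="module")
def tiny_instance():
    """2 districts x 4 years with observations, classification gaps and a
    parameter point away from the generator truth."""
    districts = ["A", "B"]
    years = [2004, 2005, 2006, 2007]
    design = DesignSpec.from_strings(["spring_precip", "swe"])
    cfg = simulate.ScenarioConfig(
        districts=districts, years=years, design=design,
        beta=np.array([-0.2, 0.1]),
        coverage={"A": years, "B": [2004, 2006, 2007]},
        classification_missing=[("A", 2005)],
        seed=21,
    )
    surveys, harvest, cov, truth = simulate.make_study(cfg)
    data = pm.PopulationData.from_tables(surveys, harvest, cov, design)
    t = truth["latent_states"]
    latents = pm.LatentStates(np.array(t["n_calves"]),
                              np.array(t["n_adult_females"]),
                              np.array(t["n_adult_males"]))
    params = pm.ProcessParameters(
        alpha=-1.0, beta=np.array([-0.15, 0.05]),
        zeta=np.array([0.1, -0.2, 0.05]), phi_a=0.8,
        sigma_zeta=0.5, sigma_beta=0.3, sigma_count=0.12,
        gamma=np.where(data.obs_mask, 0.03, 0.0),
    )
    return data, latents, params


class TestRecruitmentRate:
    def test_mean_recruitment_profile(self):
        assert pm.recruitment_rate(logit(0.25), 0.0, [], []) == pytest.approx(0.25)

    def test_one_sd_shift_moves_rate(self):
        tau = pm.recruitment_rate(logit(0.25), 0.0, [1.0], [-0.2])
        assert tau == pytest.approx(expit(logit(0.25) - 0.2), abs=1e-12)
        assert tau == pytest.approx(0.214, abs=5e-4)

    def test_zero_linear_predictor_is_half(self):
        assert pm.recruitment_rate(0.0, 0.0, [0.0], [0.3]) == 0.5

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            pm.recruitment_rate(0.0, 0.0, [1.0, 2.0], [0.1])


class TestExpectedTransition:
    def test_direct_evaluation(self):
        e = pm.expected_transition((100, 200, 50), (0, 0, 0), 1.0, 0.5, 0.25)
        assert e == (50.0, 250.0, 100.0)

    def test_zero_recruitment(self):
        assert pm.expected_transition((10, 20, 5), (0, 0, 0), 0.9, 0.5, 0.0)[0] == 0.0

    def test_full_female_removal(self):
        e = pm.expected_transition((100, 200, 50), (0, 250, 0), 0.9, 0.5, 0.25)
        assert e[1] == pytest.approx(0.0)


class TestDensities:
    def test_joint_matches_bruteforce_oracle(self, tiny_instance):
        data, latents, params = tiny_instance
        mine = pm.joint_log_density(latents, data, params)
        oracle = oracle_joint(latents, data, params, pm.PriorConfig())
        assert mine == pytest.approx(oracle, abs=1e-8)

    def test_joint_is_sum_of_three_components(self, tiny_instance):
        data, latents, params = tiny_instance
        total = pm.joint_log_density(latents, data, params)
        parts = (pm.log_prior(params)
                 + pm.log_process_density(latents, data, params)
                 + pm.log_observation_density(data, latents, params))
        assert total == pytest.approx(parts, abs=1e-10)

    def test_single_transition_term(self):
        # one district, two years, N_af at its mean: the af term is the
        # Poisson log-pmf at 250
        cfg_design = DesignSpec.from_strings(["swe"])
        data = pm.PopulationData(
            districts=["A"], years=[2004, 2005],
            h_calves=np.zeros((1, 2)), h_adult_females=np.zeros((1, 2)),
            h_adult_males=np.zeros((1, 2)),
            X=np.zeros((1, 2, 1)), design_names=cfg_design.names,
            obs_mask=np.zeros((1, 2), bool), counts=np.zeros((1, 2)),
            cls_mask=np.zeros((1, 2), bool), y_calves=np.zeros((1, 2)),
            y_adult_females=np.zeros((1, 2)), y_adult_males=np.zeros((1, 2)),
        )
        params = pm.ProcessParameters(
            alpha=logit(0.25), beta=np.zeros(1), zeta=np.zeros(1), phi_a=1.0,
            sigma_zeta=1.0, sigma_beta=1.0, sigma_count=1.0,
            gamma=np.zeros((1, 2)),
        )
        latents = pm.LatentStates(np.array([[100, 50]]), np.array([[200, 250]]),
                                  np.array([[150, 200]]))
        lp = pm.log_process_density(latents, data, params)
        # means: calves 0.25*200 = 50; females 0.5*100+200 = 250 (value at
        # its mean); males 0.5*100+150 = 200
        expected = (
            -3 * np.log(10_000 + 1)
            + stats.poisson.logpmf(50, 50)
            + stats.poisson.logpmf(250, 250)
            + stats.poisson.logpmf(200, 200)
        )
        assert lp == pytest.approx(float(expected), abs=1e-10)

    def test_initial_state_below_harvest_truncation_is_minus_inf(self, tiny_instance):
        data, latents, params = tiny_instance
        bad = pm.LatentStates(latents.n_calves.copy(),
                              latents.n_adult_females.copy(),
                              latents.n_adult_males.copy())
        bad.n_calves[0, 0] = max(0, data.h_calves[0, 1] - 1)
        assert pm.log_process_density(bad, data, params) == -np.inf

    def test_out_of_support_prior_is_minus_inf(self, tiny_instance):
        _, _, params = tiny_instance
        import copy
        p2 = copy.deepcopy(params)
        p2.sigma_zeta = 11.0
        assert pm.log_prior(p2) == -np.inf
        p3 = copy.deepcopy(params)
        p3.phi_a = 1.5
        assert pm.log_prior(p3) == -np.inf

    def test_flat_prior_values(self, tiny_instance):
        _, _, params = tiny_instance
        import copy
        p = copy.deepcopy(params)
        # alpha at 0 contributes -0.5 log(2 pi); phi contributes 0
        p.alpha = 0.0
        p.beta = np.zeros(0)
        p.zeta = np.zeros(0)
        lp = pm.log_prior(p)
        expected = -0.5 * np.log(2 * np.pi) - 3 * np.log(10.0)
        assert lp == pytest.approx(float(expected), abs=1e-12)

    def test_label_invariance_under_district_permutation(self, tiny_instance):
        data, latents, params = tiny_instance
        perm = [1, 0]
        import dataclasses
        data2 = dataclasses.replace(
            data,
            districts=[data.districts[i] for i in perm],
            h_calves=data.h_calves[perm], h_adult_females=data.h_adult_females[perm],
            h_adult_males=data.h_adult_males[perm], X=data.X[perm],
            obs_mask=data.obs_mask[perm], counts=data.counts[perm],
            cls_mask=data.cls_mask[perm], y_calves=data.y_calves[perm],
            y_adult_females=data.y_adult_females[perm],
            y_adult_males=data.y_adult_males[perm],
        )
        latents2 = pm.LatentStates(latents.n_calves[perm],
                                   latents.n_adult_females[perm],
                                   latents.n_adult_males[perm])
        import copy
        params2 = copy.deepcopy(params)
        params2.gamma = params.gamma[perm]
        assert pm.joint_log_density(latents2, data2, params2) == pytest.approx(
            pm.joint_log_density(latents, data, params), abs=1e-10
        )


class TestHpdInterval:
    def test_uniform_ties_take_lowest_start(self):
        lo, hi = hpd_interval(np.arange(1, 101), 0.9)
        assert (lo, hi) == (1.0, 90.0)

    def test_identical_samples_zero_width(self):
        assert hpd_interval(np.full(50, 3.3), 0.5) == (3.3, 3.3)

    def test_matches_exhaustive_window_oracle(self):
        rng = np.random.default_rng(8)
        x = np.sort(rng.normal(size=301))
        k = int(np.ceil(0.9 * x.size))
        best = min(
            ((x[i + k - 1] - x[i], x[i], x[i + k - 1])
             for i in range(x.size - k + 1)),
        )
        assert hpd_interval(x, 0.9) == (best[1], best[2])

    def test_symmetric_unimodal_close_to_central_interval(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40_000)
        lo, hi = hpd_interval(x, 0.9)
        assert lo == pytest.approx(-1.645, abs=0.06)
        assert hi == pytest.approx(1.645, abs=0.06)

    def test_bad_mass_errors(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(20), 1.5)

    def test_summaries_nest(self):
        s = summarize_samples(np.random.default_rng(0).normal(size=2000))
        assert s["hpd90_low"] <= s["hpd50_low"] <= s["median"] \
            <= s["hpd50_high"] <= s["hpd90_high"]


class TestFit:
    def test_draw_counts_follow_protocol(self, small_scenario):
        surveys, harvest, cov, _ = simulate.make_study(small_scenario)
        data = pm.PopulationData.from_tables(surveys, harvest, cov,
                                             small_scenario.design)
        mc = MCMCConfig(chains=2, iterations=60, burnin=20, thin=4)
        draws = pm.fit(data, mc, seed=0)
        assert draws["alpha"].shape == (2, 10)
        assert draws["n_calves"].shape[:2] == (2, 10)

    def test_reproducible_given_seed(self, small_scenario):
        surveys, harvest, cov, _ = simulate.make_study(small_scenario)
        data = pm.PopulationData.from_tables(surveys, harvest, cov,
                                             small_scenario.design)
        mc = MCMCConfig(chains=2, iterations=80, burnin=30, thin=1)
        d1 = pm.fit(data, mc, seed=7)
        d2 = pm.fit(data, mc, seed=7)
        np.testing.assert_array_equal(d1["alpha"], d2["alpha"])
        np.testing.assert_array_equal(d1["n_calves"], d2["n_calves"])

    def test_latent_draws_respect_truncation_and_sign(self, small_scenario):
        surveys, harvest, cov, _ = simulate.make_study(small_scenario)
        data = pm.PopulationData.from_tables(surveys, harvest, cov,
                                             small_scenario.design)
        mc = MCMCConfig(chains=2, iterations=300, burnin=100, thin=1)
        draws = pm.fit(data, mc, seed=3)
        for name, h in (("n_calves", data.h_calves),
                        ("n_adult_females", data.h_adult_females),
                        ("n_adult_males", data.h_adult_males)):
            arr = draws.stacked(name)
            assert (arr >= 0).all()
            assert (arr[:, :, 0] >= h[None, :, 1]).all()

    def test_fitted_totals_track_counts_when_overdispersion_tiny(self):
        # sigma_count ~ 0 and full classification: posterior median N_total
        # stays within Poisson noise of the observed counts
        cfg = simulate.make_scenario(
            seed=13, n_districts=4, first_year=2004, last_year=2009,
            sigma_count=1e-4, classification_missing=[],
            classification_fraction=(0.9, 1.0),
            coverage={f"HD{200 + 10 * i}": list(range(2004, 2010))
                      for i in range(4)},
        )
        surveys, harvest, cov, _ = simulate.make_study(cfg)
        data = pm.PopulationData.from_tables(surveys, harvest, cov, cfg.design)
        draws = pm.fit(data, MCMCConfig.reduced(chains=2, kept=600, burnin=600),
                       seed=5)
        ntot = (draws.stacked("n_calves") + draws.stacked("n_adult_females")
                + draws.stacked("n_adult_males"))
        med = np.median(ntot, axis=0)
        obs = data.obs_mask
        resid = med[obs] - data.counts[obs]
        assert np.all(np.abs(resid) < 4 * np.sqrt(data.counts[obs]) + 5)

    def test_relaxed_backend_agrees_on_location(self, small_study, small_scenario):
        surveys, harvest, cov, truth = small_study
        data = pm.PopulationData.from_tables(surveys, harvest, cov,
                                             small_scenario.design)
        mc = MCMCConfig.reduced(chains=2, kept=800, burnin=800)
        d_int = pm.fit(data, mc, seed=2, backend="integer")
        d_rel = pm.fit(data, mc, seed=2, backend="relaxed")
        a_int = np.median(d_int.stacked("alpha"))
        a_rel = np.median(d_rel.stacked("alpha"))
        assert abs(a_int - a_rel) < 0.25
        p_int = np.median(d_int.stacked("phi_a"))
        p_rel = np.median(d_rel.stacked("phi_a"))
        assert abs(p_int - p_rel) < 0.1


class TestDerivedQuantities:
    def _draws_with_latents(self, data, nc, naf, nam):
        from elkipm.draws import PosteriorDraws
        mc = MCMCConfig(chains=1, iterations=20, burnin=0, thin=1)
        S = 20
        return PosteriorDraws(
            data={
                "n_calves": np.broadcast_to(nc, (1, S) + nc.shape).copy(),
                "n_adult_females": np.broadcast_to(naf, (1, S) + naf.shape).copy(),
                "n_adult_males": np.broadcast_to(nam, (1, S) + nam.shape).copy(),
            },
            config=mc,
        )

    def test_constant_totals_give_lambda_one(self, tiny_instance):
        data, _, _ = tiny_instance
        shape = (data.n_districts, data.n_years)
        draws = self._draws_with_latents(
            data, np.full(shape, 100.0), np.full(shape, 200.0), np.full(shape, 50.0))
        lam, table = pm.derive_lambda(draws, data, district="A")
        np.testing.assert_allclose(lam, 1.0)
        assert (table["median"] == 1.0).all()

    def test_doubling_totals_give_lambda_two(self, tiny_instance):
        data, _, _ = tiny_instance
        T = data.n_years
        base = 100 * 2 ** np.arange(T, dtype=float)
        grid = np.tile(base, (data.n_districts, 1))
        draws = self._draws_with_latents(data, grid, grid, grid)
        lam, _ = pm.derive_lambda(draws, data)
        np.testing.assert_allclose(lam, 2.0)

    def test_lambda_covers_generator_trajectory(self, small_study, small_scenario):
        surveys, harvest, cov, truth = small_study
        data = pm.PopulationData.from_tables(surveys, harvest, cov,
                                             small_scenario.design)
        draws = pm.fit(data, MCMCConfig.reduced(chains=2, kept=800, burnin=800),
                       seed=11)
        t = truth["latent_states"]
        true_tot = (np.array(t["n_calves"]) + np.array(t["n_adult_females"])
                    + np.array(t["n_adult_males"])).sum(axis=0)
        true_lam = true_tot[1:] / true_tot[:-1]
        lam, table = pm.derive_lambda(draws, data)
        lo = np.array([hpd_interval(lam[:, j], 0.98)[0] for j in range(lam.shape[1])])
        hi = np.array([hpd_interval(lam[:, j], 0.98)[1] for j in range(lam.shape[1])])
        # generous interval: most years should bracket the realized ratio
        assert np.mean((true_lam >= lo - 0.03) & (true_lam <= hi + 0.03)) >= 0.8

    def test_predict_recruitment_profiles(self, small_study, small_scenario):
        surveys, harvest, cov, _ = small_study
        data = pm.PopulationData.from_tables(surveys, harvest, cov,
                                             small_scenario.design)
        draws = pm.fit(data, MCMCConfig.reduced(chains=2, kept=200, burnin=200),
                       seed=4)
        zero = pm.predict_recruitment(draws, np.zeros(data.n_terms))
        np.testing.assert_allclose(
            zero, pm.invlogit(draws.stacked("alpha")), atol=1e-12)
        same = pm.predict_recruitment(draws, np.zeros(data.n_terms)) - zero
        np.testing.assert_allclose(same, 0.0)
        with pytest.raises(ValueError):
            pm.predict_recruitment(draws, np.zeros(data.n_terms + 1))

    def test_prior_recovery_without_observations(self, small_scenario):
        _, harvest, cov, _ = simulate.make_study(small_scenario)
        data = pm.PopulationData.from_tables([], harvest, cov,
                                             small_scenario.design)
        draws = pm.fit(data, MCMCConfig.reduced(chains=2, kept=4000, burnin=10),
                       seed=9)
        phi = draws.stacked("phi_a")
        assert phi.mean() == pytest.approx(0.5, abs=0.02)
        assert phi.std() == pytest.approx(np.sqrt(1 / 12.0), abs=0.02)
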