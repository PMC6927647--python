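"""Discrepancies, posterior-predictive checks, convergence, power report."""

import numpy as np
import pytest

import arviz as az

from elkipm import ageratio as ar
from elkipm import diagnostics as dg
from elkipm import population as pm
from elkipm import simulate
from elkipm.data import DesignSpec, HARVEST_TERM, Term
from elkipm.draws import MCMCConfig, PosteriorDraws
from elkipm.experiments import PowerReport, detects, power_experiment


class TestDiscrepancies:
    def test_ssq(self):
        assert dg.discrepancy_ssq([3, 5], [1, 2]) == 13.0
        assert dg.discrepancy_ssq([1.5, 2.5], [1.5, 2.5]) == 0.0
        with pytest.raises(ValueError):
            dg.discrepancy_ssq([1, 2], [1])

    def test_ssq_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        y, e = rng.normal(size=30), rng.normal(size=30)
        loop = sum((yi - ei) ** 2 for yi, ei in zip(y, e))
        assert dg.discrepancy_ssq(y, e) == pytest.approx(loop, rel=1e-12)

    def test_freeman_tukey(self):
        assert dg.discrepancy_freeman_tukey([4, 9], [1, 4]) == pytest.approx(2.0)
        assert dg.discrepancy_freeman_tukey([7, 7], [7, 7]) == 0.0
        with pytest.raises(ValueError):
            dg.discrepancy_freeman_tukey([-1], [1])

    def test_freeman_tukey_quarter_chi2_limit(self):
        # for Poisson counts at large mean, E[(sqrt(y)-sqrt(mu))^2] -> 1/4
        rng = np.random.default_rng(1)
        mu = 400.0
        y = rng.poisson(mu, size=20_000)
        per_obs = np.mean((np.sqrt(y) - np.sqrt(mu)) ** 2)
        assert per_obs == pytest.approx(0.25, abs=0.02)

    def test_calf_variance(self):
        assert dg.discrepancy_calf_variance([10, 20]) == pytest.approx(50.0)
        assert dg.discrepancy_calf_variance([4, 4, 4]) == 0.0
        with pytest.raises(ValueError):
            dg.discrepancy_calf_variance([4])


class TestBayesP:
    def test_ties_count_half(self):
        assert dg._bayes_p(np.zeros(10), np.zeros(10)) == 0.5

    def test_monotone_rescale_invariance(self):
        rng = np.random.default_rng(2)
        obs = rng.random(500)
        rep = rng.random(500)
        p1 = dg._bayes_p(rep, obs)
        p2 = dg._bayes_p(np.exp(3 * rep), np.exp(3 * obs))
        assert p1 == p2


@pytest.fixture(scope="module")
def fitted_small(small_scenario_module=None):
    districts = [f"HD{i}" for i in range(5)]
    years = list(range(2004, 2011))
    design = DesignSpec.from_strings(["spring_precip", "swe"])
    cfg = simulate.ScenarioConfig(
        districts=districts, years=years, design=design,
        beta=np.array([-0.2, 0.0]),
        coverage={d: years for d in districts},
        classification_missing=[(districts[0], 2006)],
        seed=31,
    )
    surveys, harvest, cov, truth = simulate.make_study(cfg)
    data = pm.PopulationData.from_tables(surveys, harvest, cov, design)
    draws = pm.fit(data, MCMCConfig.reduced(chains=2, kept=700, burnin=700), seed=3)
    return cfg, surveys, harvest, cov, data, draws


class TestPosteriorPredictiveCheck:
    def test_population_checks_not_extreme_on_own_data(self, fitted_small):
        *_, data, draws = fitted_small
        rng = np.random.default_rng(0)
        for disc in ("freeman_tukey", "calf_variance"):
            res = dg.posterior_predictive_check(draws, data, disc, rng)
            assert 0.01 < res.bayesian_p < 0.99, disc
            assert res.observed.shape == res.replicated.shape

    def test_incompatible_discrepancy_errors(self, fitted_small):
        *_, data, draws = fitted_small
        with pytest.raises(ValueError):
            dg.posterior_predictive_check(draws, data, "ssq")

    def test_doubled_calf_counts_flagged_by_calf_variance(self, fitted_small):
        # corrupt the observed data and check it against the fitted model's
        # predictive distribution: the calf-variance p-value must go extreme
        cfg, surveys, harvest, cov, data, draws = fitted_small
        from elkipm.data import SurveyObservation
        corrupted = []
        for s in surveys:
            if s.has_classification:
                corrupted.append(SurveyObservation(
                    s.district, s.year, s.total_count + s.count_calves,
                    2 * s.count_calves, s.count_adult_females, s.count_adult_males))
            else:
                corrupted.append(s)
        data2 = pm.PopulationData.from_tables(corrupted, harvest, cov, cfg.design)
        res = dg.posterior_predictive_check(
            draws, data2, "calf_variance", np.random.default_rng(1))
        assert res.bayesian_p < 0.05 or res.bayesian_p > 0.95

    def test_degenerate_ageratio_check_gives_half(self):
        # sigma -> 0 and data exactly at expectations: all discrepancies tie
        n = 12
        data = ar.AgeRatioData(
            districts=["A"], years=[2004], ratio=np.full(n, 25.0),
            X=np.zeros((n, 1)), design_names=["x0"],
            year_index=np.zeros(n, dtype=int), row_district=["A"] * n,
        )
        S = 40
        draws = PosteriorDraws(
            data={
                "alpha": np.full((1, S), 25.0),
                "beta": np.zeros((1, S, 1)),
                "zeta": np.zeros((1, S, 1)),
                "sigma_ageratio": np.zeros((1, S)),
            },
            config=MCMCConfig(chains=1, iterations=S, burnin=0, thin=1),
        )
        res = dg.posterior_predictive_check(draws, data, "ssq",
                                            np.random.default_rng(0))
        assert res.bayesian_p == pytest.approx(0.5)

    def test_replicated_rows_obey_schema(self, fitted_small):
        # replicated counts are integers within [0, classified total]
        *_, data, draws = fitted_small
        rng = np.random.default_rng(5)
        res = dg.posterior_predictive_check(draws, data, "calf_variance", rng)
        assert np.isfinite(res.replicated).all()
        assert (res.replicated >= 0).all()


class TestConvergenceReport:
    def test_iid_chains_have_rhat_one(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(size=(4, 2000))
        assert dg.split_rhat(arr) == pytest.approx(1.0, abs=0.01)

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(4)
        arr = rng.normal(size=(4, 1000)) + np.array([[0.0], [0.0], [3.0], [3.0]])
        assert dg.split_rhat(arr) > 1.1

    def test_matches_arviz_split_rhat(self):
        rng = np.random.default_rng(5)
        arr = rng.normal(size=(4, 500)) * np.array([[1.0], [1.2], [0.8], [1.1]])
        ours = dg.split_rhat(arr)
        theirs = float(az.rhat(az.convert_to_dataset(arr[..., None]),
                               method="split")["x"].values.item())
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_report_shape_and_single_chain_warns(self):
        rng = np.random.default_rng(6)
        draws = PosteriorDraws(
            data={"alpha": rng.normal(size=(4, 200)),
                  "beta": rng.normal(size=(4, 200, 2))},
            config=MCMCConfig(chains=4, iterations=200, burnin=0, thin=1),
            coords={"beta": ["a", "b"]},
        )
        rep = dg.convergence_report(draws, names=["alpha", "beta"])
        assert list(rep["parameter"]) == ["alpha", "beta[a]", "beta[b]"]
        assert (rep["ess"] > 100).all()
        single = PosteriorDraws(
            data={"alpha": rng.normal(size=(1, 200))},
            config=MCMCConfig(chains=1, iterations=200, burnin=0, thin=1),
        )
        with pytest.warns(UserWarning):
            rep1 = dg.convergence_report(single, names=["alpha"])
        assert np.isnan(rep1["rhat"]).all()


class TestPowerExperiment:
    def test_single_replicate_degenerate_fractions(self):
        districts = [f"HD{i}" for i in range(5)]
        years = list(range(2004, 2011))
        design = DesignSpec.from_strings(["spring_precip", "swe"])
        cfg = simulate.ScenarioConfig(
            districts=districts, years=years, design=design,
            beta=np.array([-0.2, 0.0]),
            coverage={d: years for d in districts}, seed=41,
        )
        report = power_experiment(
            cfg, n_replicates=1,
            mcmc_population=MCMCConfig.reduced(chains=2, kept=400, burnin=400),
            mcmc_ageratio=MCMCConfig.reduced(chains=2, kept=400, burnin=200),
            seed=0,
        )
        for name in report.coefficients:
            assert report.detection_population[name] in (0.0, 1.0)
            assert report.detection_ageratio[name] in (0.0, 1.0)
        assert report.n_replicates == 1

    def test_report_reproducible_and_serializable(self, tmp_path):
        districts = [f"HD{i}" for i in range(4)]
        years = list(range(2004, 2010))
        design = DesignSpec.from_strings(["spring_precip"])
        cfg = simulate.ScenarioConfig(
            districts=districts, years=years, design=design,
            beta=np.array([-0.2]), coverage={d: years for d in districts},
            seed=17,
        )
        kwargs = dict(
            n_replicates=2,
            mcmc_population=MCMCConfig.reduced(chains=2, kept=300, burnin=300),
            mcmc_ageratio=MCMCConfig.reduced(chains=2, kept=300, burnin=150),
            seed=5,
        )
        r1 = power_experiment(cfg, **kwargs)
        r2 = power_experiment(cfg, **kwargs)
        assert r1.per_replicate == r2.per_replicate
        r1.to_json(tmp_path / "report.json")
        import json
        payload = json.loads((tmp_path / "report.json").read_text())
        assert payload["n_replicates"] == 2
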