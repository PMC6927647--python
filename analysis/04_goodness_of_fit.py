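"""Posterior-predictive goodness-of-fit for both models.

Refits both models to the working study (reduced protocol) and computes the
three Bayesian p-values: Freeman-Tukey on the total counts and the variance
of classified calf counts for the population model, and the sum-of-squared
residuals for the age-ratio model.  Values near 0.5 indicate the replicated
data resemble the observed data; values near 0 or 1 flag misfit.  Writes
results/gof.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from elkipm import ageratio as ar
from elkipm import diagnostics as dg
from elkipm import population as pm
from elkipm.data import (
    DesignSpec, HARVEST_TERM, Term,
    read_covariate_table, read_harvest_table, read_survey_table,
)
from elkipm.draws import MCMCConfig
from elkipm.simulate import default_scenario_design

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/study"))
parser.add_argument("--seed", type=int, default=4)
parser.add_argument("--out", type=Path, default=Path("results/gof.json"))
args = parser.parse_args()

surveys = read_survey_table(args.study / "surveys.csv")
harvest = read_harvest_table(args.study / "harvest.csv")
cov = read_covariate_table(args.study / "covariates.csv")
design = default_scenario_design()

data = pm.PopulationData.from_tables(surveys, harvest, cov, design)
draws = pm.fit(data, MCMCConfig.reduced(chains=4, kept=2500, burnin=1200),
               seed=args.seed)
rng = np.random.default_rng(args.seed + 1)
gof = {}
for disc in ("freeman_tukey", "calf_variance"):
    res = dg.posterior_predictive_check(draws, data, disc, rng)
    gof[f"population_{disc}"] = res.bayesian_p

ar_design = DesignSpec(design.terms + [Term(((HARVEST_TERM, 0),))])
ar_data = ar.AgeRatioData.from_tables(surveys, harvest, cov, ar_design)
ar_draws = ar.fit(ar_data, MCMCConfig.reduced(chains=4, kept=2500, burnin=600),
                  seed=args.seed + 2)
gof["ageratio_ssq"] = dg.posterior_predictive_check(
    ar_draws, ar_data, "ssq", rng).bayesian_p

args.out.parent.mkdir(parents=True, exist_ok=True)
with open(args.out, "w") as fh:
    json.dump(gof, fh, indent=1, sort_keys=True)
for name, p in gof.items():
    print(f"Bayesian p ({name}): {p:.3f}")
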