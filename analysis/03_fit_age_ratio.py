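"""Fit the age-ratio comparator model to the working study.

The traditional analysis: a Gaussian linear model of the observed
calves:100-adult-females ratios with year random effects, shrinkage over
the covariate coefficients and a standardized adult-female harvest term.
Writes the posterior summary under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from elkipm import ageratio as ar
from elkipm.data import (
    DesignSpec,
    HARVEST_TERM,
    Term,
    read_covariate_table,
    read_harvest_table,
    read_survey_table,
)
from elkipm.draws import MCMCConfig, summarize_samples
from elkipm.simulate import default_scenario_design

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/study"))
parser.add_argument("--seed", type=int, default=3)
parser.add_argument("--full", action="store_true")
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

surveys = read_survey_table(args.study / "surveys.csv")
harvest = read_harvest_table(args.study / "harvest.csv")
cov = read_covariate_table(args.study / "covariates.csv")
design = DesignSpec(default_scenario_design().terms + [Term(((HARVEST_TERM, 0),))])
data = ar.AgeRatioData.from_tables(surveys, harvest, cov, design)
print(f"{data.n_rows} classification-complete district-years, "
      f"{data.n_terms} regression terms")

mcmc = MCMCConfig.ageratio_default() if args.full else \
    MCMCConfig.reduced(chains=4, kept=4000, burnin=1000)
draws = ar.fit(data, mcmc, seed=args.seed)

rows = [{"quantity": q, **summarize_samples(draws.stacked(q))}
        for q in ("alpha", "sigma_ageratio", "sigma_zeta", "sigma_beta")]
beta = draws.stacked("beta")
for j, name in enumerate(draws.coords["beta"]):
    rows.append({"quantity": f"beta[{name}]", **summarize_samples(beta[:, j])})
summary = pd.DataFrame(rows)
args.out.mkdir(parents=True, exist_ok=True)
summary.to_csv(args.out / "ageratio_summary.csv", index=False)
print(summary.to_string(index=False, float_format=lambda v: f"{v: .3f}"))
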