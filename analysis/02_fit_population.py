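"""Fit the state-space population model to the working study.

Reads the CSVs written by 01_simulate_study.py, runs the
Metropolis-within-Gibbs sampler (reduced protocol by default; pass
--full for the 100k-iteration production protocol), and writes posterior
summaries, a convergence report, the derived annual growth rates and the
mild/average/severe-winter recruitment predictions under results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from elkipm import population as pm
from elkipm.data import read_covariate_table, read_harvest_table, read_survey_table
from elkipm.diagnostics import convergence_report
from elkipm.draws import MCMCConfig, hpd_interval, summarize_samples
from elkipm.simulate import default_scenario_design

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/study"))
parser.add_argument("--seed", type=int, default=2)
parser.add_argument("--full", action="store_true",
                    help="production-length protocol (slow) instead of the reduced one")
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

surveys = read_survey_table(args.study / "surveys.csv")
harvest = read_harvest_table(args.study / "harvest.csv")
cov = read_covariate_table(args.study / "covariates.csv")
design = default_scenario_design()
data = pm.PopulationData.from_tables(surveys, harvest, cov, design)

mcmc = MCMCConfig.population_default() if args.full else \
    MCMCConfig.reduced(chains=4, kept=4000, burnin=1500)
print(f"fitting: {data.n_districts} districts x {data.n_years} years, "
      f"{mcmc.chains} chains x {mcmc.kept_per_chain} kept")
draws = pm.fit(data, mcmc, seed=args.seed)

args.out.mkdir(parents=True, exist_ok=True)
scalars = ["alpha", "phi_a", "sigma_zeta", "sigma_beta", "sigma_count"]
rows = [{"quantity": q, **summarize_samples(draws.stacked(q))} for q in scalars]
beta = draws.stacked("beta")
for j, name in enumerate(draws.coords["beta"]):
    rows.append({"quantity": f"beta[{name}]", **summarize_samples(beta[:, j])})
tau0 = pm.predict_recruitment(draws, np.zeros(data.n_terms))
rows.append({"quantity": "mean_recruitment", **summarize_samples(tau0)})
summary = pd.DataFrame(rows)
summary.to_csv(args.out / "population_summary.csv", index=False)
print(summary.to_string(index=False, float_format=lambda v: f"{v: .3f}"))

report = convergence_report(draws)
report.to_csv(args.out / "population_convergence.csv", index=False)
print(f"max split R-hat {report['rhat'].max():.3f}, "
      f"min ESS {report['ess'].min():.0f}")

lam, lam_table = pm.derive_lambda(draws, data)
lam_table.to_csv(args.out / "population_lambda.csv", index=False)
print("annual growth rate (region): median range "
      f"[{lam_table['median'].min():.3f}, {lam_table['median'].max():.3f}]")

# winter-severity contrast at the 5th/95th percentiles of standardized SWE
swe_col = design.names.index("swe")
swe_vals = data.X[:, 1:, swe_col].ravel()
profiles = {"mild_winter": np.percentile(swe_vals, 5),
            "average_winter": 0.0,
            "severe_winter": np.percentile(swe_vals, 95)}
rows = []
for label, swe in profiles.items():
    x = np.zeros(data.n_terms)
    x[swe_col] = swe
    rows.append({"profile": label, "swe": swe,
                 **summarize_samples(pm.predict_recruitment(draws, x))})
winter = pd.DataFrame(rows)
winter.to_csv(args.out / "population_winter_contrast.csv", index=False)
print(winter.to_string(index=False, float_format=lambda v: f"{v: .3f}"))
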