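"""Head-to-head power contrast: population model vs age-ratio regression.

Simulates replicate studies with a true logit-scale spring-precipitation
effect of -0.2 on recruitment, fits both models to every study, and reports
how often each model's 90% HPD interval for the coefficient excludes zero.
The population model separates observation error from process variance and
links counts across years through the demographic model, so it detects the
effect far more often than the regression on noisy derived ratios.
Writes results/power.json.
"""

import argparse
from pathlib import Path

from elkipm import simulate
from elkipm.draws import MCMCConfig
from elkipm.experiments import power_experiment

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=5)
parser.add_argument("--reps", type=int, default=10)
parser.add_argument("--out", type=Path, default=Path("results/power.json"))
args = parser.parse_args()

scenario = simulate.make_scenario(seed=args.seed, n_districts=10,
                                  first_year=2004, last_year=2013)
report = power_experiment(
    scenario, n_replicates=args.reps,
    mcmc_population=MCMCConfig.reduced(chains=4, kept=1500, burnin=800),
    mcmc_ageratio=MCMCConfig.reduced(chains=4, kept=1500, burnin=400),
    seed=args.seed,
)
args.out.parent.mkdir(parents=True, exist_ok=True)
report.to_json(args.out)

print(f"{report.n_replicates} replicates ({report.n_excluded} excluded by the "
      "convergence gate)")
print(f"{'coefficient':16s} {'true':>6s} {'population':>11s} {'age ratio':>10s}")
for name in report.coefficients:
    print(f"{name:16s} {report.true_beta[name]:6.2f} "
          f"{report.detection_population[name]:11.2f} "
          f"{report.detection_ageratio[name]:10.2f}")
d = report.difference("spring_precip")
lo, hi = report.difference_interval("spring_precip")
print(f"detection difference for spring_precip: {d:+.2f} (approx CI [{lo:+.2f}, {hi:+.2f}])")
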