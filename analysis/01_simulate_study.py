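"""Generate the working synthetic study.

Emulates the monitoring design the models were built for: 17 hunting
districts followed over 2004-2016 with discontinuous aerial spring surveys
(6-13 observed years per district, median 7; 140 observed district-years,
135 with an age/sex classification), continuous fall harvest series, and
standardized environmental/predator covariates screened at |r| <= 0.50.
Writes surveys.csv, harvest.csv, covariates.csv and truth.json under
results/study/.
"""

import argparse
from pathlib import Path

import numpy as np

from elkipm import simulate
from elkipm.data import observed_age_ratio

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/study"))
args = parser.parse_args()

cfg = simulate.make_scenario(seed=args.seed)
surveys, harvest, cov, truth = simulate.make_study(cfg, args.out, overwrite=True)

ratios = [observed_age_ratio(s) for s in surveys if s.has_classification]
counts = [s.total_count for s in surveys]
print(f"wrote study to {args.out}")
print(f"  {len(surveys)} observed district-years, "
      f"{sum(s.has_classification for s in surveys)} classified")
print(f"  counts: min {min(counts)}, max {max(counts)}")
print(f"  observed age ratios: mean {np.mean(ratios):.1f}, sd {np.std(ratios):.1f}, "
      f"range [{min(ratios):.1f}, {max(ratios):.1f}]")
print(f"  true mean recruitment {1/(1+np.exp(-truth['parameters']['alpha'])):.3f}, "
      f"adult survival {truth['parameters']['phi_a']}")
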