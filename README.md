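# elkipm

Bayesian state-space population modelling for harvested elk herds, built
around the data wildlife agencies already collect: spring aerial counts, a
partial age/sex classification of the counted animals, and estimated fall
harvest. The package estimates per capita recruitment (calves per adult
female surviving to the spring survey), apparent adult survival and annual
growth rates, links recruitment to environmental and predator covariates,
and quantifies — by simulation — how much statistical power this approach
gains over the traditional regression on observed calves:100-females age
ratios.

## The model

Latent abundances of calves, adult females and adult males per hunting
district `u` and year `t` evolve with Poisson demographic stochasticity,
harvest `h` removed immediately after the previous survey:

    N^c_t  ~ Poisson( τ_{t,u} N^af_{t−1} − h^c_t )
    N^af_t ~ Poisson( φ_a (δ N^c_{t−1} + N^af_{t−1} − h^af_t) )
    N^am_t ~ Poisson( φ_a ((1−δ) N^c_{t−1} + N^am_{t−1} − h^am_t) )

    logit(τ_{t,u}) = α + ζ_t + x_{t,u}'β,   ζ_t ~ N(0, σ²_ζ),
    β_j ~ N(0, σ²_β)  (common shrinkage prior)

Counts and classifications are modelled separately from the biology:

    Count_t,u ~ Poisson( N^total exp(γ_{t,u}) ),  γ ~ N(0, σ²_count)
    [y^c, y^af, y^am] ~ Multinomial( N-class shares, Classified_t,u )

so process variance and observation error are not conflated, surveys may be
missing in any year, and classification may be missing while a count exists.
The comparator is the traditional Gaussian linear model of the observed
ratios, `ratio ~ N(α + ζ_t + x'β + β_harv h^af, σ²)`.

Posterior sampling is a vectorised Metropolis-within-Gibbs scheme written
in-package (integer random walks over the latent states on an even/odd-year
checkerboard, adaptive scalar updates, an exact Gibbs recentering move along
the α/ζ ridge); see `docs/methods.md` for the full account.

The agency data behind the motivating analysis are not public, so the
package ships a first-class synthetic-study generator
(`elkipm.simulate`) that reproduces the design: 17 districts × 2004–2016,
140 observed district-years (135 classified), continuous harvest,
covariates screened at |r| ≤ 0.50. Everything below runs on such studies
with known truth.

## Worked example

```
python analysis/01_simulate_study.py --seed 1      # writes results/study/
python analysis/02_fit_population.py               # state-space fit
python analysis/03_fit_age_ratio.py                # comparator fit
python analysis/04_goodness_of_fit.py              # Bayesian p-values
python analysis/05_power_contrast.py --reps 10     # head-to-head power
```

`01` prints the study summary (seed 1):

```
  140 observed district-years, 135 classified
  counts: min 212, max 1284
  observed age ratios: mean 26.3, sd 14.5, range [4.4, 74.9]
  true mean recruitment 0.250, adult survival 0.85
```

`02` fits the population model (4 chains × 4,000 kept at the default
reduced protocol; `--full` runs 4 × 100,000/20,000/5 = 64,000 kept) and
prints, among others:

```
           quantity  median  hpd50_low  hpd50_high  hpd90_low  hpd90_high
              alpha  -1.092     -1.218      -0.965     -1.431      -0.763
              phi_a   0.854      0.850       0.856      0.846       0.861
beta[spring_precip]  -0.165     -0.186      -0.146     -0.213      -0.118
   mean_recruitment   0.251      0.225       0.272      0.192       0.317
max split R-hat 1.037, min ESS 128
annual growth rate (region): median range [0.878, 1.087]
```

Read: with all covariates at their average (zero, standardized), the herd
produces about 0.25 calves per adult female by the next spring — the
posterior median recovers the generating value logit(0.25) ≈ −1.099 —
adult survival after harvest is ~0.85 (truth 0.85), a one-sd wetter spring
lowers recruitment on the logit scale by ~0.17 (truth −0.2), and the
region's annual growth rate λ ranges from mild decline to mild growth
across years under the simulated harvest pressure.

`04` prints the three goodness-of-fit p-values (≈0.5 means replicated data
resemble the observed data; here 0.49 / 0.36 / 0.50). `05` prints the
detection contrast:

```
coefficient        true  population  age ratio
spring_precip     -0.20        1.00       0.90
summer_precip      0.08        0.70       0.20
```

— the population model's 90% HPD excludes zero more often than the
age-ratio regression for both real effects on the very same studies, the
gap widest for the weaker effect the ratio regression almost never finds.

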