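# Methods

## The scientific problem

Wildlife agencies monitor harvested elk herds with spring aerial counts, a
partial age/sex classification of the counted animals, and fall harvest
estimates. The traditional summary — the observed calves per 100 adult
females — conflates two age classes, mixes process variance with observation
error, and has little power to reveal what drives recruitment. This package
implements the alternative: a Bayesian state-space population model that
treats the latent class abundances as a demographic time series and models
the survey process separately, together with the traditional age-ratio
regression as a comparator, and the simulation machinery needed to evaluate
both.

Because the original agency survey and harvest tables are not publicly
deposited, every analysis here runs on synthetic studies generated from the
model's own equations at the design scale of the motivating data set
(17 hunting districts, 2004–2016, 140 observed district-years of counts of
which 135 carry a classification). All conclusions the test-suite and the
acceptance script draw are therefore statements about the *method* —
correctness of the densities, calibration of the inference, relative power
of the two analyses — not reproductions of the original real-data estimates.

## Population model

Latent classes per district `u` and year `t`: calves `N^c` (~10 months old at
the spring survey), adult females `N^af`, adult males `N^am`. Harvest
`h^c, h^af, h^am` is data, treated as removed immediately after the previous
spring survey. Demographic stochasticity is Poisson:

    N^c_t  ~ Poisson( tau_t,u * N^af_{t-1} - h^c_t )
    N^af_t ~ Poisson( phi_a ( delta N^c_{t-1} + N^af_{t-1} - h^af_t ) )
    N^am_t ~ Poisson( phi_a ((1-delta) N^c_{t-1} + N^am_{t-1} - h^am_t ) )

with apparent adult survival `phi_a` shared by both adult classes, calf
female fraction `delta = 0.5` (fixed), and per capita recruitment on the
logit scale

    logit(tau_t,u) = alpha + zeta_t + x_t,u' beta,

where `x` are standardized covariates, `zeta_t ~ N(0, sigma_zeta^2)` are
year random effects shared across districts (so herds differ only through
their covariate values), and all regression coefficients share the
hierarchical shrinkage prior `beta_j ~ N(0, sigma_beta^2)`.

Poisson means are floored at `eps = 1e-3`: the calf subtraction can go
non-positive for large calf harvest, and the floor keeps the density proper.
The simulator treats a *configured* harvest rate whose expected trajectory
hits a non-positive mean as an error instead, naming the district-year —
a scenario whose expected herd collapses is a configuration mistake, not a
tail event to be papered over.

Observation layer, for surveyed district-years only:

    Count_t,u ~ Poisson( N^total_t,u * exp(gamma_t,u) ),
    gamma_t,u ~ N(0, sigma_count^2)
    [y^c, y^af, y^am]_t,u ~ Multinomial( pi_t,u , Classified_t,u ),
    pi = class shares of N^total

The exp() in the count mean is deliberate: a literal Normal multiplier on a
Poisson rate would permit negative rates, so the observation-level random
effect enters log-normally (median multiplier 1). Classification-missing
years keep the count terms and drop only the multinomial term; unsurveyed
years contribute no observation terms at all while the latent dynamics
propagate through them.

Priors: `phi_a ~ Beta(1,1)`; `alpha ~ N(0,1)` on the logit scale; initial
abundances per class discrete-uniform on `[h_next, 10000]` (left-truncated
at the class harvest subtracted in the next transition); `sigma_zeta,
sigma_beta, sigma_count ~ Uniform(0, 10)` on the standard-deviation scale
(the standard-deviation reading is the numerically stable one and is
configurable in `PriorConfig`).

## Sampling

No probabilistic-programming backend is used; the sampler
(`elkipm.sampler`) is a vectorised Metropolis-within-Gibbs scheme with all
chains advanced simultaneously as an array axis:

* **Latent states.** Integer random walks with symmetric geometric step
  sizes (sign uniform), one class at a time over an even/odd-year
  checkerboard. No transition or observation term links two states of the
  same class two years apart, so each checkerboard batch is a set of
  conditionally independent single-site updates and vectorises exactly.
  Acceptance deltas touch only the local terms: the state's own Poisson
  term, the following year's means it feeds, and the count/multinomial terms
  of its site.
* **Parameters.** Adaptive Gaussian random walks for `alpha`, each `beta_j`,
  `phi_a`, the observation effects `gamma` (all sites at once) and the three
  sds; the year effects update jointly as a vector of conditionally
  independent sites. Proposal scales adapt toward 0.44 acceptance during
  burn-in only (Robbins–Monro on the log scale, frozen afterwards so the
  kept chain is a valid Markov chain).
* **Ridge recentering.** Only `alpha + zeta_t` is likelihood-identified, so
  a dedicated exact Gibbs move samples a shift `eps` along the ridge
  (`alpha += eps`, `zeta -= eps`; the likelihood is invariant and the
  conditional of `eps` under the two Gaussian priors is itself Gaussian).
  Without this move `alpha` mixes an order of magnitude more slowly.
* **Continuous relaxation.** `backend="relaxed"` keeps the identical
  densities but treats the latent states as positive reals (the Poisson
  pmf evaluated at real arguments via `xlogy(y, mu) - mu - lgamma(y+1)`)
  with Gaussian proposals. It exists as an internal cross-check on the
  integer backend and for samplers that need a continuous state space.
* **No-data fast path.** With zero observed surveys the joint factorises as
  prior × process, and `fit()` samples it *exactly* by ancestral simulation
  (parameters from their priors, latents forward through the process).
  This is what the prior-recovery check exercises.

Initial states: latent totals from the observed counts (log-linear
interpolation through unsurveyed years), split by average observed class
shares, jittered per chain; parameters from dispersed plausible ranges
(`phi_a ~ U(0.5, 0.95)`, `alpha` uniform between logit(0.1) and logit(0.5)),
retried until the joint density is finite.

The production protocol is 4 chains × 100,000 iterations, 20,000 burn-in,
thin 5 (16,000 kept per chain, 64,000 total); the test-suite and the
acceptance script run the same machinery at 4 chains × a few thousand kept,
which the convergence report (split R-hat < ~1.02 on the hyperparameters,
ESS in the hundreds-to-thousands) shows is adequate at these problem sizes.
Split R-hat is implemented in-package and cross-checked against arviz
(`method="split"`) to 1e-6; ESS is delegated to arviz.

## Age-ratio comparator

`ratio_t,u ~ N(mu, sigma_ageratio^2)` with
`mu = alpha + zeta_t + x'beta + beta_harvest * h^af` (identity link;
negative predictions are possible and intentional — this is the traditional
model, warts included). The adult-female harvest covariate is standardized
like every other covariate, and `beta_harvest` shares the common shrinkage
prior. The intercept gets a diffuse `N(0, 100)` (variance 100). The
residual sd gets `Uniform(0, 20)` — wider than the other sd priors because
the ratio scale admits much larger residual spread. Sampling is Gibbs
(conjugate multivariate-normal block for the coefficients, conjugate
normals for the year effects, random-walk Metropolis for the sds) at
4 chains × 20,000 iterations, 5,000 burn-in (60,000 kept) in the production
protocol. District-years without a usable classification are dropped with a
logged count — the structural disadvantage of this model relative to the
state-space approach, which keeps them.

One caveat the default scenario exposes: a logit-scale year effect of
sd 0.6 maps to roughly `100·τ(1−τ)·0.6 ≈ 12` points on the calves:100
scale, beyond the Uniform(0, 10) bound the year-effect sd prior shares
across models, so the ratio model's `sigma_zeta` posterior piles up at the
boundary and the unabsorbed year variance spills into the residual. The
bound is configurable (`AgeRatioPriors.sigma_zeta_bound`); the default is
kept as prescribed, and the truncation is itself illustrative of how
awkwardly the fixed-prior ratio analysis sits on its own scale.

## Covariate pipeline

* **NDVI smoothing.** Centered running mean (default window 3 composites —
  minimal smoothing for 8-day composites; configurable) followed by an
  iterative upper-envelope correction that lifts *dips* (points below the
  chord of their neighbours and below both neighbours) onto the chord,
  iterated to convergence (max change < 1e-9 or 100 passes). Errant NDVI
  values are assumed biased low, so values are never lowered; a converged
  envelope pass is a fixed point (idempotent). Lifting every sub-chord
  point instead would converge to the concave majorant and distort clean
  convex segments, which is why the dip condition is part of the rule.
* **Growing season.** Threshold phenology inside a March–October window
  (days 60–304): the season starts at the first observation at or above 50%
  of the window's maximum and ends when the series next falls to 50%
  (clamped to the window edge if it never does).
* **Time-integrated NDVI.** Cumulative sum of differences from the value at
  season start, split into spring (start through June 30, day 181) and
  summer (after the split through season end); composite values are summed
  directly rather than integrated against days. The two components add
  exactly to the whole-season sum for any split.
* **Precipitation windows.** Pixel-level sums over May 1–Jun 30 (neonatal
  period) and Jul 1–Sep 30 (juvenile independence), then district means
  over the summer range.
* **Winter severity.** Cumulative daily snow-water-equivalent over
  Dec 1–Apr 30 (leap-year aware; the window length is validated and gaps
  are an error listing the missing days), reported in m·days to match the
  scale the covariate summaries are quoted in.
* **Standardization** uses the sample sd (n−1); interactions are products
  of the *standardized* parents; the collinearity screen flags any pair
  with |Pearson r| > 0.50 over complete rows.

The shipped 20-term recruitment design (and the 21-term age-ratio design,
which appends the adult-female harvest term) is a reconstruction: the
original full term list lives in an unavailable supplement, so the default
contains every term the results discuss explicitly, padded to the stated 20
columns, and is config-driven (YAML term lists: `name`, `name:lag1`,
`a*b`).

## Synthetic studies

`elkipm.simulate` generates complete studies from the model's own equations
so inference is testable against known truth. Defaults mirror the
motivating study design and its printed summaries:

* 17 districts × 2004–2016; per-district observed-year counts
  [13,13,12,10,9,8,8,7×7,6×3] (median 7, min 6, max 13; 140 observed
  district-years), with 5 district-years stripped of classification;
* `alpha = logit(0.25)`, `phi_a = 0.85`, `sigma_zeta = 0.6`
  (matching the reported among-year variance 0.37), `delta = 0.5`;
  scenario design of 5 main-effect terms with
  `beta_springPrecip = −0.2` and `beta_summerPrecip = +0.08` (the two
  coefficients the population-model results quote) and three null terms;
* `sigma_count = 0.1`: the reported count-dispersion parameter's scale is
  indeterminate in the source (variance vs precision vs sd), so the
  generator uses a 10% log-scale observation sd — enough overdispersion to
  matter at counts of a few hundred to a few thousand without drowning the
  demographic signal;
* harvest is Binomial on the previous year's class abundance (so it can
  never exceed the class), with per-district-year rates drawn uniformly
  from calves 0–3%, adult females 1–5%, adult males 10–25% — the males
  heavily hunted, antlerless harvest modest, consistent with general-season
  elk management;
* initial abundances calves U{60..150}, adult females U{250..700}, adult
  males U{80..250}, giving district totals in the few-hundreds-to-thousands
  range of the real counts;
* the classified fraction of each count is U(0.6, 0.95) (the source states
  only that classification was a sample of the count);
* `center_year_effects` (off by default) conditions the drawn year effects
  on a zero realized mean. A single study identifies only
  `alpha + mean(zeta_realized)`, so an uncentered realization shifts the
  study's true mean-recruitment level off the configured `alpha` by a
  `N(0, sigma_zeta/sqrt(T-1))` nuisance (~0.17 on the logit scale at 12
  transition years). Recovery experiments turn the flag on so the level
  being recovered is exactly the configured truth — the same conditioning
  that in-sample standardization already applies to the covariates'
  realized moments;
* raw covariates are Gaussian with among-year, among-district and residual
  components (equal year/district weights, slightly larger residual), on
  raw scales matching the published covariate summaries (e.g. spring
  precipitation 0.17 ± 0.05 m, SWE 8.15 ± 6.3 m·days, lion harvest
  4.12 ± 3.76), predator counts rounded and truncated at zero; the
  generated table must pass the 0.50 collinearity screen (bounded redraws,
  then error).

What the generator does **not** emulate: sightability bias (counts are
unbiased around the latent total up to the log-normal effect),
mis-classification between classes, density dependence, age-structured
adult survival, movement between districts, and spatial covariate fields
(covariates are generated at the district level, not through the pixel
pipeline). Passing tests therefore demonstrate correctness and calibration
of the inference under the model's own assumptions — not robustness to
their violation.

## Goodness of fit and the power experiment

Posterior-predictive checks replicate the observation layer once per kept
draw: total counts from `Poisson(N_total e^gamma)` (with `gamma` freshly
drawn per replicate by default — a new-survey prediction; reusing the
fitted `gamma` is available by flag and makes the count check nearly
tautological), classified calves from the binomial margin of the
multinomial with the observed classified totals. Discrepancies: the
Freeman–Tukey statistic `sum (sqrt(y) − sqrt(E))^2` for counts (the source
prints the sum-of-squares formula twice but names Freeman–Tukey; the
standard form is implemented), the sample variance of classified calf
counts for the recruitment signal, and the omnibus sum of squared
residuals for the Gaussian comparator. One-sided Bayesian p-values count
ties as 1/2, which pins exactly degenerate checks at 0.5 and makes the
p-value invariant to monotone rescaling of the discrepancy. Expected
values are conditional on the latent states. The misfit-injection check
corrupts the *data* (doubling classified calf counts) and evaluates it
against the fitted model's predictive distribution — the question the
check answers is whether the p-value flags data the fitted model could not
have produced.

The power experiment simulates replicate studies (population-model truth),
fits both models to each, and records how often each model's 90% HPD
excludes zero per coefficient. Replicates failing a split-R-hat gate
(default 1.2 on `alpha`/`phi_a`) are flagged, excluded and counted.
Detection under the null sits below the nominal 10% for both models —
the hierarchical shrinkage priors are deliberately conservative.

## Numerical conventions

* HPD interval: shortest contiguous window over the sorted draws containing
  `ceil(mass·n)` of them; ties broken toward the lowest start. Summaries
  report the median with 50% and 90% HPDs.
* `xlogy` conventions give `0·log 0 = 0` throughout, so empty classes with
  zero observed counts contribute nothing, while a positive count against a
  zero latent class is −inf.
* All randomness flows through `numpy.random.Generator`; study generation,
  fits and experiments are reproducible from (config, seed), and a study
  written twice with the same seed is byte-identical.
* Problem sizes in the test-suite and acceptance script (reduced chain
  lengths, 6–10-district studies for the replicated experiments) were
  chosen as the smallest sizes at which the convergence report is clean and
  the Monte-Carlo error of the checked fractions is well inside the asserted
  margins; the production protocol is available behind `--full` flags.

## Known limitations

* Per capita recruitment is a compound of pregnancy, in-utero and calf
  survival and is not separately identifiable; `alpha` is only identified
  jointly with the realized mean of the year effects, so its posterior in
  any one study is centred on `alpha + mean(zeta_realized)` (the recovery
  suite measures coverage across replicate studies, where this is part of
  the nominal uncertainty).
* The integer-state sampler is exact but random-walk based; very large
  studies would want the relaxed backend with gradient-based updates.
* The age-ratio model inherits the pathologies it is meant to illustrate
  (unbounded Gaussian ratios, no observation model); that is the point of
  the comparison, not an oversight.
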