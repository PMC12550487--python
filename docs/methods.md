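# Methods

## Process model

A predator's gut content is observed through a binary molecular test.
Two latent processes determine the outcome.

**Digestion.** The probability that a meal eaten *t* hours ago is
still detectable decays logistically, `logit π(t) = β₀ − β₁ t` with
`β₁ > 0`. `expit(β₀)` is the detection probability immediately after
the meal; `β₀/β₁` is the half-life of the signal. Predator voracity
(meal size) is not explicit — it is absorbed into the pair's digestion
curve.

**Predation.** Meals arrive as a homogeneous Poisson process with
intensity λ per hour (the steady-state assumption: λ and the digestion
curve are constant in time). Thinning each past meal by its current
detectability leaves a Poisson number of detectable meals with mean
λ·I, where the detectability window is

    I = ∫₀^∞ π(t) dt = ln(1 + e^{β₀}) / β₁   [hours].

The closed form is validated against adaptive quadrature to 1e-8
relative error in the test suite; it is computed via `logaddexp` so
|β₀| up to hundreds cannot overflow.

**Observation.** Feeding-trial tests are Bernoulli(π(d)) at known
delay d. A field test is positive as soon as one past meal is
detectable: Bernoulli(1 − e^{−λI}). Multi-prey outcomes of one field
individual are treated as independent across prey — the model fits one
λ per pair and no cross-prey dependence is specified. The assay is
assumed perfect (no false positives/negatives beyond digestion).

Time is handled in hours internally (feeding-trial delays are recorded
in hours); every reported rate is daily, 24·λ, to match how field
ecologists discuss predation pressure.

## Effect decomposition and priors

    β₀(p,c)   = α(p) + δ(c) + γ(p,c)
    ln λ(p,c) = α'(p) + δ'(c) + γ'(p,c)
    ln β₁(p,c) ~ Normal(μ_b1, σ_b1)      (one log-normal family for slopes)

Predator effects (δ, δ'), interaction effects (γ, γ') and log-slopes
are hierarchized: each family is Normal with a group-level location
and scale, so information flows from data-rich species to rare ones.
Prey effects are few and heterogeneous, so they carry fixed priors.

Default hyperpriors (all overridable through the config file):

| quantity                      | prior          | rationale |
|-------------------------------|----------------|-----------|
| prey effects α, α'            | Normal(0, 2)   | weakly informative on logit/log scales |
| family locations μ            | Normal(0, 1)   | group-level effects near zero a priori |
| family scales σ               | HalfNormal(1)  | order-unity spread, shrinks when data allow |
| interaction locations         | fixed at 0     | identifiability: a free interaction mean is exchangeable with the main effects |

The interaction-location pinning is structural (not configurable); all
remaining redundancy between α, δ and γ is only softly identified
through the priors, which is intentional — the identified quantities
are the sums.

## Inference

The posterior is sampled by a self-contained gradient-based sampler
(`molpred.hmc`): multinomial NUTS (trajectory doubling with U-turn
termination), a dense mass matrix estimated over Stan-style expanding
warmup windows, and dual-averaging step-size adaptation (target
acceptance 0.95, tree depth ≤ 6 by default). Hierarchized effects are
sampled as standard-Normal offsets (non-centred), scales on the log
scale with the half-Normal prior's Jacobian.

Two features of this posterior defeat plain HMC and are handled by
composing every NUTS step with exact auxiliary updates
(`PredationModel._gibbs_interweave`):

* **Funnels.** Conditional on the effects, the data carry no
  information about a family's location or scale, so their centred
  full conditionals are available — Normal for locations, a univariate
  density (slice-sampled) for scales. After the draw the offsets are
  recoded so the effects are numerically unchanged. This is the
  interweaving (sufficient-augmentation) strategy; it makes the scale
  parameters mix essentially independently of the funnel geometry.
* **Translation ridges.** The likelihood sees only α+δ+γ, so shifting
  mass between a prey effect and the matching predator/interaction
  effects moves along likelihood-null directions whose conditional
  densities (priors only) are univariate Gaussians; one exact draw per
  direction per iteration removes the slowest ridge modes.

Both extra transitions preserve the posterior exactly (Gibbs moves in
reparameterized coordinate systems); the model's log-density gradient
is analytic and verified against finite differences in the tests.

Three chains, 1000 warmup + 1000 retained draws by default; runs are
bit-reproducible given a seed. Convergence is gated on the classic
Gelman–Rubin statistic < 1.01 for every sampled quantity; the
rank-normalized split R-hat (arviz) is reported alongside as the
stricter modern diagnostic. Posterior summaries use lower-interpolation
quantiles so every reported value is an actual draw. Saturated data
(all field tests positive) trigger a warning: the rate is then
prior-driven, and a quantitative assay would be needed instead.

Likelihood evaluation aggregates both tables to sufficient statistics
(lab: counts per pair × delay; field: counts per pair), so cost is
independent of the number of individuals. The log-density gradient is
evaluated by a numba-compiled kernel (a few microseconds per call);
a pure-numpy reference implementation computes the same quantities and
the two are asserted equal in the tests.

## Synthetic data generator

`simulate_field_tests` is mechanistic, not a draw from the fitted
likelihood: predation events are placed on a look-back window
`W = (|β₀| + 10)/β₁` before capture (beyond it π < 5e-5, so the
truncation error of the improper integral is negligible — doubling W
changes nothing beyond Monte-Carlo noise, which is tested), each event
survives digestion with probability π(elapsed), and the test is
positive iff at least one event survives. With independent events the
positive frequency converges to 1 − e^{−λI}; this oracle equivalence
is the generator's defining test and the cross-check of the model's
closed form.

Aggregated predation (violating the one-item-per-event assumption) is
simulated as a compound Poisson process: clusters arrive at rate λ/k̄
and carry a shifted-geometric number of items (mean k̄ ≥ 1) sharing
the arrival time, keeping the item consumption rate at λ. One knob,
minimal deviation.

`make_study_like_scenario` emulates a field campaign on a large
assemblage: 25 predator species × 5 prey; species sample sizes follow
a rank-abundance power law from 657 down to 1 individual (~1050 field
captures — the long-tailed shape and extremes of a realistic campaign,
slightly below the ~1500 of a full multi-season study); feeding-trial
delays 3–72 h with one test per pair and delay (625 tests); daily
rates log-normal around 0.5 events/day clipped to [0.005, 10]; β₀ ~
Normal(1.5, 1) and log β₁ ~ Normal(ln 0.08, 0.6), giving digestion
half-lives from under 10 h to beyond 72 h. The
`detectability_hours` option instead pins each prey's detectability
window I in a given range (used to study digestibility effects in
isolation). What the generator does *not* emulate: seasonal or
temperature variation of rates, trap-timing effects, assay error, or
cross-prey dependence within an individual — passing tests show the
estimator is correct under its own assumptions plus moderate event
aggregation, not that real field data satisfy them.

## Validation suite (scenario sizes)

Everything below runs from `molpred.validation` (used by both
`tests/test_acceptance.py` and `scripts/acceptance.py`), sized for a
single CPU core:

* **Quadrature check** — 21×21 grid, β₀ ∈ [−5, 5], β₁ ∈ [0.01, 5];
  closed-form I vs `scipy.integrate.quad`, tolerance 1e-8 relative.
* **Simulator oracle** — 10 random parameter sets, 20 000 individuals
  each; empirical frequency within 3 Monte-Carlo SEs of 1 − e^{−λI}.
* **Recovery suite** — 20 replicates of a 4-predator × 2-prey
  community, true daily rates log-uniform in [0.2, 3], β₀ ~ N(2, 0.5),
  β₁ log-normal(ln 0.1, 0.3); 300 field captures per predator, 30
  lab tests per pair over delays {2, 8, 16, 24, 48, 72} h; 3 chains ×
  (1500 warmup + 4000 draws — the convergence gate is a worst case
  over ~3200 parameter instances and needs the effective-sample
  margin). Measured: pooled median absolute relative
  error of posterior-median daily rates, central-90%-interval
  coverage, worst Gelman–Rubin.
* **Hierarchy transfer** — same community plus a fifth predator
  present only in the feeding trial (0 field rows); its daily-rate
  posterior must be proper and wider (log-scale sd) than a 300-capture
  predator's.
* **Underestimation check** — reduced community (10 species × 3 prey,
  ≤ 600 captures per species, 50 lab tests per pair) with
  prey-specific detectability windows
  drawn in (3, 8), (8, 15) and (15, 22) h — all below one day — and
  identical rate draws across prey so the comparison isolates
  digestibility. The abundance-weighted detection frequency must
  undershoot the model indicator for every prey, the more so the
  shorter the window.
* **Aggregation robustness** — one pair, β₀ = 3 (detection ≈ 0.95 at
  t = 0, as observed for abundant well-fed species), β₁ = 0.1, item
  rate 0.06/h, cluster mean 3; 6000 field captures and 600 lab tests
  for precision. Closed-form analysis gives the large-sample recovered
  consumption ratio (λ̂·k̄ / λ_true) as the ratio of cluster to
  single-item detectability integrals, ≈ 1.35 under these conditions;
  the check requires the measured ratio within a factor 1.5.

## Numerical choices and degenerate inputs

* Bernoulli-logit likelihood in the stable `kη − n·softplus(η)` form;
  field channel via `expm1`/`log1p`; positions with any coordinate
  beyond ±300 are treated as off-support (the sampler sees a
  divergence, never a NaN).
* Quantile convention: lower interpolation, everywhere.
* Predator/prey registries are the union of labels in the two tables;
  species present in only one dataset are retained and informed
  through the hierarchy. Unknown labels in downstream tables (e.g.,
  abundances) are errors, not silently dropped.
* A species with zero field rows for a prey is excluded from the
  posterior-predictive comparison (its frequency is undefined) with a
  logged notice; in the rough indicator it contributes frequency 0.
* Input validation collects *all* row-level problems with 1-based file
  line numbers before raising.

## Known limitations

* Steady-state assumption: rates and digestion constant over the
  capture window; seasonal structure enters only through per-community
  abundances (refit on data subsets to relax).
* The taxonomic-group hierarchy is a single level; trait-based or
  phylogenetic structure would need a different effects module.
* Detection saturation: with (nearly) all field tests positive the
  rate is unidentified and only a prior-driven upper bound is
  returned.
* The indicator is relative predation pressure (rate × activity-
  density); converting to prey killed per unit area needs absolute
  predator densities, which activity-density does not provide.
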