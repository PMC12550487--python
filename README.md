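# molpred

Estimating **daily predation rates** from binary molecular gut-content
data, with full uncertainty propagation to a community-scale biocontrol
indicator.

## The problem

For most inconspicuous predators (ground beetles, spiders, soil fauna),
nobody has ever watched a meal happen in the field.  What we can
measure is a PCR presence/absence call: did this captured predator
carry detectable DNA of prey *p*?  Two confounded processes generate
that bit — how often the predator eats (*predation*) and how fast the
molecular signal fades (*digestion*).  A raw detection frequency
conflates them: a prey digested in six hours can be eaten daily yet
rarely test positive.

`molpred` separates the two by fitting one hierarchical Bayesian model
jointly to:

* a **laboratory feeding trial** — predators fed a known prey and
  tested at delays *d*, calibrating the digestion curve; and
* **field captures** — one binary test per (individual, prey).

## The model

Detectability of a meal decays logistically with time since ingestion,

```
logit π(t) = β₀ − β₁·t,            β₁ > 0
```

and predation is a homogeneous Poisson process with intensity λ
(meals/hour).  Thinning past meals by their current detectability makes
the number of *detectable* meals at capture Poisson with mean λ·I,
where

```
I = ∫₀^∞ π(t) dt = ln(1 + e^{β₀}) / β₁        (hours)
```

is the expected detectability window.  Hence the two observation
models:

```
T_lab(d)  ~ Bernoulli( π(d) )
T_field   ~ Bernoulli( 1 − e^{−λ·I} )
```

Each predator–prey pair (p, c) gets its own parameters through an
additive decomposition, `β₀(p,c) = α(p) + δ(c) + γ(p,c)` and
`ln λ(p,c) = α'(p) + δ'(c) + γ'(p,c)`, with log-normal decay slopes
β₁(p,c).  Predator, interaction and slope effects are drawn from
group-level Normal distributions (hierarchical shrinkage: data-rich
species inform the range of plausible values for rare ones); prey
effects carry fixed weakly-informative priors.  Sampling is by NUTS
(dense metric) composed with interweaved Gibbs updates of the
group-level locations/scales; convergence is gated on the
Gelman–Rubin statistic < 1.01 over three chains.

Rates are reported per day (24·λ).  The community-scale biocontrol
indicator for prey *p* weights each species' daily rate by its
activity-density A_c:

```
λ_com,p = Σ_c λ(p,c) · A_c
```

evaluated over joint posterior draws (100 by default), alongside the
digestion-uncorrected "rough" comparator Σ_c freq(p,c)·A_c.

## Worked example

```python
import numpy as np
import molpred as mp

# a synthetic single-pair study with known truth:
# beta0 = 2, beta1 = 0.1 /h  (detectability window I = 21.3 h)
# lam = 0.05 meals/h  (1.2 meals/day)
scn = mp.SimulationScenario(
    prey=("springtail",), predators=("PoCu",),
    beta0=np.array([[2.0]]), beta1=np.array([[0.1]]),
    lam=np.array([[0.05]]), field_n=np.array([500]),
    lab_times=(2, 8, 16, 24, 48, 72), lab_n=17, seed=11)
lab = mp.simulate_feeding_trial(scn)
field = mp.simulate_field_tests(scn)

res = mp.PredationModel(lab, field).fit(seed=1)
print(res.daily_rate_summary().round(3))
```

```
                          median   mean     sd  q0.05  q0.25  q0.75  q0.95
predator_code prey
PoCu          springtail   1.214  1.223  0.193  0.932  1.085  1.347  1.547
```

The posterior median daily rate (1.21 meals/day) recovers the true 1.2
within sampling noise, and the 90% interval [0.93, 1.55] covers it —
even though only 66% of the field tests were positive.  The rough
frequency-based estimate would report 0.66 "meals/day", a 45%
underestimate, because springtail DNA is detectable for less than a
day.

Further down the pipeline:

```python
res.posterior_predictive_check()      # observed freq vs posterior p(I)
res.summary()                         # rates + digestion + PSRF table
ab = mp.CommunityAbundance("May", {"PoCu": 10.0})
res.biocontrol_indicator(ab, "springtail", n_draws=100, seed=0)
```

A thin CLI mirrors the pipeline: `molpred simulate | fit | diagnose |
indicator`, configured by a YAML file (`molpred init-config cfg.yaml`
writes the template with every hyperprior and sampler default).

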