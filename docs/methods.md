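# Methods

## Model structure

The population of adults aged 20–79 is partitioned into compartments indexed
by sex (2), age band (20 bands of 3 years), risk profile (the 2³ = 8
combinations of obesity, physical inactivity and smoking), T2DM status
(susceptible / diabetic) and intervention-coverage class (uncovered plus one
bit per active scenario, so a run with *K* active scenarios carries 2ᴷ
coverage classes).  The state also carries three flow accumulators:
cumulative T2DM onsets by sex and age band (for annual new-case accounting),
and cumulative demographic entries and exits per sex (so the exact mass
balance `total(t) = total(t₀) + entries − exits` is checkable on any run).

Dynamics are deterministic ODEs:

- **Aging** is a continuous transfer at rate 1/(band width) = 1/3 per year;
  people leaving the last band (age 80) exit the modelled population.  This
  is the standard pure-ODE treatment; it implies exponentially distributed
  band residence times rather than sharp cohort shifts.
- **Entry** at age 20 is an exponentially growing flow `E₀·exp(g·τ)` per sex,
  with the entrant risk profile drawn from the first-year band-1 marginals
  (factors independent) and all entrants susceptible.
- **Mortality** is Gompertz-like in age, `μ(a) = 0.004·exp(0.085·(a−50))`
  per year before calibration scaling, multiplied by `κ = 1.5` for diabetics.
  κ is configurable; 1.5 is a mid-range literature value for all-cause
  excess mortality with diabetes.
- **Risk-factor transitions** move one factor at a time along lattice edges
  with acquisition rates α_f and exit rates ω_f.  Default turnover: obesity
  ω = 0.02/yr (slow remission), inactivity ω = 0.10/yr, smoking ω = 0.03/yr;
  the α_f are set at equilibrium for the first-year prevalence of each
  (sex, band) cell, so the baseline risk-factor surfaces are approximately
  stationary apart from a solved obesity drift `α_ob(t) = α_ob·exp(d·τ)`.
- **T2DM onset** occurs at hazard `λ₀(s,a) · Π_f RR_f · trend(t) · m`, with
  `λ₀ = exp(a_s + b_s x + c_s x²)`, `x = (age − 50)/10`.  Relative risks
  compose multiplicatively across co-occurring factors (defaults 3.6 / 1.3 /
  1.4 for obesity / inactivity / smoking, fixed rather than fitted — effect
  sizes come from the literature, the fit supplies incidence and transition
  rates).  `trend(t) = exp(γτ + γ₂τ²)` is a secular multiplier absorbing
  incidence drivers not modelled explicitly (cohort composition, diagnostics,
  residual risk-factor trends).  There is no remission and no explicit
  pre-diabetes stage.

With the default shape parameters the age-specific hazard peaks near age 52
and is ~3% of its peak at the early twenties, consistent with onset
concentrating at ages 40–55.

## Synthetic baseline generator

The original national calibration data are not publicly deposited.  The
generator therefore constructs an explicit stand-in world — not a
reconstruction — that encodes the published aggregate anchors:

| anchor | value |
|---|---|
| T2DM prevalence, 2021 / 2050 | 17.1% / 29.5% |
| prevalent cases, 2021 / 2050 | 33,821 / 84,516 |
| annual new cases, 2021 / 2050 | 2,145 / 3,931 |
| obesity prevalence, 2030 | 53.3% |
| inactivity / smoking prevalence (held flat) | 46.5% / 20.7% |
| implied cumulative new cases, 2021–2050 | ≈ 81,700 |

Population totals are derived as cases/prevalence (197,784 in 2021; 286,495
in 2050).  The cumulative-incidence anchor is implied by the published
averted-case pairs (18,619/22.8% and 38,379/46.9%).

First-year marginals use a Gaussian-in-age population density (mode 30, SD
16 years — a young, national-population-style pyramid), a logistic-in-age
T2DM prevalence (midpoint 50, scale 8 years, scaled to the aggregate
anchor), a mild obesity age gradient, flat inactivity and smoking, and a
50/50 sex split (no sex-specific anchors are in scope; both sexes share one
parameterisation, which the calibration is free to split).

The generator then solves six scalar knobs — hazard scale, γ, γ₂, a
mortality scale, an entry scale and the obesity drift — by a root solve on
full model simulations so the truth trajectory hits the six solved anchors
(first-year prevalence and cases are exact by construction of the initial
state).  Calibration targets are tabulated from this truth simulation, which
makes them dynamically consistent with the model family: the least-squares
fit can in principle recover the truth exactly.  That is deliberate — the
pipeline check is of the machinery, not of the original data.  Two
consequences are documented rather than "fixed": the aggregate population
path is smooth and monotone between its two anchored totals but its growth
rate decelerates (1.8%→0.7%/yr) instead of being exactly exponential, and a
degenerate all-flat-anchor configuration yields a trajectory flat to within
about 0.6 pp rather than perfectly constant (no exact steady state exists
for the chosen initial age profile).

What the generator does *not* emulate: survey noise, sex differences,
migration, cohort effects, or any real age-specific incidence data.  Tests
passing against this world show the pipeline is correct and internally
consistent, not that its projections match the original country data.

## Calibration

Bounded trust-region least squares (`scipy.optimize.least_squares`, TRF) on
weighted residuals over five families — T2DM, obesity, inactivity and
smoking prevalence (weighted ×100, i.e. percentage points) and population
counts (relative error ×100, i.e. percent) — across all sex × band × year
cells (6,000 residuals).  Default free parameters (11): the six log-quadratic
hazard coefficients, γ, γ₂, log mortality and entry scales, and the obesity
drift.  Free parameters are transforms of the caller's initial parameter
set, so scale parameters are expressed as log multipliers.

The analytic initialiser rebuilds equilibrium transition rates and the
demographic balance from the first target year and roughly scales the hazard
to the observed early prevalence growth.  From it, a single start converges
in ~10 iterations on the packaged targets; the least-squares surface proved
well behaved at this scale, so the default is one start, with seeded
multistart (`FitSpec.n_starts`) available for harder target sets.  Inner
simulations use RK45 at rtol 1e-8 with a coarse finite-difference step
(1e-3) so adaptive-solver noise stays out of the Jacobian.  Non-convergence
is reported via a flag, not an exception; failed trial points are penalised.

## Interventions

Scenario specifications mirror the published table: uptake × adherence =
effective coverage, a linear scale-up ramp (2021–2025 for lifestyle
scenarios, 2021–2030 otherwise) then maintenance to 2050, a target filter
(all adults; obese; 50+; obese & 35+; working ages 20–65 → bands 1–15), and
up to three effect channels.

**Coverage** is modelled with explicit covered/uncovered compartments.
Recruitment is a closed-loop tracking rate applied within every eligible
(sex, age band) stratum: feed-forward ramp slope plus a proportional
correction (gain 2/yr) toward the ramp target, divided by the uncovered
fraction.  Per-stratum (rather than aggregate) tracking keeps the covered
fraction at target at every age, preventing covered people who age into
high-risk bands from accumulating above-target coverage there; it also tops
up dilution from people entering eligibility after the ramp, matching the
"maintained thereafter" reading of the scenario table.  Entrants arrive
uncovered; coverage persists when a person's profile changes, but effects
apply only while the compartment matches the scenario filter.

**Incidence effects** multiply the onset hazard of covered, filter-matching
compartments by the scenario IRR/RR; multiple scenarios compose
multiplicatively.

**Obesity endpoints.**  The published mean-BMI reductions are *not*
converted to prevalence: the six printed (ΔBMI, endpoint) pairs are mutually
inconsistent under any single distribution-shift model (see the BMI audit),
so the printed endpoints are taken as authoritative.  Each endpoint is
achieved by an extra annual exit rate out of the obese state among covered
people — `m·w(y)` during the ramp with linear weights `w` — plus matching
acquisition damping `1/(1+rate)`; the scalar `m` is solved by bisection on
full scenario simulations so the prevalence in the stated scope (total
population, or the covered subgroup for the workplace scenario) hits the
target at ramp end within 0.1 pp.  After the ramp the rate is re-solved year
by year, holding prevalence at target through 2050 without overshoot.  In
combination packages, covered-scope targets are solved first, then one
shared multiplier serves all total-scope targets given that forcing (zero if
the covered-scope forcing alone already meets the most stringent total-scope
target); the table is silent on interactions, so this sequential composition
is a package design choice.  An unreachable target raises an error carrying
the closest achievable prevalence.

**Inactivity normalization** (public-transport scenario) moves covered
inactive people to the active state at a rate ramping to 10/yr by end of
scale-up — effectively complete conversion — emulating physical activity
restored to the healthy-population level.

One structural caveat: with equal-fraction coverage, a scenario whose filter
is a superset of another's (all obese vs obese & 35+) averts at least as
many cases by construction, so the published slight advantage of the
obese-&-35+ lifestyle variant cannot be reproduced exactly; in this
implementation the three lifestyle scenarios are comparable within ~15%,
with the all-obese variant marginally ahead.

## Outcomes

`compare` aligns a scenario trajectory with its counterfactual (identical
parameters and initial state) and reports, per year: prevalence with and
without intervention, the absolute percentage-point prevalence reduction,
annual new cases in both arms, cumulative averted cases, and the proportion
averted — cumulative averted divided by cumulative counterfactual new cases
accrued since the 2021 intervention start (this denominator convention is
consistent with the published averted-count/percentage pairs, both implying
≈ 81,700 cumulative baseline cases).  Both absolute (pp) and relative
prevalence reductions appear in summaries, since published phrasing mixes
the two.  A one-at-a-time sensitivity sweep over scenario or natural-history
parameters reports the 2050 outcome set per grid point with a monotonicity
flag; the full multivariate uncertainty analysis of the original model
lineage is out of scope.

## Numerics

Scenario and pipeline simulations use DOP853 with rtol 1e-11 and atol 1e-6
persons, with annual dense output 2021–2051 (the extra year defines the
2050 new-case flow).  At these tolerances a null scenario (multiplier 1, no
targets) is indistinguishable from its counterfactual to better than 1e-8
relative on all outcome series, and the 30-year mass balance closes to
better than 1e-6 relative.  Calibration and forcing-solver inner loops use
RK45 at rtol 1e-8/1e-6 for speed; final evaluations are always re-run tight.
Integrator correctness is cross-checked against an independent fixed-step
explicit-Euler integrator on small instances (agreement within 1e-4).
Negative counts from solver excursions are clipped to zero in snapshots
(never below −1e-9 of the total; larger excursions are logged).  Bisection
tolerances: 0.02 pp on obesity-endpoint achievement, well inside the 0.1 pp
acceptance band.

## Problem sizes

The packaged configuration is a desk-scale world: 1,280 baseline
compartments (×2ᴷ coverage classes in scenario runs), 1,200 target cells ×
5 families in calibration, 30-year horizons.  Baseline generation ≈ 1 s,
calibration ≈ 5 s, a forcing scenario ≈ 10 s, a combination package ≈ 40 s
on one CPU.

## Known limitations

- The synthetic world is a stand-in; absolute intervention impacts (e.g.
  proportions averted) are smaller than the published ones, which were
  computed on the original national calibration.  Qualitative orderings and
  all engine properties are preserved and tested.
- No pre-diabetes compartment, no complications or expenditure modelling,
  no migration, no stochasticity, no sex-specific anchors.
- BMI reductions below the obesity threshold carry no incidence benefit
  (only the obese/non-obese dichotomy enters the hazard), mirroring the
  obesity-endpoint formulation and understating continuous BMI effects.
- Whether published BMI reductions are per-covered-person or
  population-wide is ambiguous in the source material; endpoints are used
  instead, with the stated scope per scenario.
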