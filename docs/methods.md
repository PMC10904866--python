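# Methods

This note documents the model, its parameters and the design decisions that
were genuinely open, in the package's own terms. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Time and the screening cycle

One tick is one week. An invitation ("call") is issued when the simulation
week reaches the agent's `next_call_week`; the screening date falls
`notice_weeks` later (default 4); the next call is scheduled
`interval_weeks` (default 52) after the **call**, so consecutive calls — and
consecutive screening dates — are exactly one interval apart and a run of
`n_cycles` cycles spans `n_cycles × interval_weeks` weeks (520 by default).
Anchoring the cycle on the call rather than on the screening date is a
modelling choice; the alternative (interval counted from the screening
date) would stretch the cycle to `interval + notice` weeks. All agents are
called in week 0 by default; `stagger_first_call` spreads first calls
uniformly over one interval for steady-state studies.

Non-attendance counts: a missed screening increments `times_called` and
enters the denominator of the prior-adherence percentage, which is the
natural reading of "percentage of times adhered to previous screenings".
The current call is added to `times_called` *before* the decision (so the
logistic feature is always ≥ 1 at decision time) while `pct_prior_adherence`
reflects only completed calls. Inconclusive results are terminal for the
cycle; re-calls always wait a full interval.

## Screening outcomes

Two modes. `marginal` (default) draws positive/negative/inconclusive
directly from (0.04, 0.93, 0.03); no disease process is modelled.
`diagnostic` draws a latent disease state from `disease_prevalence`,
declares a positive with probability `sensitivity` (0.96) if diseased or
`1 − specificity` (0.06) if healthy, and splits the non-positive mass
between negative and inconclusive in their marginal proportions
(0.93 : 0.03). The split-the-remainder construction keeps
P(positive | diseased) exactly equal to the sensitivity; overlaying
inconclusives on the whole mass would silently deflate it.

## The fuzzy decision system

Three Mamdani components score an "adherence propensity" on [0, 100]. Every
input variable has exactly two linguistic terms, each of one of three
shapes: a line through two anchor points clamped to [0, 1]; a
peak-normalized gaussian `exp(−(x−c)²/2σ²)`; or the pointwise maximum of
two such gaussians with a shared σ. Gaussians are fuzzy memberships, not
probability densities — a density at, e.g., σ = 17,000 €/yr would give
memberships of order 10⁻⁵ and a degenerate system.

| Component | Variable (units, domain) | "favorable" term | other term |
|---|---|---|---|
| access barriers | age (yr, 0–100) | easy: line (0,0)–(100,1) | difficult: line (0,1)–(100,0) |
| | income (€/yr, 0–100k) | easy: max gauss(0, 100k), σ=17k | difficult: gauss(50k), σ=17k |
| | location difficulty (0–100) | easy: line (0,1)–(100,0) | difficult: line (0,0)–(100,1) |
| | urbanization (0–1) | easy: max gauss(0, 0.5), σ=0.1 | difficult: gauss(0.3), σ=0.1 |
| disease knowledge | age (yr, 0–100) | high: gauss(65), σ=30 | low: max gauss(18, 100), σ=30 |
| | education score (0–100) | high: line (0,0)–(100,1) | low: line (0,1)–(100,0) |
| | prior adherence (%, 0–100) | high: line (0,0)–(100,1) | low: line (0,1)–(100,0) |
| programme quality | reminder score (0–100) | high: line (0,0)–(100,1) | low: line (0,1)–(100,0) |
| | waiting time (min, 0–500) | high: line (0,1)–(500,0) | low: line (0,0)–(500,1) |
| | notice lead (wk, 0–12) | high: gauss(4), σ=2 | low: max gauss(0, 8), σ=2 |

Domains not implied by anchor points (location, education, reminder scores
on 0–100; urbanization on 0–1; notice on 0–12 weeks; income on 0–100,000
€/yr) were fixed once from the anchor and distribution parameters above.
Out-of-domain crisp inputs are clamped with a logged warning. The
age-barrier direction (access most difficult at age 0, easiest at 100) is
implemented exactly as specified by the source membership anchors, although
it is behaviourally counterintuitive; it is a faithful-reproduction choice,
not an endorsement.

Rule bases are generated, not hand-written: all 2ⁿ combinations of the
binary labels, with consequent "strong" when at least ⌈n/2⌉ inputs carry
their favorable label — 16 + 8 + 8 = 32 rules
(`drscreen list-rules`; also shipped as
`src/drscreen/data/fuzzy_components.json`). Inference is standard Mamdani:
minimum t-norm for antecedents, consequent sets clipped at the activation
level, pointwise-maximum aggregation, centre-of-gravity defuzzification.
The consequent terms ("strong" = line (0,0)–(100,1), "weak" its mirror)
mirror the dominant input shapes; the source system does not pin them down.
COG is computed by the trapezoid rule on 1001 evenly spaced points, which
the test suite shows agrees with a 20,001-point brute-force oracle to well
under 0.1 points; an identically-zero aggregate falls back to the domain
midpoint (50) rather than crashing a population run.

The final fuzzy probability is the mean of the three component scores ÷ 100
plus Uniform(−v/2, +v/2) noise, clipped to [0, 1], where `v` is the
`variability` parameter (default 0.1; the noise law is a design choice —
only its magnitude parameter is externally specified). Programme-quality
inputs are properties of the strategy, so that component is one number per
run; access barriers are static per agent and precomputed; only disease
knowledge is re-evaluated as histories evolve.

## The logistic engine and its calibration

`logit(p) = β₀ + β₁·pct_prior + β₂·times_called + Σ γ_k·1[last_result=k]`,
with "none" (never screened) as reference level — the coding is a choice,
as is probability averaging (rather than vote averaging) in the combined
engine, whose default weights are 0.5/0.5.

The shipped default coefficients (β₀ = −0.7, β₁ = 0.012 per percentage
point, β₂ = 0.06 per call, γ = +0.15 negative / −0.40 positive / −0.10
inconclusive) are also the generating coefficients of the synthetic
call-record generator, so stepwise refits recover them; their signs follow
the qualitative findings for this population (prior adherence and call
count raise the odds of attending; a previous positive result lowers them,
plausibly because hospital-followed patients are still being called). They
are configuration, not estimates from real data.

Calibration: forward-stepwise selection over 21 candidate covariates (the
three history predictors plus 18 registry-style variables — age, gender,
income, education, urbanization, occupation, phone contact, family doctor,
primary-care visits, diabetes type, BMI, HbA1c, call month, days between
calls, payment exemption, unit type, list size, distance). Each step scores
every remaining candidate by a likelihood-ratio test (categoricals enter
and leave as one block), admits the best if its p-value survives a
Bonferroni adjustment across the candidates examined at that step at
`entry_p = 0.05`, then removes any included candidate whose removal LR
p-value exceeds `stay_p = 0.10`. The per-step adjustment is deliberate:
naive per-candidate entry at 0.05 would admit at least one pure-noise
covariate from an 18-strong null pool more often than not, while the
adjusted rule keeps the family-wise false-entry rate near 5% and leaves the
three active predictors (whose LR p-values are ~10⁻⁷ or smaller at
n = 20,000) untouched. `multiplicity="none"` restores the classic rule.
Accuracy (0.5 cut) and AUC are reported on a 25% held-out split.

## The synthetic population

The generator emulates the *structure* of a confidential regional diabetic
registry; every distribution below is a synthetic stand-in, not an
estimate. Consequences: simulated regional adherence rates should track the
engine's probability model, not the shipped real-rate reference column, and
cross-region differences reflect only the synthetic attribute gradients.

Defaults (all editable in the config): 10,000 agents; subregion shares
(Porto metro 0.33, Entre Douro e Vouga 0.135, Tâmega e Sousa 0.13, Ave
0.125, Cávado 0.10, Alto Minho 0.075, Douro 0.06, Trás-os-Montes 0.045)
chosen so the five training subregions hold 66.5% of agents, matching the
published 66.41/33.59 geography split used for train/test experiments. Two
clusters: cluster 1 (share 0.509) age ~ N(48, 12²) truncated to [18, 100],
75% active / 5% students; cluster 2 (0.491) age ~ N(71, 9²), 82% retired.
Students are re-aged to Uniform(18, 25) so the student-intervention
subgroup exists. Income is log-normal per subregion, parameterized by a
median (8.4–11 k€/yr along an interior→coast gradient, σ_log = 0.45);
education and urbanization are subregion beta laws around means following
the same gradient. Initial histories: 30% never called; the rest get
`times_called ~ 1 + Poisson(2)` with per-call attendance Bernoulli(0.66)
and, if they ever attended, a last result drawn from (0.04, 0.93, 0.03).
The 0.66 per-call rate matches the observed overall adherence scale and
gives the logistic engine a non-degenerate week-0 feature set.

The KS-based generator tests check agreement with the *generating* laws;
they say nothing about agreement with real registry marginals, which are
not public.

## Scenarios

A scenario is a conjunction of attribute/history conditions evaluated on
the agent's state at decision time plus one action (`set`, `add`,
`multiply`), clipped to [0, 1]. "Increase adherence by 5%" is read as +5
percentage points on the decision probability (an additive uplift on a
subpopulation produces overall deltas of a few points, consistent with how
such interventions are usually reported); a multiplicative action is also
provided. `set` overrides whatever earlier scenarios did; scenarios compose
left-to-right; uplifts persist for as long as the selector holds. Paired
seeds plus a fixed number of random draws per decision batch (noise,
adherence and outcome variates are drawn for every decider, attending or
not) make scenario arms bitwise-comparable: agents outside the selector
reproduce the baseline run exactly.

## Replicates and reporting

Replicate seeds are spawned from a base seed via `numpy.random.SeedSequence`
(reported, so any replicate can be rerun alone). Reports give per-subregion
means and sample SDs of the final cumulative adherence rate over replicates
with Student-t confidence intervals at 95% and 99% (n−1 df) — the
documented, reproducible choice; published tables of this kind sometimes
print intervals matching no standard formula, and no attempt is made to
reverse-engineer one. With fewer than two replicates the intervals are
omitted with a warning. The convergence trace is the cumulative
attended/called ratio per week; with constant decision probabilities it
stabilizes as 1/cycles, and the engine's law-of-large-numbers behaviour is
verified at 10,000 agents × 10 cycles in the acceptance suite.

## Problem sizes and limitations

Default experiments use 10,000 agents × 520 weeks × 5 replicates (a few
seconds each); calibration experiments use 20,000 call records; Monte-Carlo
outcome checks use 100,000 draws. Known limitations: no disease-progression
model (outcomes are memoryless draws); no interaction between agents, so
population effects are sums of independent decisions; re-call scheduling is
uniform (no fast-track after a miss or an inconclusive result); and all
population-level numbers inherit the synthetic-population caveat above.
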