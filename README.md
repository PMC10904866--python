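# drscreen

An agent-based simulator of population adherence to diabetic-retinopathy
(DR) screening. DR is asymptomatic in its treatable stages, so health
administrations screen the whole diabetic population on a fixed cycle — and
the value of such a programme hinges on whether the people called actually
show up. `drscreen` models a regional screening programme (eight subregions,
weekly time steps, 52-week screening cycles) in which every diabetic is an
agent who individually decides, at each screening date, whether to attend.

It is intended for health-planning and simulation researchers who want to
compare decision mechanisms and stage hypothetical interventions ("what if
previously-positive patients were recalled more persuasively?") without
access to confidential registry data: a synthetic-population module emulates
the structure of a real registry (demographics, socioeconomics, screening
histories, two demographic clusters) so every experiment is reproducible
from a seed.

## The model

Each agent carries demographics (age, gender, income, education,
urbanization, occupation), a screening history (times called `t`, times
attended, percentage of prior adherence `pct`, last result ∈ {none,
negative, positive, inconclusive}) and a four-state status: *not called* →
*called* → *attended* / *did not attend* → *not called*. Calls are issued
every 52 weeks, the screening date falls `notice_weeks` (default 4) after
the call, and attended tests return positive/negative/inconclusive with
probabilities 0.04/0.93/0.03 (or via sensitivity 0.96 / specificity 0.94 in
diagnostic mode).

The decision to attend is a probability `p` produced by one of three
engines:

1. **Logistic** — `logit(p) = β₀ + β₁·pct + β₂·t + Σ γ_k·1[last result = k]`,
   calibrated by forward-stepwise selection (likelihood-ratio tests, enter
   p < 0.05 with per-step Bonferroni adjustment, remove p > 0.10) over 21
   candidate covariates; on the shipped synthetic call records exactly the
   three history predictors survive.
2. **Fuzzy** — a Mamdani system with three Health-Belief-Model components:
   *access barriers* (age, income, screening-location difficulty,
   urbanization; 16 rules), *disease knowledge* (age, education, prior
   adherence; 8 rules) and *programme quality* (reminders, waiting time,
   call-notice lead time; 8 rules). All 32 IF–THEN rules follow an
   "at-least-half favorable ⇒ strong propensity" template; inference uses
   min activation, max aggregation and centre-of-gravity defuzzification on
   a 0–100 propensity scale; `p` is the mean of the three component scores
   ÷ 100 plus a small uniform noise (the `variability` parameter).
3. **Combined** — `w·p_logistic + (1−w)·p_fuzzy` (default 50/50).

Intervention scenarios rewrite `p` for a selected subgroup (override to a
value, add percentage points, or multiply, always clipped to [0, 1]) and are
compared against a paired-seed baseline; three presets ship with the
package (previous-positives attend with p = 0.95; +5 points for anyone who
has attended before; +20 points for students under 25).

## Worked example

```bash
drscreen simulate --mode combined --replicates 5 --seed 7 --out demo
```

generates the default 10,000-agent population, runs five replicates of a
520-week simulation with the combined decision engine, and prints (also
written to `demo/report.csv`, with a convergence trace and per-cycle
summary alongside):

```
| subregion                  | mean_pct | sd_pct | ci95_lo | ci95_hi | ci99_lo | ci99_hi | reference_pct | difference_pct | ...
| Alto Minho                 | 61.29    | 0.50   | 60.66   | 61.91   | 60.25   | 62.32   | 74.10         | -12.81         |
| Ave                        | 59.96    | 0.59   | 59.24   | 60.69   | 58.76   | 61.17   | 72.09         | -12.13         |
| ...                        |          |        |         |         |         |         |               |                |
| Overall                    | 60.15    | 0.16   | 59.96   | 60.35   | 59.83   | 60.48   |               |                |
```

`mean_pct` is the cumulative adherence rate (attended ÷ called, %) per
subregion at week 520, averaged over the five replicates; `sd_pct` the
replicate standard deviation; the intervals are Student-t CIs on the
replicate mean. `reference_pct` is a shipped table of real regional
adherence rates included purely for side-by-side comparison — the synthetic
population is not calibrated to reproduce it, so differences of several
points are expected (see `docs/methods.md`).

Other entry points:

```bash
drscreen list-rules                       # audit the 32 generated fuzzy rules
drscreen generate-population --out pop.csv --seed 1
drscreen fit-logistic --n 20000 --seed 1  # stepwise calibration demo
drscreen simulate --mode logistic --scenario scenario2 --seed 1 --out scn2
```

All behaviour is configurable through a hierarchical YAML file (see
`src/drscreen/data/default_config.yaml`, the canonical record of the
default screening parameters); `drscreen simulate --config my.yaml ...`.

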