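# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, the synthetic default inputs, the numerical
choices, and the limits of what the shipped tests demonstrate.

## Model structure

Each woman is simulated independently, event-driven (no global time
step). Her pipeline is:

1. **Attributes** — birth year, region, BRCA1/2 carriage, family
   history, a single HRT exposure interval, and an other-cause death
   age from the life table. Other-cause mortality is independent of
   breast-cancer history: comorbidity feedback is out of scope.
2. **Natural history** — tumour onsets, growth coefficients, the
   counterfactual clinical detection age, node events, metastasis.
   This block consumes only the woman's `natural_history` random
   stream and is therefore *identical across scenarios* sharing a
   master seed (common random numbers).
3. **Screening overlay** — invitations, attendance, test results.
   Screening never alters the latent history; it can only observe the
   cancer earlier than the counterfactual clinical detection.
4. **Detection, staging, biology** — the earliest detection event
   (screen true positive or counterfactual clinical detection, both
   truncated at death) produces the diagnosed cancer.
5. **Progression** — a semi-Markov Weibull walk to recurrence and
   breast-cancer death, competing with other-cause death.
6. **Economics** — three-phase costs and multiplicative-utility QALYs.

### Onset

DCIS and invasive onsets are nonhomogeneous Poisson processes with
age × calendar-year base rates times multiplicative relative risks.
The two processes are independent except through history: a *prior
transforming DCIS* (one that onset before any invasive tumour) applies
a relative risk to the invasive process. Once a woman has an invasive
tumour, later DCIS lesions are flagged non-transforming and no longer
prime the invasive rate — the reduced-form expression of "in-situ
disease can no longer seed an invasive transformation after invasive
disease exists". There is no mechanistic DCIS→invasive transformation
event; the linkage is entirely through that relative risk, consistent
with invasive tumours being allowed to arise with no apparent in-situ
precursor (they pass the 2 mm modelling threshold already invasive).

Sampling is by thinning against a per-woman dominating constant (her
maximum attainable rate × relative-risk product); a violated bound is
an internal assertion error, not silently accepted.

### Growth

Gompertz diameter growth `d(t) = d0 (dmax/d0)^(1-exp(-alpha t))` with
`d0 = 0.2 cm` (the probable minimum mammographically detectable size;
all tumours enter the model at 2 mm). `alpha` (per year) and `dmax`
(cm) are lognormal within an aggressiveness class (mixture weights per
tumour type); BRCA carriers get a multiplier on `alpha`. `dmax` draws
are floored at 0.5 cm so the support always exceeds `d0`. Volume is
spherical, `V = pi d^3 / 6`, with `V'` by the chain rule.

### Nodal spread and metastasis

Nodes: NHPP with `lambda(t) = mu_N (b1 + b2 V + b3 V')`, invasive
tumours only, count unbounded. `mu_N` is drawn once per tumour from a
gamma distribution parameterised by mean and variance (shape =
mean²/var, scale = var/mean; zero variance degenerates to the mean).
The intensity is clamped at zero — the coefficients are unconstrained
data, and a Poisson intensity must be non-negative.

Metastasis: per-tumour hazard `mu_M · k(size class, node class)` with
`k` a lookup table on size × node-count classes, clamped to the
nearest class at the top; the woman-level hazard is the sum over her
invasive tumours. `k`'s tabular form is a modelling choice — only its
arguments (size, positive nodes) are structural.

### Detection and staging

Clinical detection hazard is the sum over tumours of a size-dependent
hazard linearly interpolated between knots; below the smallest knot it
ramps linearly from zero at size 0 (continuity; sub-2 mm tumours do
not exist in-model), above the largest knot it is clamped. The
first-event draw defines the counterfactual clinical detection age and
the "leading" tumour (picked proportionally to hazard share at that
age). For screen detection the leading tumour is the largest
screen-detected one; if the woman is metastatic at detection an
in-situ leading lesion is replaced by the largest invasive tumour so
Tis/M1 cannot co-occur.

T assignment: in-situ → Tis; otherwise a Bernoulli T4 draw from a
size × node-class probability table, then AJCC size bands (≤0.5 cm →
T1a — a floor, since T1mi is not modelled separately and onset is at
0.2 cm; then T1b, T1c, T2, T3). N is a categorical draw given (N\*
class, T); M1 iff metastasis preceded detection. The stage-group map
is a 7th-edition-style anatomic table collapsed to 0–IV, shipped as
code-level data and swappable. Biology (ER/PR × HER2 × grade) is one
joint categorical draw per detection, stratified by T, N, M, age
group, BRCA, and HRT; it does not feed back into natural history.

### Progression

Five transitions (diagnosis→local, diagnosis→distant, local→distant,
diagnosis→bc-death, distant→bc-death) as Weibull *accelerated failure
time* models: scale′ = scale · exp(Σβx), time = scale′·(−ln U)^(1/shape).
AFT was chosen because "Weibull regression" does not pin a
parameterisation; the coefficient tables declare the convention. The
walk is semi-Markov (clock resets at each transition); stage IV starts
in the distant state. Every candidate time competes with the woman's
other-cause death age; ties go to other-cause death (conservative for
screening benefit). An optional plateau fraction per transition lets a
transition never fire ("cured" fraction). Screen detection affects
survival only through the detection-mode covariate and the earlier
(smaller, less nodal) stage at diagnosis — no lead-time or survival
benefit is ever an input, so both are legitimate model *outputs*.

### Screening

A strategy is (start age, end age, interval, program calendar window,
participation, retention, re-entry, modality, sensitivity multiplier).
Attendance is a two-state chain on the previous invitation: first
invitation → participation; attended previous → retention; missed
previous → re-entry (defaults to participation). "Screen sequence" is
the two-level factor {first, subsequent}. Sensitivity varies by tumour
size × age group × sequence; specificity by age group. Per-tumour
detection is Bernoulli(sensitivity); a woman with tumours present is
TP if any is detected, else FN; tumour-free attenders are FP with
probability 1 − specificity. A TP exits the schedule (diagnosed); FP
costs a workup and returns her to the schedule.

Per-invitation uniforms are pre-drawn with shapes depending only on
the schedule and tumour count, never on test performance, so raising
sensitivity is a coupled, monotone perturbation: the same woman can
only be detected at the same screen or earlier. This is what makes the
overdetection-monotonicity property exact rather than statistical.

Lead time = counterfactual clinical detection age − screen age
(measured to end of life when no counterfactual exists). Overdetected
= the counterfactual is absent or falls after the woman's other-cause
death. Both denominators (per screen-detected case, per cohort) can be
derived from the per-woman report.

Rescreening calibration bisects the retention probability against a
target mean number of screens per woman, simulating the cohort's
natural histories once and replaying only the screening overlay per
candidate (common random numbers across candidates); tolerance 0.05
screens, with an explicit error naming the achievable bracket when the
target is outside it.

### Economics

Three phases: initial (first 18 months after diagnosis), continuing,
terminal (default final 1 year before a breast-cancer death — the
window length is a parameter because the phase is named without a
duration); terminal takes precedence on overlap, and other-cause
deaths have no terminal phase. Stage 0 has its own cost row. QALYs
integrate population age scores times all active state utilities
multiplicatively; since all weights lie in [0, 1], QALYs ≤ life years
by construction. Costs and QALYs are undiscounted by default with an
optional continuous annual discount rate (`discount_rate` constant) —
made explicit because the source convention is unstated.

## Random streams

`rng_stream(master_seed, individual_id, purpose)` with purposes
(population, natural_history, screening, progression, economics),
implemented as `SeedSequence(master_seed, spawn_key=(purpose, id))` —
counter-based, so streams never depend on execution order or scenario.
Within `simulate_natural_history` the draw order is fixed (onsets,
per-tumour coefficients, counterfactual detection, nodes, metastasis),
making per-woman histories bit-reproducible. The stream discipline is
this package's own design; nothing in the source material prescribes
one.

## Numerical choices

- **First-event sampling** (clinical detection, generic hazards): the
  cumulative hazard is inverted against a unit exponential on a
  uniform grid (default step 0.02 yr) treating the hazard as piecewise
  linear, with the in-segment inversion solved exactly as a quadratic.
  Constant and linear hazards are sampled exactly; smooth hazards to
  O(step²). This replaces adaptive quadrature + root refinement, which
  cost an order of magnitude more per draw for no measurable accuracy
  gain at these grid sizes.
- **Metastasis times** are exact: the hazard is piecewise constant
  between node events and size-class crossing ages (the Gompertz curve
  inverts in closed form), so the cumulative hazard is piecewise
  linear and inverted analytically.
- **Node thinning bound**: μ_N(b1 + b2·V(dmax) + b3·max V′), with
  max V′ from a 256-point grid inflated by 1.25 (V′ is unimodal);
  the acceptance step asserts the bound.
- **Life-table sampling** inverts the discrete survival CDF with one
  uniform plus uniform placement within the death year —
  distributionally identical to a year-by-year Bernoulli walk.
- **Tie order** for simultaneous events (measure-zero but fixed for
  reproducibility): other-cause death ≺ breast-cancer death ≺
  detection; equal progression times resolve to other-cause death.
- Degenerate inputs: gamma variance 0 → point mass at the mean; empty
  sampling windows → no events; rates/hazards validated non-negative
  at load rather than silently clipped (only λ(t) is clamped, by
  documented design).

## The toy parameter bundle

The calibrated input tables behind the original model (registry-fit
onset rates, growth mixtures, spread coefficients, staging and biology
distributions, survival regressions, costs, utilities) are not public.
The shipped bundle in `bcmicrosim.toy` is therefore synthetic, chosen
once for qualitative plausibility and never tuned to outputs:

- female all-cause mortality: Gompertz–Makeham, terminal at age 110;
- invasive onset rising from 5·10⁻⁵/yr (ages 20–29) to 3·10⁻³/yr
  (70s), DCIS at 22% of invasive, a mild secular increase after 1990;
  lifetime invasive risk ≈ 11%;
- growth classes indolent/intermediate/aggressive with median α of
  0.12/0.35/0.80 per year and median dmax 3–5 cm (invasive);
- μ_N mean 0.7 (variance 0.35), b = (0.05, 0.01, 0.5); μ_M mean 1.0
  (variance 0.5); k from 0.001 to 0.3 per year across size × node
  classes;
- detection hazards from 0.01/yr at 2 mm to 4/yr at 8 cm;
- mammography sensitivity 0.30–0.95 by size, specificity 0.93–0.96;
- Weibull transitions with baseline scales of years to decades and
  stage coefficients spanning exp(−2.6) (stage IV death) to exp(+1.8)
  (stage 0 distant recurrence).

What the toy bundle reproduces: incidence rising with age, multi-year
sojourn times through the screen-detectable size range, nodal and
metastatic burden growing with size, a screen-vs-clinical stage shift,
later-stage survival deficits, and an attendance chain whose retention
dial spans the trial's 4.8 mean screens. What it does **not** do:
match any registry's incidence, mortality, stage distribution, or cost
levels. Passing tests therefore demonstrate mechanistic and
statistical correctness of the machinery — closed forms, oracle
agreement, counterfactual exactness, conservation — not predictive
validity for any real population.

## Problem sizes in the shipped tests

Monte-Carlo checks use 10,000–50,000 replicates depending on the
statistic (binomial/multinomial frequencies at 10,000; event-count and
KS oracles at 20,000; medians and moment checks at 50,000), with
3-standard-error tolerances computed from the oracle value. The
trial-replication calibration runs 10,000 women; the discrete-time
competing-risk oracle uses Δt = 0.001 yr over an 11-year horizon at
n = 20,000. These sizes keep every statistical tolerance at least ~3×
its standard error.

## Known limitations

- Cohort mode only: no open-population demography, immigration, or
  provincial projection; male breast cancer excluded.
- One HRT interval per woman; no breast density, polygenic risk, or
  modality-specific physics; no radiation-induced risk.
- Biology is fixed at detection; no receptor-status evolution,
  treatment assignment, or pathologic-vs-clinical staging distinction.
- The transition set is the five named transitions; additional
  transitions would be a data/schema extension.
- Bootstrap intervals on rate ratios quantify Monte-Carlo noise only,
  not parameter or structural uncertainty.
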