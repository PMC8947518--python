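# bcmicrosim

An individual-level (microsimulation) model of breast cancer natural
history, screening, and outcomes, for epidemiologists and health-policy
analysts who want to compare early-detection strategies in silico:
screening start/stop ages, intervals, participation, test performance —
with the benefits (mortality reduction, stage shift) and harms (false
positives, overdetection) emerging mechanically from a latent disease
model rather than being assumed as inputs.

The package simulates one woman at a time: occult tumour onset, growth,
nodal spread and metastasis; clinical or screen detection with AJCC
staging and tumour biology; Weibull disease progression under competing
risk with other-cause death; and payer costs plus quality-adjusted life
years. A two-arm harness replicates a randomized screening-trial design
(annual mammography at ages 40–49 vs no screening) under common random
numbers.

## The model

**Onset.** Occult tumours (DCIS and invasive, independent processes)
arise from nonhomogeneous Poisson processes whose rates depend on age
and calendar year, scaled multiplicatively by risk-factor relative risks
(BRCA1/2 carriage, family history, hormone-replacement therapy, and a
prior-DCIS effect on the invasive process).

**Growth.** Each tumour starts at the occult-onset diameter
d₀ = 0.2 cm and follows a Gompertz curve

    d(t) = d₀ · (dmax / d₀)^(1 − e^(−αt))

with growth rate α and saturating diameter dmax drawn per tumour from
class-specific lognormal mixtures.

**Nodal spread** (invasive only) is a Poisson process with intensity

    λ(t) = μ_N · { b₁ + b₂ V(t) + b₃ V′(t) }

where V is the spherical tumour volume and μ_N is gamma-distributed
across tumours. **Metastasis** hazard is μ_M · k(size class, node
class), summed over a woman's invasive tumours, with μ_M gamma as well.

**Detection.** Clinical detection is a woman-level hazard: the sum over
tumours of a size-interpolated detection hazard. The first-event draw
from this hazard is the *counterfactual* clinical detection age, fixed
in the natural history; screening can only observe the cancer earlier.
Lead time and overdetection are therefore exact per-woman counterfactual
quantities. At detection, latent size T\* and node count N\* map to AJCC
T/N/M and an anatomic stage group, and an ER/PR × HER2 × grade triple is
drawn from the stratum's joint distribution.

**Progression.** Transitions (diagnosis → local recurrence, diagnosis →
distant recurrence, local → distant, diagnosis → breast-cancer death,
distant → breast-cancer death) are Weibull accelerated-failure-time
models with covariates for stage, age band, grade, receptor status,
HER2, and detection mode. A woman dies of breast cancer only if the
simulated breast-cancer death precedes her other-cause death age drawn
from the life table.

**Economics.** Costs follow the three-phase convention (initial = first
18 months, continuing, terminal); QALYs multiply age-specific population
preference scores with all concurrently active state utilities.

> **Parameter status.** The repository ships a synthetic "toy-default"
> parameter bundle that is structurally valid and qualitatively
> plausible but **not calibrated to any registry**. Absolute incidence,
> mortality, and cost outputs under the toy bundle are placeholders;
> the mechanisms, invariants, and counterfactual accounting are the
> product. Calibrated tables can be dropped in as CSV bundles
> (`bcmicrosim.params.write_parameter_set` documents the schema).

## Worked example

```python
import json
import bcmicrosim as bc

p = bc.default_parameters()
s = bc.Scenario(
    n=2000, birth_year_lo=1950, birth_year_hi=1957, master_seed=1,
    screening={"start_age": 50.0, "end_age": 69.0, "interval": 2.0},
    label="biennial_50_69",
)
report = bc.run_scenario(p, s)
print(json.dumps(report.summary(), indent=1, default=str))
```

prints

```json
{
 "scenario": "biennial_50_69",
 "n": 2000,
 "woman_years": 163882.0854769497,
 "diagnosed": 237,
 "dcis_diagnosed": 32,
 "bc_deaths": 114,
 "other_deaths": 1886,
 "incidence_per_100k": 144.61617284784583,
 "bc_mortality_per_100k": 69.56220972428027,
 "stage_distribution": {"I": 87, "II": 76, "III": 38, "0": 32, "IV": 4},
 "screens": 15278,
 "TP": 88,
 "FP": 770,
 "overdetected": 4,
 "total_cost": 25769503.56006721,
 "total_qaly": 148709.83571593737
}
```

Reading it: 2,000 women born 1950–1957 were offered biennial
mammography at ages 50–69. Over their 163,882 woman-years, 237 cancers
were diagnosed (32 in situ), 88 of them at screens; 770 screens were
false positives and 4 screen-detected cancers would never have
presented clinically (overdetection). Rates are per 100,000
woman-years; costs are in the toy bundle's currency units; QALYs are
utility-weighted life years. All numbers are toy-parameter outputs,
reproducible exactly from the master seed.

The same machinery is exposed on the command line:

```bash
bcmicrosim simulate --scenario scenario.yaml --seed 1 --out out/
bcmicrosim compare --scenario-a a.yaml --scenario-b b.yaml --seed 1
bcmicrosim age-trial --n 10000 --seed 1
```

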