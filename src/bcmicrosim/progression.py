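"""Post-diagnosis disease course under competing risks.

Transitions between clinical states (diagnosis, local recurrence, distant
recurrence, breast-cancer death) are Weibull accelerated-failure-time
models: the scale parameter is multiplied by exp(beta . x) for covariates
describing stage, age band, grade, receptor status, HER2, and detection
mode.  The walk is semi-Markov — the Weibull clock resets at each
transition — and every candidate event time competes against the woman's
other-cause death age; the earliest event wins.  An optional plateau
("cured") fraction lets a transition never fire.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .detection import DetectedCancer
from .population import Individual

__all__ = [
    "WeibullTransitionModel",
    "ClinicalCourse",
    "TRANSITIONS",
    "models_from_table",
    "covariates_for",
    "weibull_time",
    "simulate_course",
    "resolve_death",
]

TRANSITIONS = (
    "diagnosis_to_local",
    "diagnosis_to_distant",
    "local_to_distant",
    "diagnosis_to_bc_death",
    "distant_to_bc_death",
)


@dataclasses.dataclass(frozen=True)
class WeibullTransitionModel:
    """One state-to-state Weibull AFT model.

    ``scale`` is the baseline scale in years; ``coefficients`` act on the
    log of the scale (positive beta lengthens times).  ``plateau`` is the
    fraction for whom the transition never occurs.
    """

    transition: str
    shape: float
    scale: float
    coefficients: dict[str, float]
    plateau: float = 0.0

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        if not 0 <= self.plateau <= 1:
            raise ValueError("plateau fraction must lie in [0, 1]")

    def adjusted_scale(self, covariates: dict[str, float]) -> float:
        lp = 0.0
        for name, beta in self.coefficients.items():
            x = covariates.get(name, 0.0)
            if not np.isfinite(x):
                raise ValueError(f"covariate {name!r} outside model support: {x}")
            lp += beta * x
        return self.scale * math.exp(lp)


@dataclasses.dataclass
class ClinicalCourse:
    """Ordered post-diagnosis events ending in exactly one death."""

    events: list[tuple[float, str]]  # (age, event name)
    cause_of_death: str  # "breast_cancer" | "other"
    death_age: float


def models_from_table(table: pd.DataFrame) -> dict[str, WeibullTransitionModel]:
    """Build transition models from the progression parameter table."""
    meta = {"transition", "shape", "scale", "plateau"}
    models = {}
    for _, row in table.iterrows():
        coeffs = {c: float(row[c]) for c in table.columns if c not in meta}
        models[str(row["transition"])] = WeibullTransitionModel(
            transition=str(row["transition"]),
            shape=float(row["shape"]),
            scale=float(row["scale"]),
            coefficients=coeffs,
            plateau=float(row.get("plateau", 0.0)),
        )
    return models


def covariates_for(dc: DetectedCancer) -> dict[str, float]:
    """Indicator covariates for the fitted transition models.

    Baseline woman: clinically detected stage I, age 50-69 at diagnosis,
    grade 2, ER/PR-positive, HER2-negative.
    """
    return {
        "stage_0": 1.0 if dc.stage == "0" else 0.0,
        "stage_II": 1.0 if dc.stage == "II" else 0.0,
        "stage_III": 1.0 if dc.stage == "III" else 0.0,
        "stage_IV": 1.0 if dc.stage == "IV" else 0.0,
        "age_lt50": 1.0 if dc.detection_age < 50 else 0.0,
        "age_ge70": 1.0 if dc.detection_age >= 70 else 0.0,
        "grade_1": 1.0 if dc.grade == 1 else 0.0,
        "grade_3": 1.0 if dc.grade == 3 else 0.0,
        "er_pr_neg": 1.0 if dc.er_pr == "neg" else 0.0,
        "her2_pos": 1.0 if dc.her2 == "pos" else 0.0,
        "screen_detected": 1.0 if dc.mode == "screen" else 0.0,
    }


def weibull_time(
    m: WeibullTransitionModel, covariates: dict[str, float], rng: np.random.Generator
) -> float:
    """AFT draw: time = scale' * (-ln U)^(1/shape); inf for the plateau."""
    if m.plateau > 0 and rng.uniform() < m.plateau:
        return math.inf
    scale = m.adjusted_scale(covariates)
    u = rng.uniform()
    # guard against u == 0 (log of zero)
    u = max(u, 1e-300)
    return scale * (-math.log(u)) ** (1.0 / m.shape)


def resolve_death(t_bc: float, t_other: float) -> tuple[str, float]:
    """Competing-risk rule: breast-cancer death iff strictly sooner.

    Ties break in favour of other-cause death (conservative for any
    screening benefit).  ``t_bc`` may be +inf ("never").
    """
    if not math.isfinite(t_other):
        raise ValueError("other-cause death time must be finite")
    if t_bc < t_other:
        return "breast_cancer", t_bc
    return "other", t_other


def simulate_course(
    dc: DetectedCancer,
    ind: Individual,
    models: dict[str, WeibullTransitionModel],
    rng: np.random.Generator,
) -> ClinicalCourse:
    """Semi-Markov walk from diagnosis to a single death event.

    Stage IV disease starts in the distant state.  At each state the
    candidate transition times are drawn fresh (clock reset) and the
    minimum — or the woman's other-cause death, whichever is earlier —
    determines the next event.
    """
    for name in TRANSITIONS:
        if name not in models:
            raise ValueError(f"missing transition model {name!r}")
    cov = covariates_for(dc)
    t_other = ind.other_cause_death_age
    events: list[tuple[float, str]] = []
    now = dc.detection_age
    state = "distant" if dc.stage == "IV" else "diagnosis"
    if state == "distant":
        events.append((now, "distant_recurrence_at_diagnosis"))

    while True:
        if state == "diagnosis":
            candidates = {
                "local_recurrence": now + weibull_time(models["diagnosis_to_local"], cov, rng),
                "distant_recurrence": now + weibull_time(models["diagnosis_to_distant"], cov, rng),
                "bc_death": now + weibull_time(models["diagnosis_to_bc_death"], cov, rng),
            }
        elif state == "local":
            candidates = {
                "distant_recurrence": now + weibull_time(models["local_to_distant"], cov, rng)
            }
        elif state == "distant":
            candidates = {
                "bc_death": now + weibull_time(models["distant_to_bc_death"], cov, rng)
            }
        else:  # pragma: no cover - unreachable
            raise RuntimeError(f"unknown state {state}")

        event = min(candidates, key=candidates.get)
        t_event = candidates[event]
        if t_other <= t_event:
            events.append((t_other, "other_death"))
            return ClinicalCourse(events=events, cause_of_death="other", death_age=t_other)
        if event == "bc_death":
            events.append((t_event, "bc_death"))
            return ClinicalCourse(
                events=events, cause_of_death="breast_cancer", death_age=t_event
            )
        events.append((t_event, event))
        now = t_event
        state = "local" if event == "local_recurrence" else "distant"
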