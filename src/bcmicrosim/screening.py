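"""Screening strategies applied to a latent natural history.

The natural history (onsets, growth, node events, metastasis, and the
counterfactual clinical-detection age) is simulated once per woman and is
invariant across scenarios; screening only changes what is *observed*.
That makes lead time (counterfactual clinical detection age minus screen
detection age) and overdetection (screen-detected cancers that would
never have surfaced clinically within the woman's lifetime) well-defined
per-woman counterfactual quantities rather than population inferences.

Per-invitation random draws are pre-generated with shapes that depend
only on the invitation schedule and the tumour burden — never on test
performance — so attendance and detection are monotonically coupled
across sensitivity settings (the same woman under higher sensitivity is
detected at the same screen or earlier).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import _tables
from .natural_history import NaturalHistory, diameter
from .params import ParameterSet, Scenario, rng_stream
from .population import Individual

__all__ = [
    "ScreeningStrategy",
    "ScreenRecord",
    "ScreenDetection",
    "strategy_from_dict",
    "build_schedule",
    "attend",
    "run_screening",
    "account_screen_detection",
    "calibrate_rescreening",
]


@dataclasses.dataclass(frozen=True)
class ScreeningStrategy:
    start_age: float
    end_age: float
    interval: float = 1.0
    program_year_lo: float = -math.inf
    program_year_hi: float = math.inf
    participation: float = 0.9  # first-invitation attendance probability
    retention: float = 0.85  # attend | attended previous invitation
    reentry: float | None = None  # attend | missed previous; default participation
    modality: str = "mammography"
    sensitivity_multiplier: float = 1.0  # experiment dial; effective sens clipped to [0,1]

    def __post_init__(self):
        if not self.start_age < self.end_age:
            raise ValueError("strategy requires start_age < end_age")
        if self.interval <= 0:
            raise ValueError("screening interval must be positive")
        for name in ("participation", "retention"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability")
        if self.reentry is not None and not 0 <= self.reentry <= 1:
            raise ValueError("reentry must be a probability")

    @property
    def reentry_prob(self) -> float:
        return self.participation if self.reentry is None else self.reentry


def strategy_from_dict(d: dict) -> ScreeningStrategy:
    return ScreeningStrategy(**d)


@dataclasses.dataclass
class ScreenRecord:
    age: float
    invitation_number: int  # 1-based position in the schedule
    sequence: str | None  # "first" | "subsequent" (None if not attended)
    attended: bool
    result: str | None  # "TP" | "FP" | "TN" | "FN" (None if not attended)
    detected_sizes: tuple[float, ...] = ()
    detected_indices: tuple[int, ...] = ()


@dataclasses.dataclass
class ScreenDetection:
    age: float
    leading_index: int
    lead_time: float
    overdetected: bool


def build_schedule(s: ScreeningStrategy, ind: Individual) -> np.ndarray:
    """Invitation ages: start to end by interval, clipped to the program's
    calendar window and the woman's lifespan."""
    n = int(math.floor((s.end_age - s.start_age) / s.interval + 1e-9)) + 1
    ages = s.start_age + s.interval * np.arange(n)
    years = ind.birth_year + ages
    keep = (
        (ages < ind.other_cause_death_age)
        & (years >= s.program_year_lo)
        & (years <= s.program_year_hi)
    )
    return ages[keep]


def attend(s: ScreeningStrategy, prior_state: str, u: float) -> bool:
    """Attendance decision given the previous-invitation state.

    ``prior_state`` is "none" at the first invitation, else "attended" or
    "missed" for the preceding one.
    """
    if prior_state == "none":
        prob = s.participation
    elif prior_state == "attended":
        prob = s.retention
    elif prior_state == "missed":
        prob = s.reentry_prob
    else:
        raise ValueError(f"unknown attendance state {prior_state!r}")
    return u < prob


def _sensitivity(
    p: ParameterSet, s: ScreeningStrategy, size: float, age: float, sequence: str
) -> float:
    raw = _tables.lookup_sensitivity(p.sensitivity, size, age, sequence)
    return float(np.clip(raw * s.sensitivity_multiplier, 0.0, 1.0))


def _specificity(p: ParameterSet, age: float) -> float:
    return _tables.lookup_interval(p.specificity, "age_lo", "age_hi", age, "specificity")


def account_screen_detection(
    nh: NaturalHistory, ind: Individual, screen_age: float
) -> tuple[float, bool]:
    """Lead time and overdetection flag for a true-positive screen.

    Lead time is measured to the counterfactual clinical detection age;
    if the cancer would never have presented clinically, it is measured to
    end of life and the case is overdetected.
    """
    c = nh.counterfactual_clinical_detection_age
    if c is None:
        return ind.other_cause_death_age - screen_age, True
    overdetected = c > ind.other_cause_death_age
    return c - screen_age, overdetected


def run_screening(
    p: ParameterSet,
    s: ScreeningStrategy,
    nh: NaturalHistory,
    ind: Individual,
    rng: np.random.Generator,
) -> tuple[list[ScreenRecord], ScreenDetection | None]:
    """Overlay one woman's screening pathway on her latent history.

    Screens stop at the first detection event (screen TP or, implicitly,
    the counterfactual clinical detection, whichever comes first) or at
    death.  A false positive sends the woman to workup and back into the
    schedule; a true positive exits her to the diagnosed pathway.
    """
    schedule = build_schedule(s, ind)
    n_inv = len(schedule)
    records: list[ScreenRecord] = []
    if n_inv == 0:
        return records, None

    # pre-drawn uniforms: shapes depend only on schedule and tumour count
    u_attend = rng.uniform(size=n_inv)
    u_fp = rng.uniform(size=n_inv)
    n_tum = max(len(nh.tumours), 1)
    u_detect = rng.uniform(size=(n_inv, n_tum))

    c = nh.counterfactual_clinical_detection_age
    detection_bound = min(
        ind.other_cause_death_age, c if c is not None else math.inf
    )
    prior_state = "none"
    attended_before = False
    for j, age in enumerate(schedule):
        if age >= detection_bound:
            break
        is_attending = attend(s, prior_state, u_attend[j])
        prior_state = "attended" if is_attending else "missed"
        if not is_attending:
            records.append(
                ScreenRecord(age=age, invitation_number=j + 1, sequence=None, attended=False, result=None)
            )
            continue
        sequence = "subsequent" if attended_before else "first"
        attended_before = True
        present = [
            (i, t) for i, t in enumerate(nh.tumours) if t.onset_age <= age
        ]
        detected: list[tuple[float, int]] = []
        for i, t in present:
            d = diameter(t, age)
            sens = _sensitivity(p, s, d, age, sequence)
            if u_detect[j, i] < sens:
                detected.append((d, i))
        if detected:
            result = "TP"
        elif present:
            result = "FN"
        else:
            result = "FP" if u_fp[j] < 1.0 - _specificity(p, age) else "TN"
        records.append(
            ScreenRecord(
                age=age,
                invitation_number=j + 1,
                sequence=sequence,
                attended=True,
                result=result,
                detected_sizes=tuple(d for d, _ in detected),
                detected_indices=tuple(i for _, i in detected),
            )
        )
        if result == "TP":
            leading = max(detected)[1]  # largest screen-detected tumour
            lead_time, overdetected = account_screen_detection(nh, ind, age)
            return records, ScreenDetection(
                age=age, leading_index=leading, lead_time=lead_time, overdetected=overdetected
            )
    return records, None


# ---------------------------------------------------------------------------
# Rescreening calibration


def calibrate_rescreening(
    p: ParameterSet,
    strategy: ScreeningStrategy,
    target_mean_screens: float,
    cohort: Scenario,
    master_seed: int,
    *,
    tol: float = 0.05,
    max_iter: int = 60,
) -> tuple[float, float]:
    """Bisection on the retention probability to hit a mean screen count.

    Simulates the cohort's natural histories once (they do not depend on
    the screening strategy) and replays the screening overlay at each
    candidate retention, with common random numbers across candidates.
    Returns (retention, achieved mean screens per woman).
    """
    from .natural_history import simulate_natural_history
    from .population import sample_individual

    women = []
    for i in range(cohort.n):
        ind = sample_individual(p, cohort, i, rng_stream(master_seed, i, "population"))
        nh = simulate_natural_history(p, ind, rng_stream(master_seed, i, "natural_history"))
        women.append((ind, nh))

    def mean_screens(retention: float) -> float:
        strat = dataclasses.replace(strategy, retention=retention)
        total = 0
        for i, (ind, nh) in enumerate(women):
            records, _ = run_screening(
                p, strat, nh, ind, rng_stream(master_seed, i, "screening")
            )
            total += sum(1 for r in records if r.attended)
        return total / len(women)

    lo, hi = 0.0, 1.0
    m_lo, m_hi = mean_screens(lo), mean_screens(hi)
    if not (m_lo - tol <= target_mean_screens <= m_hi + tol):
        raise ValueError(
            f"target {target_mean_screens} screens/woman outside achievable "
            f"range [{m_lo:.3f}, {m_hi:.3f}] for retention in [0, 1]"
        )
    if abs(m_hi - target_mean_screens) <= tol:
        return hi, m_hi
    if abs(m_lo - target_mean_screens) <= tol:
        return lo, m_lo

    achieved = m_hi
    mid = hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        achieved = mean_screens(mid)
        if abs(achieved - target_mean_screens) <= tol:
            break
        if achieved < target_mean_screens:
            lo = mid
        else:
            hi = mid
    return mid, achieved
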