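"""Simulated women: demographic attributes, risk factors, other-cause death.

Other-cause mortality is sampled from the life table independently of any
breast-cancer history (comorbidity feedback is out of model scope), which
is exactly what makes it the competing risk in the progression layer.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import _tables
from .params import ParameterSet, Scenario

__all__ = ["Individual", "HRTExposure", "sample_individual", "sample_other_cause_death_age"]


@dataclasses.dataclass(frozen=True)
class HRTExposure:
    """One hormone-replacement-therapy use interval [start_age, stop_age)."""

    start_age: float
    stop_age: float

    def __post_init__(self):
        if not (0 < self.start_age <= self.stop_age):
            raise ValueError("HRT exposure interval must be well ordered")

    def status_at(self, age: float) -> str:
        if age < self.start_age:
            return "never"
        if age < self.stop_age:
            return "current"
        return "past"


@dataclasses.dataclass(frozen=True)
class Individual:
    id: int
    birth_year: int
    region: str
    brca: str  # "none" | "carrier"
    family_history: bool
    hrt: HRTExposure | None
    other_cause_death_age: float

    def hrt_status_at(self, age: float) -> str:
        return self.hrt.status_at(age) if self.hrt is not None else "never"

    @property
    def hrt_ever(self) -> bool:
        return self.hrt is not None


def sample_other_cause_death_age(
    life_table: pd.DataFrame, birth_year: int, rng: np.random.Generator
) -> float:
    """Draw an age at death from all causes other than breast cancer.

    Equivalent to a year-by-year Bernoulli walk through the table's annual
    death probabilities with uniform placement inside the death year,
    implemented by inverting the discrete survival curve with a single
    uniform (distributionally identical, O(log n) per draw).  The life
    table must terminate with probability 1, so the support is bounded by
    the table's maximum age.
    """
    ages, qx, cdf = _tables.life_table_cdf(life_table)
    if qx[-1] < 1.0:
        raise ValueError("life table must terminate with death probability 1")
    # P(death in year i) = qx_i * prod_{j<i}(1 - qx_j); cdf is the implied
    # CDF evaluated at the end of each year
    u = rng.uniform()
    i = int(np.searchsorted(cdf, u, side="left"))
    i = min(i, len(ages) - 1)
    return float(ages[i]) + float(rng.uniform())


def sample_individual(
    p: ParameterSet, s: Scenario, ind_id: int, rng: np.random.Generator
) -> Individual:
    """Draw one woman's fixed attributes from the prevalence tables."""
    birth_year = int(rng.integers(s.birth_year_lo, s.birth_year_hi + 1))
    brca = "carrier" if rng.uniform() < p.prevalence("brca") else "none"
    family_history = bool(rng.uniform() < p.prevalence("family_history"))
    hrt = None
    # draw the HRT interval unconditionally so that downstream stream
    # consumption does not depend on the ever-use coin (keeps per-woman
    # draw counts fixed -> reproducible across prevalence settings)
    u_ever = rng.uniform()
    start = rng.normal(p.prevalence("hrt_start_mean"), p.prevalence("hrt_start_sd"))
    duration = rng.exponential(p.prevalence("hrt_duration_mean"))
    if u_ever < p.prevalence("hrt_ever"):
        start = max(start, 30.0)
        hrt = HRTExposure(start_age=start, stop_age=start + duration)
    death_age = sample_other_cause_death_age(p.life_table, birth_year, rng)
    death_age = min(death_age, s.max_age)
    return Individual(
        id=ind_id,
        birth_year=birth_year,
        region=s.region,
        brca=brca,
        family_history=family_history,
        hrt=hrt,
        other_cause_death_age=death_age,
    )
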