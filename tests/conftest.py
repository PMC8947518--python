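"""Shared fixtures: toy parameter bundles and purpose-built variants."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from bcmicrosim import Scenario, default_parameters
from bcmicrosim.params import ParameterSet


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    """The shipped toy-default bundle (read-only across the session)."""
    return default_parameters()


def flat_onset_params(
    base: ParameterSet, rate_invasive: float, rate_dcis: float = 0.0
) -> ParameterSet:
    """Variant with a constant onset rate at all ages/years and RRs of 1."""
    rows = []
    for ttype, r in (("invasive", rate_invasive), ("dcis", rate_dcis)):
        rows.append((0, 200, 1700, 3000, ttype, r))
    onset = pd.DataFrame(
        rows, columns=["age_lo", "age_hi", "year_lo", "year_hi", "tumour_type", "rate"]
    )
    rrs = base.risk_relative_risks.copy()
    rrs["rr"] = 1.0
    prev = base.risk_factor_prevalence.copy()
    prev.loc[prev["key"].isin(["brca", "family_history", "hrt_ever"]), "value"] = 0.0
    return dataclasses.replace(
        base, onset_rates=onset, risk_relative_risks=rrs, risk_factor_prevalence=prev
    )


def fixed_death_life_table(age: int) -> pd.DataFrame:
    """Degenerate life table: certain death in year ``age``."""
    ages = np.arange(0, age + 1)
    qx = np.zeros(len(ages))
    qx[-1] = 1.0
    return pd.DataFrame({"age": ages, "qx": qx})


@pytest.fixture
def trial_cohort() -> Scenario:
    return Scenario(n=200, birth_year_lo=1950, birth_year_hi=1957, master_seed=11)
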