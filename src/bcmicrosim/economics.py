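"""Payer-perspective costs and quality-adjusted life years.

Cancer costs follow the three-phase convention: an initial phase covering
the first 18 months after diagnosis, a continuing phase, and a terminal
phase (default final year before a breast-cancer death); the terminal
phase takes precedence where the windows overlap.  Screening and workup
costs are unit costs per event.

QALYs integrate the product of the age-specific population preference
score and all concurrently active health-state utilities (multiplicative
combination), so QALYs can never exceed life years.  An optional annual
discount rate (continuous compounding from birth) applies to both costs
and QALYs; the default is undiscounted.
"""

from __future__ import annotations

import math

import numpy as np

from .params import ParameterSet

__all__ = ["phase_at", "lifetime_cost", "qaly"]


def phase_at(
    diagnosis_age: float,
    death_age: float,
    t: float,
    *,
    bc_death: bool,
    terminal_window: float = 1.0,
) -> str:
    """Phase of care at age ``t`` for a diagnosed woman."""
    if not diagnosis_age <= t <= death_age:
        raise ValueError("phase query outside [diagnosis, death]")
    if bc_death and death_age - t <= terminal_window:
        return "terminal"
    if t - diagnosis_age <= 1.5:
        return "initial"
    return "continuing"


def _disc_integral(rate: float, t0: float, t1: float, r: float) -> float:
    """Integral of rate * exp(-r*t) dt over [t0, t1]."""
    if t1 <= t0:
        return 0.0
    if r == 0.0:
        return rate * (t1 - t0)
    return rate * (math.exp(-r * t0) - math.exp(-r * t1)) / r


def _phase_cost_rate(p: ParameterSet, stage: str, phase: str) -> float:
    tab = p.phase_costs
    hit = tab[(tab["stage"] == stage) & (tab["phase"] == phase)]
    if hit.empty:
        raise ValueError(f"no phase cost for stage {stage!r}, phase {phase!r}")
    return float(hit["annual_cost"].iloc[0])


def lifetime_cost(history, p: ParameterSet) -> float:
    """Total lifetime cost for one simulated woman.

    ``history`` is any object with ``screen_records`` (ScreenRecord list),
    ``cancer`` (DetectedCancer or None), ``course`` (ClinicalCourse or
    None) and ``individual`` attributes, i.e. an engine LifeHistory.
    """
    r = p.constant("discount_rate")
    screen_cost = float(p.unit_costs.loc[p.unit_costs["item"] == "screen", "cost"].iloc[0])
    workup_cost = float(p.unit_costs.loc[p.unit_costs["item"] == "workup", "cost"].iloc[0])
    total = 0.0
    for rec in history.screen_records:
        if rec.attended:
            disc = math.exp(-r * rec.age) if r else 1.0
            total += screen_cost * disc
            if rec.result in ("FP", "TP"):  # abnormal screen -> workup bundle
                total += workup_cost * disc

    dc = history.cancer
    if dc is None:
        return total
    course = history.course
    death = course.death_age
    bc_death = course.cause_of_death == "breast_cancer"
    window = p.constant("terminal_window_years")
    # phase boundaries: initial ends at dx+1.5, terminal begins at death-window
    cuts = sorted({dc.detection_age, min(dc.detection_age + 1.5, death), death}
                  | ({max(death - window, dc.detection_age)} if bc_death else set()))
    for t0, t1 in zip(cuts[:-1], cuts[1:]):
        if t1 <= t0:
            continue
        mid = 0.5 * (t0 + t1)
        phase = phase_at(dc.detection_age, death, mid, bc_death=bc_death, terminal_window=window)
        total += _disc_integral(_phase_cost_rate(p, dc.stage, phase), t0, t1, r)
    return total


def _state_utility(p: ParameterSet, state: str) -> float:
    tab = p.state_utilities
    hit = tab[tab["state"] == state]
    if hit.empty:
        raise ValueError(f"no utility for state {state!r}")
    return float(hit["utility"].iloc[0])


def qaly(history, p: ParameterSet) -> float:
    """Quality-adjusted life years over the woman's whole life.

    Piecewise-constant integration: within each segment the population
    age score and the set of active states are constant, so midpoint
    evaluation is exact.
    """
    r = p.constant("discount_rate")
    death = history.course.death_age if history.course is not None else history.individual.other_cause_death_age
    pu = p.population_utilities
    cuts = {0.0, death}
    cuts.update(float(a) for a in pu["age_lo"] if 0.0 < float(a) < death)
    dc = history.cancer
    recurrences: list[tuple[float, str]] = []
    bc_death = False
    if dc is not None:
        course = history.course
        bc_death = course.cause_of_death == "breast_cancer"
        window = p.constant("terminal_window_years")
        cuts.add(dc.detection_age)
        cuts.add(min(dc.detection_age + 1.5, death))
        if bc_death:
            cuts.add(max(death - window, dc.detection_age))
        for age, ev in course.events:
            if ev in ("local_recurrence", "distant_recurrence", "distant_recurrence_at_diagnosis"):
                recurrences.append((age, ev))
                cuts.add(age)
    grid = sorted(c for c in cuts if 0.0 <= c <= death)
    total = 0.0
    for t0, t1 in zip(grid[:-1], grid[1:]):
        if t1 <= t0:
            continue
        mid = 0.5 * (t0 + t1)
        u = float(
            pu.loc[(pu["age_lo"] <= mid) & (mid < pu["age_hi"]), "score"].iloc[0]
        )
        if dc is not None and mid >= dc.detection_age:
            phase = phase_at(
                dc.detection_age, death, mid, bc_death=bc_death,
                terminal_window=p.constant("terminal_window_years"),
            )
            if phase == "initial":
                u *= _state_utility(p, f"initial_{dc.stage}")
            elif phase == "terminal":
                u *= _state_utility(p, "terminal")
            else:
                u *= _state_utility(p, "continuing")
            # recurrence states persist from their event to death, multiplicatively
            active = set()
            for age, ev in recurrences:
                if age <= mid:
                    active.add("local_recurrence" if ev == "local_recurrence" else "distant_recurrence")
            for st in active:
                u *= _state_utility(p, st)
        total += _disc_integral(u, t0, t1, r)
    return total
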