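"""Toy default parameter bundle.

The simulator's calibrated input tables (onset rates, growth-coefficient
distributions, nodal-spread and metastasis coefficients, staging and
biology distributions, survival regressions, costs and utilities) are
proprietary registry-calibrated data that are not redistributable.  This
module therefore ships a fully synthetic, clearly NON-CALIBRATED bundle
whose only claims are structural: incidence rises with age, tumours take
years to traverse the clinically relevant size range, nodal and metastatic
burden grow with size, screening detects smaller tumours than clinical
presentation, and later stage means worse survival.  Absolute numbers are
placeholders chosen once for qualitative plausibility; nothing here is fit
to any registry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import ParameterSet

__all__ = ["default_parameters", "T_CATEGORIES", "N_CATEGORIES", "AGE_GROUPS"]

T_CATEGORIES = ["Tis", "T1a", "T1b", "T1c", "T2", "T3", "T4"]
N_CATEGORIES = ["N0", "N1mi", "N1", "N2", "N3"]
AGE_GROUPS = ["<50", "50-69", "70+"]

MAX_AGE = 110


def _life_table() -> pd.DataFrame:
    """Gompertz–Makeham female all-cause mortality, terminal at MAX_AGE."""
    ages = np.arange(0, MAX_AGE + 1)
    qx = 0.0004 + 2.2e-5 * np.exp(0.092 * ages)
    qx[0] = 0.004  # infant mortality bump
    qx = np.clip(qx, 0.0, 1.0)
    qx[-1] = 1.0
    return pd.DataFrame({"age": ages, "qx": qx})


def _onset_rates() -> pd.DataFrame:
    """Occult-onset rate per woman-year by age band, period, tumour type."""
    bands = [
        (0, 20, 0.0),
        (20, 30, 5e-5),
        (30, 40, 3e-4),
        (40, 50, 1.2e-3),
        (50, 60, 2.0e-3),
        (60, 70, 2.7e-3),
        (70, 80, 3.0e-3),
        (80, 121, 2.8e-3),
    ]
    periods = [(1700, 1990, 1.0), (1990, 3000, 1.1)]  # mild secular increase
    rows = []
    for alo, ahi, r in bands:
        for ylo, yhi, mult in periods:
            rows.append((alo, ahi, ylo, yhi, "invasive", r * mult))
            rows.append((alo, ahi, ylo, yhi, "dcis", 0.22 * r * mult))
    return pd.DataFrame(
        rows, columns=["age_lo", "age_hi", "year_lo", "year_hi", "tumour_type", "rate"]
    )


def _growth_params() -> pd.DataFrame:
    """Lognormal (alpha, dmax) mixtures by tumour type and aggressiveness."""
    rows = [
        # type, class, proportion, log alpha mean/sd, log dmax mean/sd
        ("invasive", "indolent", 0.25, np.log(0.12), 0.45, np.log(3.0), 0.35),
        ("invasive", "intermediate", 0.50, np.log(0.35), 0.45, np.log(4.0), 0.35),
        ("invasive", "aggressive", 0.25, np.log(0.80), 0.45, np.log(5.0), 0.35),
        ("dcis", "indolent", 0.60, np.log(0.10), 0.50, np.log(2.0), 0.30),
        ("dcis", "intermediate", 0.40, np.log(0.30), 0.50, np.log(2.8), 0.30),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "tumour_type",
            "aggressiveness_class",
            "proportion",
            "log_alpha_mean",
            "log_alpha_sd",
            "log_dmax_mean",
            "log_dmax_sd",
        ],
    )


def _biology() -> pd.DataFrame:
    """Joint ER/PR x HER2 x grade distribution over full strata.

    Built as a product of stratum-dependent marginals (so every stratum
    sums to one by construction).  BRCA carriers skew hormone-receptor
    negative and high grade; HRT exposure skews toward lower grade; larger
    T and positive nodes skew toward higher grade.
    """
    t_grade_shift = {
        "Tis": -0.5,
        "T1a": -0.3,
        "T1b": -0.2,
        "T1c": 0.0,
        "T2": 0.25,
        "T3": 0.5,
        "T4": 0.7,
    }
    n_shift = {"N0": 0.0, "N1mi": 0.1, "N1": 0.2, "N2": 0.35, "N3": 0.5}
    rows = []
    for t in T_CATEGORIES:
        for n in N_CATEGORIES:
            for m in ["M0", "M1"]:
                for ag in AGE_GROUPS:
                    for brca in ["none", "carrier"]:
                        for hrt in ["never", "ever"]:
                            p_er = 0.30 if brca == "carrier" else 0.80
                            p_her2 = 0.10 if brca == "carrier" else 0.15
                            shift = t_grade_shift[t] + n_shift[n]
                            shift += 0.6 if brca == "carrier" else 0.0
                            shift += -0.2 if hrt == "ever" else 0.0
                            shift += 0.3 if m == "M1" else 0.0
                            # grade logits around a moving centre
                            w = np.exp([-(shift), 0.4, shift])
                            g = w / w.sum()
                            for er, p1 in (("pos", p_er), ("neg", 1 - p_er)):
                                for her2, p2 in (("pos", p_her2), ("neg", 1 - p_her2)):
                                    for gi in range(3):
                                        rows.append(
                                            (t, n, m, ag, brca, hrt, er, her2, gi + 1, p1 * p2 * g[gi])
                                        )
    return pd.DataFrame(
        rows,
        columns=["t", "n", "m", "age_group", "brca", "hrt", "er_pr", "her2", "grade", "prob"],
    )


def _n_distribution() -> pd.DataFrame:
    """P(N category | simulated node count N*, T).

    Toy mapping: the nodal category tracks the latent count with modest
    misclassification; Tis is always N0 (no nodal spread for in-situ
    lesions in-model).
    """
    nstar_bins = [(0, 1), (1, 4), (4, 10), (10, 1000)]
    base = {
        (0, 1): {"N0": 0.92, "N1mi": 0.05, "N1": 0.03, "N2": 0.0, "N3": 0.0},
        (1, 4): {"N0": 0.10, "N1mi": 0.15, "N1": 0.65, "N2": 0.10, "N3": 0.0},
        (4, 10): {"N0": 0.02, "N1mi": 0.03, "N1": 0.25, "N2": 0.60, "N3": 0.10},
        (10, 1000): {"N0": 0.0, "N1mi": 0.0, "N1": 0.05, "N2": 0.25, "N3": 0.70},
    }
    rows = []
    for t in T_CATEGORIES:
        for lo, hi in nstar_bins:
            if t == "Tis":
                dist = {"N0": 1.0, "N1mi": 0.0, "N1": 0.0, "N2": 0.0, "N3": 0.0}
            else:
                dist = base[(lo, hi)]
            for cat in N_CATEGORIES:
                rows.append((lo, hi, t, cat, dist[cat]))
    return pd.DataFrame(rows, columns=["nstar_lo", "nstar_hi", "t", "n_category", "prob"])


_SIZE_BINS = [(0.0, 1.0), (1.0, 2.0), (2.0, 5.0), (5.0, 1000.0)]
_NODE_BINS = [(0, 1), (1, 4), (4, 10), (10, 100000)]


def _k_table() -> pd.DataFrame:
    """Annual metastasis hazard lookup by size class x positive-node class."""
    k = np.array(
        [
            [0.001, 0.004, 0.010, 0.030],
            [0.004, 0.012, 0.030, 0.070],
            [0.012, 0.030, 0.070, 0.150],
            [0.030, 0.070, 0.150, 0.300],
        ]
    )
    rows = []
    for i, (slo, shi) in enumerate(_SIZE_BINS):
        for j, (nlo, nhi) in enumerate(_NODE_BINS):
            rows.append((slo, shi, nlo, nhi, k[i, j]))
    return pd.DataFrame(rows, columns=["size_lo", "size_hi", "nodes_lo", "nodes_hi", "k"])


def _t4_model() -> pd.DataFrame:
    """P(T4 | size T*, node count N*): rises with both."""
    p = np.array(
        [
            [0.000, 0.002, 0.005, 0.02],
            [0.002, 0.005, 0.015, 0.05],
            [0.010, 0.030, 0.060, 0.12],
            [0.060, 0.120, 0.200, 0.35],
        ]
    )
    rows = []
    for i, (slo, shi) in enumerate(_SIZE_BINS):
        for j, (nlo, nhi) in enumerate(_NODE_BINS):
            rows.append((slo, shi, nlo, nhi, p[i, j]))
    return pd.DataFrame(rows, columns=["size_lo", "size_hi", "nodes_lo", "nodes_hi", "p_t4"])


def _progression() -> pd.DataFrame:
    """Weibull AFT transition models with log-scale covariate coefficients.

    ``scale`` is the baseline Weibull scale in years for a clinically
    detected stage I, grade 2, ER/PR-positive, HER2-negative woman aged
    50-69; coefficients multiply the scale through exp(beta * x).
    ``plateau`` is the fraction for whom the transition never fires.
    """
    cols = [
        "transition",
        "shape",
        "scale",
        "plateau",
        "stage_0",
        "stage_II",
        "stage_III",
        "stage_IV",
        "age_lt50",
        "age_ge70",
        "grade_1",
        "grade_3",
        "er_pr_neg",
        "her2_pos",
        "screen_detected",
    ]
    rows = [
        ("diagnosis_to_local", 1.30, 30.0, 0.70, 1.2, -0.5, -0.9, -1.2, -0.1, 0.0, 0.2, -0.3, -0.2, -0.1, 0.10),
        ("diagnosis_to_distant", 1.20, 28.0, 0.55, 1.8, -0.8, -1.5, 0.0, -0.1, 0.0, 0.3, -0.4, -0.3, -0.1, 0.15),
        ("local_to_distant", 1.10, 8.0, 0.30, 1.0, -0.4, -0.8, 0.0, 0.0, 0.0, 0.2, -0.3, -0.2, -0.1, 0.05),
        ("diagnosis_to_bc_death", 1.40, 45.0, 0.00, 1.5, -0.7, -1.4, -2.6, 0.0, -0.2, 0.2, -0.4, -0.3, -0.1, 0.10),
        ("distant_to_bc_death", 1.10, 3.0, 0.00, 0.5, -0.1, -0.2, -0.4, 0.0, -0.1, 0.1, -0.2, -0.1, -0.1, 0.05),
    ]
    return pd.DataFrame(rows, columns=cols)


def _sensitivity() -> pd.DataFrame:
    """Mammography sensitivity by tumour size x age group x screen sequence."""
    size_bins = [(0.0, 0.5), (0.5, 1.0), (1.0, 2.0), (2.0, 5.0), (5.0, 1000.0)]
    base = [0.30, 0.55, 0.75, 0.90, 0.95]
    age_bins = [(0, 50, -0.05), (50, 70, 0.0), (70, 200, 0.02)]
    rows = []
    for (slo, shi), s in zip(size_bins, base):
        for alo, ahi, adj in age_bins:
            for seq, sadj in (("first", 0.0), ("subsequent", -0.02)):
                rows.append((slo, shi, alo, ahi, seq, float(np.clip(s + adj + sadj, 0, 1))))
    return pd.DataFrame(
        rows, columns=["size_lo", "size_hi", "age_lo", "age_hi", "sequence", "sensitivity"]
    )


def default_parameters() -> ParameterSet:
    """Build the shipped toy-default :class:`ParameterSet` (non-calibrated)."""
    constants = pd.DataFrame(
        {
            "name": [
                "d0",
                "dmax_floor",
                "brca_alpha_multiplier",
                "terminal_window_years",
                "discount_rate",
                "max_age",
            ],
            "value": [0.2, 0.5, 1.5, 1.0, 0.0, float(MAX_AGE)],
        }
    )
    prevalence = pd.DataFrame(
        {
            "key": [
                "brca",
                "family_history",
                "hrt_ever",
                "hrt_start_mean",
                "hrt_start_sd",
                "hrt_duration_mean",
            ],
            "value": [0.003, 0.12, 0.25, 50.0, 3.0, 5.0],
        }
    )
    rrs = pd.DataFrame(
        {
            "factor": ["brca", "family_history", "hrt_current", "hrt_past", "prior_dcis_invasive"],
            "rr": [8.0, 1.8, 1.3, 1.1, 2.0],
        }
    )
    node_spread = pd.DataFrame(
        [[0.05, 0.01, 0.5, 0.7, 0.35]],
        columns=["b1", "b2", "b3", "mu_n_mean", "mu_n_var"],
    )
    metastasis = pd.DataFrame([[1.0, 0.5]], columns=["mu_m_mean", "mu_m_var"])
    detection_hazard = pd.DataFrame(
        {
            "size_cm": [0.2, 0.5, 1.0, 2.0, 3.0, 5.0, 8.0],
            "hazard": [0.01, 0.03, 0.08, 0.25, 0.60, 1.50, 4.00],
        }
    )
    specificity = pd.DataFrame(
        {"age_lo": [0, 50, 70], "age_hi": [50, 70, 200], "specificity": [0.93, 0.95, 0.96]}
    )
    unit_costs = pd.DataFrame({"item": ["screen", "workup"], "cost": [100.0, 850.0]})
    phase_rows = []
    initial = {"0": 15000.0, "I": 30000.0, "II": 45000.0, "III": 60000.0, "IV": 80000.0}
    continuing = {"0": 1000.0, "I": 2000.0, "II": 2500.0, "III": 3500.0, "IV": 20000.0}
    terminal = {s: 60000.0 for s in initial}
    for stage in initial:
        phase_rows.append((stage, "initial", initial[stage]))
        phase_rows.append((stage, "continuing", continuing[stage]))
        phase_rows.append((stage, "terminal", terminal[stage]))
    phase_costs = pd.DataFrame(phase_rows, columns=["stage", "phase", "annual_cost"])
    pop_util = pd.DataFrame(
        {
            "age_lo": [0, 20, 40, 60, 80],
            "age_hi": [20, 40, 60, 80, 200],
            "score": [1.0, 0.95, 0.90, 0.83, 0.75],
        }
    )
    state_util = pd.DataFrame(
        {
            "state": [
                "initial_0",
                "initial_I",
                "initial_II",
                "initial_III",
                "initial_IV",
                "continuing",
                "local_recurrence",
                "distant_recurrence",
                "terminal",
            ],
            "utility": [0.90, 0.85, 0.82, 0.78, 0.70, 0.95, 0.80, 0.60, 0.50],
        }
    )

    return ParameterSet(
        life_table=_life_table(),
        onset_rates=_onset_rates(),
        risk_factor_prevalence=prevalence,
        risk_relative_risks=rrs,
        growth_params=_growth_params(),
        constants=constants,
        node_spread=node_spread,
        metastasis=metastasis,
        k_table=_k_table(),
        detection_hazard=detection_hazard,
        t4_model=_t4_model(),
        n_distribution=_n_distribution(),
        biology=_biology(),
        progression=_progression(),
        sensitivity=_sensitivity(),
        specificity=specificity,
        unit_costs=unit_costs,
        phase_costs=phase_costs,
        population_utilities=pop_util,
        state_utilities=state_util,
        source=None,
    )
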