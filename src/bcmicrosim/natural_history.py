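"""Latent tumour biology: onset, Gompertz growth, nodal spread, metastasis.

Everything in this module is detection-independent: a woman's tumour
burden is simulated once, from her natural-history random stream, and is
identical whether or not she is ever screened.  Detection layers only
observe (and truncate) this latent trajectory.

Model components
----------------
* Occult onset: nonhomogeneous Poisson processes (one per tumour type,
  DCIS and invasive) with age- and calendar-dependent base rates scaled by
  multiplicative risk-factor relative risks.  A prior (pre-invasive) DCIS
  raises the invasive onset rate; once a woman has an invasive tumour,
  later DCIS lesions are flagged non-transforming.
* Growth: Gompertz diameter curve d(t) = d0 * (dmax/d0)^(1 - exp(-a*t)),
  starting from the 2 mm occult-onset size and saturating at dmax.
* Nodal spread (invasive only): NHPP with intensity
  lambda(t) = mu_N * {b1 + b2*V(t) + b3*V'(t)} where V is the spherical
  tumour volume; mu_N is gamma-heterogeneous across tumours.
* Metastasis (invasive only): hazard mu_M * k(size class, node class),
  summed over a woman's invasive tumours; mu_M gamma-heterogeneous.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import _tables
from .params import ParameterSet
from .population import Individual

__all__ = [
    "Tumour",
    "NaturalHistory",
    "onset_rate",
    "sample_onsets",
    "sample_tumour",
    "diameter",
    "diameter_derivative",
    "volume",
    "volume_derivative",
    "inverse_diameter",
    "node_intensity",
    "sample_nodes",
    "metastasis_hazard",
    "sample_metastasis_age",
    "sample_first_event",
    "simulate_natural_history",
]


@dataclasses.dataclass
class Tumour:
    """One DCIS or invasive lesion with its growth and spread propensities."""

    tumour_type: str  # "dcis" | "invasive"
    onset_age: float
    alpha: float  # Gompertz growth rate, per year
    dmax: float  # saturating diameter, cm
    d0: float  # diameter at occult onset, cm
    mu_N: float  # nodal-spread propensity (0 for DCIS)
    mu_M: float  # metastasis propensity (0 for DCIS)
    aggressiveness_class: str = "intermediate"
    node_event_ages: np.ndarray = dataclasses.field(default_factory=lambda: np.empty(0))
    non_transforming: bool = False  # DCIS arising after a first invasive tumour

    def __post_init__(self):
        if self.d0 <= 0:
            raise ValueError("onset diameter d0 must be positive")
        if self.dmax <= self.d0:
            raise ValueError("dmax must exceed d0")
        if self.alpha <= 0:
            raise ValueError("growth rate alpha must be positive")
        if self.mu_N < 0 or self.mu_M < 0:
            raise ValueError("spread propensities must be non-negative")

    @property
    def invasive(self) -> bool:
        return self.tumour_type == "invasive"

    def nodes_at(self, age: float) -> int:
        """Number of positive nodes acquired by ``age``."""
        return int(np.searchsorted(self.node_event_ages, age, side="right"))


@dataclasses.dataclass
class NaturalHistory:
    """The full latent record for one woman."""

    tumours: list[Tumour]
    metastasis_age: float | None = None
    counterfactual_clinical_detection_age: float | None = None
    clinical_leading_index: int | None = None  # tumour whose detection fired

    @property
    def invasive_tumours(self) -> list[Tumour]:
        return [t for t in self.tumours if t.invasive]


# ---------------------------------------------------------------------------
# Growth geometry (closed forms)


def diameter(t: Tumour, age: float) -> float:
    """Tumour diameter in cm at a given age (Gompertz growth curve)."""
    tau = age - t.onset_age
    if tau < 0:
        raise ValueError("cannot evaluate diameter before tumour onset")
    return t.d0 * (t.dmax / t.d0) ** (1.0 - math.exp(-t.alpha * tau))


def diameter_derivative(t: Tumour, age: float) -> float:
    """d'(t) in cm/year."""
    tau = age - t.onset_age
    if tau < 0:
        raise ValueError("cannot evaluate growth rate before tumour onset")
    d = diameter(t, age)
    return d * math.log(t.dmax / t.d0) * t.alpha * math.exp(-t.alpha * tau)


def inverse_diameter(t: Tumour, d: float) -> float:
    """Age at which the tumour reaches diameter ``d`` (inf if d >= dmax)."""
    if d <= t.d0:
        return t.onset_age
    if d >= t.dmax:
        return math.inf
    frac = math.log(d / t.d0) / math.log(t.dmax / t.d0)
    return t.onset_age - math.log(1.0 - frac) / t.alpha


def volume(d: float) -> float:
    """Volume of a spherical tumour of diameter d (cm^3)."""
    if d < 0:
        raise ValueError("diameter must be non-negative")
    return math.pi * d**3 / 6.0


def volume_derivative(t: Tumour, age: float) -> float:
    """V'(t) in cm^3/year by the chain rule from the Gompertz diameter."""
    d = diameter(t, age)
    return math.pi / 2.0 * d**2 * diameter_derivative(t, age)


# ---------------------------------------------------------------------------
# Onset


def onset_rate(
    p: ParameterSet,
    ind: Individual,
    age: float,
    year: float,
    history: dict | None = None,
) -> dict[str, float]:
    """Occult onset rate per woman-year for each tumour type at (age, year).

    Base table rate times the product of the applicable relative risks
    (multiplicative combination): BRCA carriage, family history, HRT
    exposure status at this age, and — for the invasive process — a prior
    transforming DCIS.
    """
    history = history or {}
    rr_common = 1.0
    if ind.brca == "carrier":
        rr_common *= p.relative_risk("brca")
    if ind.family_history:
        rr_common *= p.relative_risk("family_history")
    status = ind.hrt_status_at(age)
    if status == "current":
        rr_common *= p.relative_risk("hrt_current")
    elif status == "past":
        rr_common *= p.relative_risk("hrt_past")

    out = {}
    for ttype in ("dcis", "invasive"):
        base = _tables.lookup_onset_rate(p.onset_rates, age, year, ttype)
        rr = rr_common
        if ttype == "invasive" and history.get("had_dcis", False):
            rr *= p.relative_risk("prior_dcis_invasive")
        out[ttype] = base * rr
    return out


def _max_relative_risk(p: ParameterSet, ind: Individual) -> float:
    """Upper bound on a woman's lifetime RR product (for thinning)."""
    rr = 1.0
    if ind.brca == "carrier":
        rr *= p.relative_risk("brca")
    if ind.family_history:
        rr *= p.relative_risk("family_history")
    if ind.hrt_ever:
        rr *= max(p.relative_risk("hrt_current"), p.relative_risk("hrt_past"), 1.0)
    return rr


def sample_onsets(
    p: ParameterSet, ind: Individual, rng: np.random.Generator
) -> list[tuple[float, str]]:
    """Draw tumour onset ages over a woman's lifespan by NHPP thinning.

    The DCIS and invasive processes run jointly against a dominating
    constant rate; history dependence (prior-DCIS relative risk on the
    invasive process) is applied through the thinning acceptance
    probability, so the two processes are independent except through the
    declared relative risks.
    """
    horizon = ind.other_cause_death_age
    rr_max = _max_relative_risk(p, ind)
    rr_dcis = p.relative_risk("prior_dcis_invasive")
    base_max = {
        t: _tables.max_onset_rate(p.onset_rates, t) for t in ("dcis", "invasive")
    }
    lam_dcis = base_max["dcis"] * rr_max
    lam_inv = base_max["invasive"] * rr_max * max(rr_dcis, 1.0)
    lam_tot = lam_dcis + lam_inv
    events: list[tuple[float, str]] = []
    if lam_tot <= 0:
        return events

    had_dcis = False  # a transforming DCIS (before any invasive tumour)
    had_invasive = False
    t = 0.0
    while True:
        t += rng.exponential(1.0 / lam_tot)
        if t >= horizon:
            break
        ttype = "dcis" if rng.uniform() < lam_dcis / lam_tot else "invasive"
        history = {"had_dcis": had_dcis, "had_invasive": had_invasive}
        rate = onset_rate(p, ind, t, ind.birth_year + t, history)[ttype]
        bound = lam_dcis if ttype == "dcis" else lam_inv
        if rate > bound * (1 + 1e-12):
            raise AssertionError(
                f"thinning bound violated: rate {rate} > dominating {bound}"
            )
        if rng.uniform() < rate / bound:
            events.append((t, ttype))
            if ttype == "invasive":
                had_invasive = True
            elif not had_invasive:
                had_dcis = True
    return events


def _gamma_draw(mean: float, var: float, rng: np.random.Generator) -> float:
    """Gamma draw parameterised by mean/variance; degenerate when var = 0."""
    if mean <= 0:
        return 0.0
    if var <= 0:
        return mean
    shape = mean * mean / var
    scale = var / mean
    return float(rng.gamma(shape, scale))


def sample_tumour(
    p: ParameterSet,
    ind: Individual,
    onset_age: float,
    tumour_type: str,
    rng: np.random.Generator,
    *,
    non_transforming: bool = False,
) -> Tumour:
    """Draw a tumour's growth coefficients and spread propensities at onset.

    The aggressiveness class is a mixture draw; (alpha, dmax) are lognormal
    within class.  BRCA carriers grow faster via a multiplier on alpha.
    mu_N and mu_M are gamma draws (mean/variance parameterisation), made
    once per tumour to give persistent heterogeneity.
    """
    mixture = _tables.growth_mixture(p.growth_params)
    if tumour_type not in mixture:
        raise ValueError(f"no growth parameters for tumour type {tumour_type!r}")
    props, rows = mixture[tumour_type]
    row = rows[int(rng.choice(len(rows), p=props))]
    alpha = float(np.exp(rng.normal(row["log_alpha_mean"], row["log_alpha_sd"])))
    if ind.brca == "carrier":
        alpha *= p.constant("brca_alpha_multiplier")
    d0 = p.constant("d0")
    dmax = float(np.exp(rng.normal(row["log_dmax_mean"], row["log_dmax_sd"])))
    dmax = max(dmax, p.constant("dmax_floor"))
    ns = _tables.single_row(p.node_spread)
    met = _tables.single_row(p.metastasis)
    if tumour_type == "invasive":
        mu_N = _gamma_draw(float(ns["mu_n_mean"]), float(ns["mu_n_var"]), rng)
        mu_M = _gamma_draw(float(met["mu_m_mean"]), float(met["mu_m_var"]), rng)
    else:
        mu_N = 0.0
        mu_M = 0.0
    return Tumour(
        tumour_type=tumour_type,
        onset_age=onset_age,
        alpha=alpha,
        dmax=dmax,
        d0=d0,
        mu_N=mu_N,
        mu_M=mu_M,
        aggressiveness_class=str(row["aggressiveness_class"]),
        non_transforming=non_transforming,
    )


# ---------------------------------------------------------------------------
# Nodal spread


def node_intensity(p: ParameterSet, t: Tumour, age: float) -> float:
    """Positive-node acquisition intensity lambda(t), per year.

    lambda = mu_N * (b1 + b2*V + b3*V'), clamped at zero so the intensity
    is always a valid Poisson rate even for unconstrained coefficients.
    Defined for invasive tumours only: in-situ lesions do not seed nodes.
    """
    if not t.invasive:
        raise ValueError("nodal spread applies to invasive tumours only")
    ns = _tables.single_row(p.node_spread)
    d = diameter(t, age)
    lam = t.mu_N * (ns["b1"] + ns["b2"] * volume(d) + ns["b3"] * volume_derivative(t, age))
    return max(lam, 0.0)


def sample_nodes(
    p: ParameterSet, t: Tumour, until: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw positive-node acquisition ages on [onset, until] by thinning.

    The dominating constant uses the saturating volume and the gridded
    maximum of V' (V' is unimodal); the count is unbounded.
    """
    if until < t.onset_age:
        raise ValueError("node sampling window ends before tumour onset")
    if until == t.onset_age or t.mu_N <= 0:
        return np.empty(0)
    ns = _tables.single_row(p.node_spread)
    b1, b2, b3 = ns["b1"], ns["b2"], ns["b3"]
    taus = np.linspace(0.0, until - t.onset_age, 256)
    d = t.d0 * (t.dmax / t.d0) ** (1.0 - np.exp(-t.alpha * taus))
    dprime = d * math.log(t.dmax / t.d0) * t.alpha * np.exp(-t.alpha * taus)
    vprime_max = float(np.max(math.pi / 2.0 * d**2 * dprime))
    lam_max = t.mu_N * max(b1 + b2 * volume(t.dmax) + b3 * vprime_max * 1.25, 0.0)
    if lam_max <= 0:
        return np.empty(0)
    ages = []
    a = t.onset_age
    while True:
        a += rng.exponential(1.0 / lam_max)
        if a >= until:
            break
        lam = node_intensity(p, t, a)
        if lam > lam_max * (1 + 1e-9):
            raise AssertionError("node thinning bound violated")
        if rng.uniform() < lam / lam_max:
            ages.append(a)
    return np.asarray(ages)


# ---------------------------------------------------------------------------
# Metastasis


def metastasis_hazard(p: ParameterSet, tumours: list[Tumour], age: float) -> float:
    """Total annual metastasis hazard at ``age``: sum over invasive tumours
    of mu_M * k(size class, positive-node class).  DCIS contributes zero."""
    total = 0.0
    for t in tumours:
        if not t.invasive or age < t.onset_age:
            continue
        d = diameter(t, age)
        k = _tables.lookup_bin2d(p.k_table, d, t.nodes_at(age), "k")
        total += t.mu_M * k
    return total


def _metastasis_breakpoints(p: ParameterSet, t: Tumour, t0: float, t1: float) -> list[float]:
    """Ages in (t0, t1) where this tumour's k-lookup can change value."""
    pts = []
    for edge in sorted(set(p.k_table["size_lo"]).union(p.k_table["size_hi"])):
        if edge <= 0 or not np.isfinite(edge):
            continue
        a = inverse_diameter(t, float(edge))
        if t0 < a < t1:
            pts.append(a)
    for a in t.node_event_ages:
        if t0 < a < t1:
            pts.append(float(a))
    return pts


def sample_metastasis_age(
    p: ParameterSet,
    nh: NaturalHistory,
    until: float,
    rng: np.random.Generator,
) -> float | None:
    """First-event draw from the woman-level metastasis hazard.

    The total hazard is piecewise constant between size-class crossings and
    node events, so the cumulative hazard is piecewise linear and the
    inversion is exact (no quadrature error).
    """
    invasive = [t for t in nh.tumours if t.invasive and t.onset_age < until]
    if not invasive:
        return None
    start = min(t.onset_age for t in invasive)
    breaks = {start, until}
    for t in invasive:
        breaks.add(min(t.onset_age, until))
        breaks.update(_metastasis_breakpoints(p, t, start, until))
    grid = sorted(breaks)
    target = rng.exponential()
    cum = 0.0
    for a0, a1 in zip(grid[:-1], grid[1:]):
        mid = 0.5 * (a0 + a1)
        h = metastasis_hazard(p, nh.tumours, mid)
        seg = h * (a1 - a0)
        if cum + seg >= target:
            return a0 + (target - cum) / h
        cum += seg
    return None


# ---------------------------------------------------------------------------
# Generic first-event sampling for smooth hazards


def sample_first_event(
    hazard_fn,
    t0: float,
    t1: float,
    rng: np.random.Generator,
    *,
    grid_step: float = 0.02,
) -> float | None:
    """Draw the first event time of a nonhomogeneous process on [t0, t1].

    Inverts the cumulative hazard against a unit-exponential draw.  The
    hazard is evaluated on a uniform grid and treated as piecewise linear
    between grid points, so the within-segment inversion is the exact root
    of a quadratic; constant and linear hazards are sampled exactly, and
    smooth hazards to O(grid_step^2).  ``hazard_fn`` must accept an array
    of times and return non-negative rates.
    """
    if t1 <= t0:
        return None
    n = max(int(math.ceil((t1 - t0) / grid_step)) + 1, 2)
    n = min(n, 20001)
    grid = np.linspace(t0, t1, n)
    h = np.asarray(hazard_fn(grid), dtype=float)
    if np.any(h < -1e-12):
        raise ValueError("hazard function returned a negative rate")
    h = np.clip(h, 0.0, None)
    dt = grid[1] - grid[0]
    seg = 0.5 * (h[:-1] + h[1:]) * dt  # trapezoid per segment
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    target = rng.exponential()
    if target > cum[-1]:
        return None
    i = int(np.searchsorted(cum, target, side="left")) - 1
    i = max(i, 0)
    rem = target - cum[i]
    h0, h1 = h[i], h[i + 1]
    slope = (h1 - h0) / dt
    # solve h0*x + slope*x^2/2 = rem for x in [0, dt]
    if abs(slope) < 1e-14:
        x = rem / h0 if h0 > 0 else dt
    else:
        disc = h0 * h0 + 2.0 * slope * rem
        x = (-h0 + math.sqrt(max(disc, 0.0))) / slope
    x = min(max(x, 0.0), dt)
    return float(grid[i] + x)


# ---------------------------------------------------------------------------
# Per-woman assembly


def simulate_natural_history(
    p: ParameterSet, ind: Individual, rng: np.random.Generator
) -> NaturalHistory:
    """Simulate a woman's full latent tumour burden from one stream.

    Order of draws is fixed (onsets, per-tumour coefficients, the
    counterfactual clinical-detection age, node events, metastasis), so a
    given (seed, id) always reproduces the identical history, in any
    scenario.  Node and metastasis processes are only simulated up to the
    counterfactual clinical detection (or death): past that point the
    woman is in the observed-disease pathway and the progression layer
    takes over.
    """
    from .detection import sample_clinical_detection_age  # avoid import cycle

    onsets = sample_onsets(p, ind, rng)
    tumours: list[Tumour] = []
    had_invasive = False
    for onset_age, ttype in onsets:
        tumours.append(
            sample_tumour(
                p,
                ind,
                onset_age,
                ttype,
                rng,
                non_transforming=(ttype == "dcis" and had_invasive),
            )
        )
        if ttype == "invasive":
            had_invasive = True
    nh = NaturalHistory(tumours=tumours)
    if not tumours:
        return nh

    death = ind.other_cause_death_age
    clin_age, leading = sample_clinical_detection_age(
        p, tumours, until=death, rng=rng, return_leading=True
    )
    nh.counterfactual_clinical_detection_age = clin_age
    nh.clinical_leading_index = leading
    horizon = min(death, clin_age) if clin_age is not None else death
    for t in tumours:
        if t.invasive and t.onset_age < horizon:
            t.node_event_ages = sample_nodes(p, t, horizon, rng)
    nh.metastasis_age = sample_metastasis_age(p, nh, horizon, rng)
    return nh
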