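"""Cancer detection and AJCC staging.

Clinical detection is a woman-level hazard: the sum over her tumours of a
size-dependent detection hazard, linearly interpolated between size knots.
The first-event draw from this hazard defines the *counterfactual*
clinical detection age stored in the natural history — the age at which
the cancer would surface without screening — which screening later uses
to account lead time and overdetection.

At detection (clinical or screen) the latent size T* and node count N* of
the leading tumour are converted to AJCC T, N, M categories and an
anatomic stage group, and the tumour biology triple (hormone-receptor
status, HER2, grade) is drawn from the registry-style joint distribution
for the stratum.  Biology is assigned only at detection and does not feed
back into the natural history.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _tables
from .natural_history import NaturalHistory, Tumour, diameter, sample_first_event
from .params import ParameterSet

__all__ = [
    "DetectedCancer",
    "clinical_detection_hazard",
    "sample_clinical_detection_age",
    "assign_T",
    "assign_N",
    "stage_group",
    "assign_biology",
    "build_detected_cancer",
]

T_SIZE_BANDS = [(0.5, "T1a"), (1.0, "T1b"), (2.0, "T1c"), (5.0, "T2")]  # then T3


@dataclasses.dataclass
class DetectedCancer:
    detection_age: float
    mode: str  # "clinical" | "screen"
    leading_tumour: Tumour
    size_at_detection: float  # T*, cm
    nodes_at_detection: int  # N*
    metastatic: bool
    T: str
    N: str
    M: str
    stage: str  # "0" | "I" | "II" | "III" | "IV"
    er_pr: str
    her2: str
    grade: int


def _per_tumour_hazards(p: ParameterSet, tumours: list[Tumour], age: float) -> np.ndarray:
    knot_xs, knot_ys = _tables.detection_knots(p.detection_hazard)
    out = np.zeros(len(tumours))
    for i, t in enumerate(tumours):
        if age >= t.onset_age:
            out[i] = np.interp(diameter(t, age), knot_xs, knot_ys)
    return out


def clinical_detection_hazard(p: ParameterSet, tumours: list[Tumour], age: float) -> float:
    """Woman-level clinical detection hazard: sum over tumours present."""
    if not tumours:
        return 0.0
    return float(_per_tumour_hazards(p, tumours, age).sum())


def sample_clinical_detection_age(
    p: ParameterSet,
    tumours: list[Tumour],
    until: float,
    rng: np.random.Generator,
    *,
    return_leading: bool = False,
):
    """First-event draw of the clinical detection age; None if never.

    The leading tumour — the one whose detection event fired — is drawn
    with probability proportional to each tumour's hazard share at the
    detection age.
    """
    if not tumours:
        return (None, None) if return_leading else None
    t0 = min(t.onset_age for t in tumours)
    if until <= t0:
        return (None, None) if return_leading else None

    knot_xs, knot_ys = _tables.detection_knots(p.detection_hazard)

    def total_hazard(ages: np.ndarray) -> np.ndarray:
        out = np.zeros_like(ages, dtype=float)
        for t in tumours:
            tau = ages - t.onset_age
            live = tau >= 0
            d = t.d0 * (t.dmax / t.d0) ** (1.0 - np.exp(-t.alpha * np.maximum(tau, 0.0)))
            out += np.where(live, np.interp(d, knot_xs, knot_ys), 0.0)
        return out

    age = sample_first_event(total_hazard, t0, until, rng)
    if age is None:
        return (None, None) if return_leading else None
    if not return_leading:
        return age
    shares = _per_tumour_hazards(p, tumours, age)
    tot = shares.sum()
    if tot <= 0:  # numerically degenerate; fall back to largest tumour
        leading = int(np.argmax([diameter(t, age) if age >= t.onset_age else 0 for t in tumours]))
    else:
        leading = int(rng.choice(len(tumours), p=shares / tot))
    return age, leading


# ---------------------------------------------------------------------------
# TNM assignment


def assign_T(
    p: ParameterSet, size: float, nodes: int, tumour_type: str, rng: np.random.Generator
) -> str:
    """AJCC T category from latent size T* and node count N*.

    In-situ lesions are Tis.  Invasive tumours are first tested for T4
    (chest-wall/skin extension, probability rising with T* and N*); non-T4
    tumours map through the AJCC size bands, with a T1a floor for sizes at
    or below 0.5 cm.
    """
    if size <= 0:
        raise ValueError("tumour size must be positive at detection")
    if tumour_type == "dcis":
        return "Tis"
    p_t4 = _tables.lookup_bin2d(p.t4_model, size, nodes, "p_t4")
    if rng.uniform() < p_t4:
        return "T4"
    for hi, cat in T_SIZE_BANDS:
        if size <= hi:
            return cat
    return "T3"


def assign_N(p: ParameterSet, nstar: int, T: str, rng: np.random.Generator) -> str:
    """Draw the AJCC N category given the latent node count N* and T."""
    rows = _tables.n_distribution_rows(p.n_distribution)
    candidates = [(lo, hi) for (lo, hi, t) in rows if t == T]
    if not candidates:
        raise ValueError(f"n_distribution has no rows for N*={nstar}, T={T}")
    match = [(lo, hi) for lo, hi in candidates if lo <= nstar < hi]
    if match:
        lo, hi = match[0]
    else:  # clamp into the top N* bin for counts beyond the table
        lo, hi = max(candidates, key=lambda b: b[1])
    cats, probs = rows[(lo, hi, T)]
    return str(rng.choice(cats, p=probs / probs.sum()))


_T1 = {"T1a", "T1b", "T1c"}


def stage_group(T: str, N: str, M: str) -> str:
    """AJCC anatomic stage group (7th-edition style), collapsed to 0-IV."""
    valid_T = {"Tis", "T4", "T2", "T3"} | _T1
    if T not in valid_T or N not in {"N0", "N1mi", "N1", "N2", "N3"} or M not in {"M0", "M1"}:
        raise ValueError(f"invalid TNM combination ({T},{N},{M})")
    if M == "M1":
        if T == "Tis":
            raise ValueError("in-situ disease cannot be metastatic")
        return "IV"
    if T == "Tis":
        if N != "N0":
            raise ValueError("Tis requires N0")
        return "0"
    if N == "N3":
        return "III"
    if T in _T1:
        return {"N0": "I", "N1mi": "I", "N1": "II", "N2": "III"}[N]
    if T == "T2":
        return {"N0": "II", "N1mi": "II", "N1": "II", "N2": "III"}[N]
    if T == "T3":
        return {"N0": "II", "N1mi": "III", "N1": "III", "N2": "III"}[N]
    return "III"  # T4, M0, N0-N2


def assign_biology(
    p: ParameterSet,
    T: str,
    N: str,
    M: str,
    age: float,
    brca: str,
    hrt_ever: bool,
    rng: np.random.Generator,
) -> tuple[str, str, int]:
    """Single joint draw of (ER/PR, HER2, grade) for the detection stratum."""
    strata = _tables.biology_strata(p.biology)
    key = (T, N, M, _tables.age_group(age), brca, "ever" if hrt_ever else "never")
    if key not in strata:
        raise ValueError(
            f"biology distribution missing stratum (T={T}, N={N}, M={M}, "
            f"age group {_tables.age_group(age)}, brca={brca}, hrt={hrt_ever})"
        )
    er_pr, her2, grade, probs = strata[key]
    idx = int(rng.choice(len(probs), p=probs / probs.sum()))
    return str(er_pr[idx]), str(her2[idx]), int(grade[idx])


def build_detected_cancer(
    p: ParameterSet,
    nh: NaturalHistory,
    ind,
    detection_age: float,
    mode: str,
    rng: np.random.Generator,
    leading_index: int | None = None,
) -> DetectedCancer:
    """Assemble the detected-cancer record at a detection event.

    ``leading_index`` names the tumour whose detection fired (clinical) or
    the largest screen-detected tumour.  If the woman is metastatic at
    detection the leading tumour must be invasive (metastases originate
    from invasive disease), so an in-situ leading lesion is replaced by
    the largest invasive tumour.
    """
    present = [t for t in nh.tumours if t.onset_age <= detection_age]
    if not present:
        raise ValueError("detection before any tumour onset")
    if leading_index is None:
        leading_index = int(
            np.argmax(
                [diameter(t, detection_age) if t.onset_age <= detection_age else -1.0 for t in nh.tumours]
            )
        )
    leading = nh.tumours[leading_index]
    metastatic = nh.metastasis_age is not None and nh.metastasis_age <= detection_age
    if metastatic and not leading.invasive:
        inv = [
            (diameter(t, detection_age), i)
            for i, t in enumerate(nh.tumours)
            if t.invasive and t.onset_age <= detection_age
        ]
        if inv:
            leading_index = max(inv)[1]
            leading = nh.tumours[leading_index]
    size = diameter(leading, detection_age)
    nstar = leading.nodes_at(detection_age) if leading.invasive else 0
    T = assign_T(p, size, nstar, leading.tumour_type, rng)
    N = assign_N(p, nstar, T, rng) if T != "Tis" else "N0"
    M = "M1" if (metastatic and leading.invasive) else "M0"
    stage = stage_group(T, N, M)
    er_pr, her2, grade = assign_biology(
        p, T, N, M, detection_age, ind.brca, ind.hrt_ever, rng
    )
    return DetectedCancer(
        detection_age=detection_age,
        mode=mode,
        leading_tumour=leading,
        size_at_detection=size,
        nodes_at_detection=nstar,
        metastatic=(M == "M1"),
        T=T,
        N=N,
        M=M,
        stage=stage,
        er_pr=er_pr,
        her2=her2,
        grade=grade,
    )
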