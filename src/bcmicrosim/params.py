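"""Parameter tables, scenario configuration, and reproducible random streams.

All model inputs live in a :class:`ParameterSet`: plain pandas DataFrames
loaded from a directory of CSV files plus a JSON manifest.  Tables are
diff-able, language-neutral, and validated against the model's structural
invariants before any simulation runs.

Randomness is organised as counter-based named streams: every draw in the
simulator comes from ``rng_stream(master_seed, individual_id, purpose)``.
Streams for distinct purposes are statistically independent, and the
natural-history stream a woman consumes is a function of (seed, id) only —
never of the scenario — which is what makes common-random-number
counterfactual comparisons (lead time, overdetection, scenario deltas)
well defined.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParameterSet",
    "Scenario",
    "Violation",
    "PURPOSES",
    "load_parameter_set",
    "write_parameter_set",
    "validate_parameter_set",
    "rng_stream",
    "load_scenario",
]

# Fixed label set for named random streams.
PURPOSES = ("population", "natural_history", "screening", "progression", "economics")

# table name -> CSV file name
TABLE_FILES = {
    "life_table": "life_table.csv",
    "onset_rates": "onset_rates.csv",
    "risk_factor_prevalence": "risk_factor_prevalence.csv",
    "risk_relative_risks": "risk_relative_risks.csv",
    "growth_params": "growth_params.csv",
    "constants": "constants.csv",
    "node_spread": "node_spread.csv",
    "metastasis": "metastasis.csv",
    "k_table": "k_table.csv",
    "detection_hazard": "detection_hazard.csv",
    "t4_model": "t4_model.csv",
    "n_distribution": "n_distribution.csv",
    "biology": "biology.csv",
    "progression": "progression.csv",
    "sensitivity": "sensitivity.csv",
    "specificity": "specificity.csv",
    "unit_costs": "unit_costs.csv",
    "phase_costs": "phase_costs.csv",
    "population_utilities": "population_utilities.csv",
    "state_utilities": "state_utilities.csv",
}

# Tables without which the simulator cannot run at all; the rest fall back
# to the shipped toy defaults when absent from a bundle.
MANDATORY_TABLES = frozenset(
    {
        "life_table",
        "onset_rates",
        "growth_params",
        "node_spread",
        "metastasis",
        "k_table",
        "detection_hazard",
        "progression",
    }
)


@dataclasses.dataclass
class ParameterSet:
    """All model input tables.

    Every field is a tidy DataFrame; ``constants`` holds scalar knobs
    (onset diameter ``d0``, terminal-care window, discount rate, ...) as
    name/value rows.  ``source`` records where the bundle was loaded from,
    for error messages; it is ``None`` for in-memory bundles.
    """

    life_table: pd.DataFrame  # age, qx  (annual death probability)
    onset_rates: pd.DataFrame  # age_lo, age_hi, year_lo, year_hi, tumour_type, rate
    risk_factor_prevalence: pd.DataFrame  # key, value
    risk_relative_risks: pd.DataFrame  # factor, rr
    growth_params: pd.DataFrame  # type, class, proportion, lognormal moments
    constants: pd.DataFrame  # name, value
    node_spread: pd.DataFrame  # b1, b2, b3, mu_n_mean, mu_n_var
    metastasis: pd.DataFrame  # mu_m_mean, mu_m_var
    k_table: pd.DataFrame  # size_lo, size_hi, nodes_lo, nodes_hi, k
    detection_hazard: pd.DataFrame  # size_cm, hazard
    t4_model: pd.DataFrame  # size_lo, size_hi, nodes_lo, nodes_hi, p_t4
    n_distribution: pd.DataFrame  # nstar_lo, nstar_hi, t, n_category, prob
    biology: pd.DataFrame  # t, n, m, age_group, brca, hrt, er_pr, her2, grade, prob
    progression: pd.DataFrame  # transition, shape, scale, plateau, coefficients...
    sensitivity: pd.DataFrame  # size_lo, size_hi, age_lo, age_hi, sequence, sensitivity
    specificity: pd.DataFrame  # age_lo, age_hi, specificity
    unit_costs: pd.DataFrame  # item, cost
    phase_costs: pd.DataFrame  # stage, phase, annual_cost
    population_utilities: pd.DataFrame  # age_lo, age_hi, score
    state_utilities: pd.DataFrame  # state, utility
    source: Path | None = None
    _scalar_cache: dict = dataclasses.field(
        default_factory=dict, init=False, repr=False, compare=False
    )

    def _scalar(self, table: str, key_col: str, key: str, val_col: str) -> float:
        cache_key = (table, key)
        if cache_key not in self._scalar_cache:
            tab = getattr(self, table)
            row = tab.loc[tab[key_col] == key, val_col]
            if row.empty:
                raise KeyError(f"{key!r} not found in {table} table")
            self._scalar_cache[cache_key] = float(row.iloc[0])
        return self._scalar_cache[cache_key]

    def constant(self, name: str) -> float:
        return self._scalar("constants", "name", name, "value")

    def prevalence(self, key: str) -> float:
        return self._scalar("risk_factor_prevalence", "key", key, "value")

    def relative_risk(self, factor: str) -> float:
        return self._scalar("risk_relative_risks", "factor", factor, "rr")

    def tables(self):
        for name in TABLE_FILES:
            yield name, getattr(self, name)


class Violation(NamedTuple):
    """One validation failure: which table, which cell/row, which rule."""

    table: str
    cell: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.table}[{self.cell}]: {self.rule}"


@dataclasses.dataclass
class Scenario:
    """Cohort + screening strategy + horizon + seeds.

    ``screening`` is either ``None`` (no screening) or a mapping with the
    strategy fields understood by :mod:`bcmicrosim.screening`.
    """

    n: int
    birth_year_lo: int
    birth_year_hi: int
    region: str = "default"
    max_age: float = 110.0
    screening: dict | None = None
    master_seed: int = 0
    label: str = "scenario"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("scenario requires n >= 1 women")
        if self.max_age <= 0:
            raise ValueError("simulation horizon must be positive")
        if not (isinstance(self.master_seed, (int, np.integer)) and self.master_seed >= 0):
            raise ValueError("master seed must be a non-negative integer")
        if self.birth_year_hi < self.birth_year_lo:
            raise ValueError("birth_year_hi < birth_year_lo")


def load_scenario(path: str | Path) -> Scenario:
    """Read a scenario from a YAML or JSON file."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            raw = json.load(fh)
        else:
            raw = yaml.safe_load(fh)
    return Scenario(**raw)


# ---------------------------------------------------------------------------
# Loading / writing


class ParameterLoadError(RuntimeError):
    pass


def load_parameter_set(path: str | Path, *, validate: bool = True) -> ParameterSet:
    """Load a parameter bundle from a directory of CSVs.

    Mandatory tables must be present; optional tables missing from the
    bundle are filled from the shipped toy defaults (clearly non-calibrated
    placeholder values).  Raises :class:`ParameterLoadError` naming the
    offending table/file on any problem.
    """
    from . import toy  # local import: toy builds on this module

    path = Path(path)
    if not path.is_dir():
        raise ParameterLoadError(f"parameter path {path} is not a directory")

    defaults = None
    found: dict[str, pd.DataFrame] = {}
    for name, fname in TABLE_FILES.items():
        fpath = path / fname
        if not fpath.exists():
            if name in MANDATORY_TABLES:
                raise ParameterLoadError(f"{name} missing (expected file {fpath})")
            if defaults is None:
                defaults = toy.default_parameters()
            found[name] = getattr(defaults, name).copy()
            continue
        try:
            found[name] = pd.read_csv(fpath)
        except Exception as exc:  # malformed CSV
            raise ParameterLoadError(f"failed to parse {fpath}: {exc}") from exc

    p = ParameterSet(**found, source=path)
    if validate:
        violations = validate_parameter_set(p)
        if violations:
            msgs = "; ".join(str(v) for v in violations)
            raise ParameterLoadError(f"invalid parameter bundle at {path}: {msgs}")
    return p


def write_parameter_set(p: ParameterSet, path: str | Path) -> None:
    """Write a bundle as CSV files plus a manifest listing table versions."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"format": "bcmicrosim-params", "version": 1, "tables": {}}
    for name, table in p.tables():
        fname = TABLE_FILES[name]
        table.to_csv(path / fname, index=False)
        manifest["tables"][name] = {"file": fname, "rows": int(len(table))}
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


# ---------------------------------------------------------------------------
# Validation


def _check_range(
    out: list[Violation], table: pd.DataFrame, tname: str, col: str, lo=None, hi=None
) -> None:
    vals = pd.to_numeric(table[col], errors="coerce")
    for idx, v in vals.items():
        if np.isnan(v):
            out.append(Violation(tname, f"row {idx}, {col}", "non-numeric value"))
        elif lo is not None and v < lo:
            out.append(Violation(tname, f"row {idx}, {col}", f"value {v} < {lo}"))
        elif hi is not None and v > hi:
            out.append(Violation(tname, f"row {idx}, {col}", f"value {v} > {hi}"))


def validate_parameter_set(p: ParameterSet) -> list[Violation]:
    """Check every structural invariant; return all violations found.

    An empty list means the bundle is internally consistent.  Violations
    are data, not exceptions: callers decide whether to abort.
    """
    out: list[Violation] = []

    # probabilities in [0, 1]
    _check_range(out, p.life_table, "life_table", "qx", 0.0, 1.0)
    _check_range(out, p.t4_model, "t4_model", "p_t4", 0.0, 1.0)
    _check_range(out, p.n_distribution, "n_distribution", "prob", 0.0, 1.0)
    _check_range(out, p.biology, "biology", "prob", 0.0, 1.0)
    _check_range(out, p.sensitivity, "sensitivity", "sensitivity", 0.0, 1.0)
    _check_range(out, p.specificity, "specificity", "specificity", 0.0, 1.0)
    _check_range(out, p.population_utilities, "population_utilities", "score", 0.0, 1.0)
    _check_range(out, p.state_utilities, "state_utilities", "utility", 0.0, 1.0)
    prob_keys = {"brca", "family_history", "hrt_ever"}
    prev_probs = p.risk_factor_prevalence[p.risk_factor_prevalence["key"].isin(prob_keys)]
    _check_range(out, prev_probs, "risk_factor_prevalence", "value", 0.0, 1.0)
    gp = p.growth_params
    _check_range(out, gp, "growth_params", "proportion", 0.0, 1.0)

    # rates and costs non-negative
    _check_range(out, p.onset_rates, "onset_rates", "rate", 0.0)
    _check_range(out, p.detection_hazard, "detection_hazard", "hazard", 0.0)
    _check_range(out, p.k_table, "k_table", "k", 0.0)
    _check_range(out, p.unit_costs, "unit_costs", "cost", 0.0)
    _check_range(out, p.phase_costs, "phase_costs", "annual_cost", 0.0)
    _check_range(out, p.risk_relative_risks, "risk_relative_risks", "rr", 0.0)

    # detection knots strictly increasing in size
    sizes = p.detection_hazard["size_cm"].to_numpy(dtype=float)
    if np.any(np.diff(sizes) <= 0):
        j = int(np.flatnonzero(np.diff(sizes) <= 0)[0])
        out.append(
            Violation(
                "detection_hazard",
                f"rows {j},{j + 1}",
                "size knots must be strictly increasing",
            )
        )

    # growth geometry: d0 > 0 and the dmax sampling floor above d0
    try:
        d0 = p.constant("d0")
        if d0 <= 0:
            out.append(Violation("constants", "d0", "onset diameter must be > 0"))
        dmax_floor = p.constant("dmax_floor")
        if dmax_floor <= d0:
            out.append(
                Violation("constants", "dmax_floor", "dmax support must exceed d0")
            )
    except KeyError as exc:
        out.append(Violation("constants", "-", str(exc)))

    # gamma moments and spread coefficients
    for tname, cols in (("node_spread", ("mu_n_mean", "mu_n_var")), ("metastasis", ("mu_m_mean", "mu_m_var"))):
        tab = getattr(p, tname)
        for col in cols:
            _check_range(out, tab, tname, col, 0.0)

    # n_distribution rows sum to one per (N* bin, T)
    nd = p.n_distribution
    for (nlo, nhi, t), grp in nd.groupby(["nstar_lo", "nstar_hi", "t"]):
        s = grp["prob"].sum()
        if abs(s - 1.0) > 1e-9:
            out.append(
                Violation(
                    "n_distribution",
                    f"N*[{nlo},{nhi}) x T={t}",
                    f"probabilities sum to {s:.6g}, expected 1",
                )
            )

    # every biology stratum sums to one
    strat_cols = ["t", "n", "m", "age_group", "brca", "hrt"]
    for key, grp in p.biology.groupby(strat_cols):
        s = grp["prob"].sum()
        if abs(s - 1.0) > 1e-9:
            cell = ",".join(str(k) for k in key)
            out.append(
                Violation("biology", cell, f"cell probabilities sum to {s:.6g}, expected 1")
            )

    # life table terminates with certain death
    lt = p.life_table.sort_values("age")
    if lt.empty or float(lt["qx"].iloc[-1]) < 1.0:
        out.append(
            Violation(
                "life_table",
                "terminal row",
                "death probability must reach 1 at the maximum age",
            )
        )

    # Weibull transition models structurally valid
    pr = p.progression
    _check_range(out, pr, "progression", "shape", 1e-12)
    _check_range(out, pr, "progression", "scale", 1e-12)
    if "plateau" in pr.columns:
        _check_range(out, pr, "progression", "plateau", 0.0, 1.0)

    return out


# ---------------------------------------------------------------------------
# Random streams


def rng_stream(master_seed: int, individual_id: int, purpose: str) -> np.random.Generator:
    """Named, reproducible random stream for one woman and one model layer.

    Deterministic function of ``(master_seed, individual_id, purpose)``.
    Distinct purposes spawn statistically independent streams; the same
    triple always yields the identical draw sequence, in any scenario.
    """
    if purpose not in PURPOSES:
        raise ValueError(f"unknown stream purpose {purpose!r}; expected one of {PURPOSES}")
    pidx = PURPOSES.index(purpose)
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(pidx, int(individual_id)))
    return np.random.default_rng(ss)
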