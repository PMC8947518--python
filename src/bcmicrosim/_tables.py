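"""Internal lookup helpers for interval-binned parameter tables.

Tables use half-open [lo, hi) bins.  2-D class lookups (metastasis k,
T4 probability) clamp to the nearest class at the top, matching the
nearest-class-clamp convention for sizes or node counts beyond the last
declared bin.

Lookups are hot paths (they run per woman, per thinning candidate, per
screen), so each table is compiled once into numpy arrays and cached,
keyed by the DataFrame's identity; a strong reference keeps the key
valid for the life of the process.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_CACHE: dict[tuple[int, str], object] = {}
_REFS: dict[int, pd.DataFrame] = {}


def _cached(df: pd.DataFrame, name: str, builder):
    key = (id(df), name)
    if key not in _CACHE:
        _REFS[id(df)] = df
        _CACHE[key] = builder(df)
    return _CACHE[key]


# ---------------------------------------------------------------------------
# Onset rates


def _build_onset(df: pd.DataFrame):
    out = {}
    for ttype, sub in df.groupby("tumour_type"):
        out[str(ttype)] = (
            sub["age_lo"].to_numpy(float),
            sub["age_hi"].to_numpy(float),
            sub["year_lo"].to_numpy(float),
            sub["year_hi"].to_numpy(float),
            sub["rate"].to_numpy(float),
        )
    return out


def lookup_onset_rate(table: pd.DataFrame, age: float, year: float, tumour_type: str) -> float:
    data = _cached(table, "onset", _build_onset)
    if tumour_type not in data:
        raise ValueError(f"onset rate table has no tumour type {tumour_type!r}")
    alo, ahi, ylo, yhi, rate = data[tumour_type]
    hit = (alo <= age) & (age < ahi) & (ylo <= year) & (year < yhi)
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        raise ValueError(
            f"onset rate table has no row for age {age:.2f}, year {year:.1f}, "
            f"type {tumour_type!r} (no extrapolation outside table support)"
        )
    return float(rate[idx[0]])


def max_onset_rate(table: pd.DataFrame, tumour_type: str) -> float:
    data = _cached(table, "onset", _build_onset)
    if tumour_type not in data:
        return 0.0
    return float(data[tumour_type][4].max())


# ---------------------------------------------------------------------------
# 2-D class tables (k, T4)


def _build_bin2d(value_col):
    def build(df: pd.DataFrame):
        size_edges = np.sort(df["size_lo"].unique())
        node_edges = np.sort(df["nodes_lo"].unique())
        mat = np.full((len(size_edges), len(node_edges)), np.nan)
        for _, row in df.iterrows():
            i = int(np.searchsorted(size_edges, row["size_lo"]))
            j = int(np.searchsorted(node_edges, row["nodes_lo"]))
            mat[i, j] = row[value_col]
        smax = float(df["size_hi"].max())
        nmax = float(df["nodes_hi"].max())
        return size_edges, node_edges, mat, smax, nmax

    return build


def lookup_bin2d(table: pd.DataFrame, size: float, nodes: float, value_col: str) -> float:
    """Lookup in a size-class x node-class table, clamping at the top."""
    size_edges, node_edges, mat, smax, nmax = _cached(
        table, f"bin2d:{value_col}", _build_bin2d(value_col)
    )
    size = min(size, smax - 1e-9)
    nodes = min(nodes, nmax - 1e-9)
    i = int(np.searchsorted(size_edges, size, side="right")) - 1
    j = int(np.searchsorted(node_edges, nodes, side="right")) - 1
    if i < 0 or j < 0 or np.isnan(mat[i, j]):
        raise ValueError(f"no {value_col} class for size {size:.3g} cm, {nodes:.0f} nodes")
    return float(mat[i, j])


# ---------------------------------------------------------------------------
# 1-D interval tables (specificity, population utilities, ...)


def lookup_interval(
    table: pd.DataFrame, col_lo: str, col_hi: str, x: float, value_col: str
) -> float:
    def build(df):
        sub = df.sort_values(col_lo)
        return (
            sub[col_lo].to_numpy(float),
            sub[col_hi].to_numpy(float),
            sub[value_col].to_numpy(float),
        )

    los, his, vals = _cached(table, f"interval:{col_lo}:{value_col}", build)
    i = int(np.searchsorted(los, x, side="right")) - 1
    if i < 0 or x >= his[i]:
        raise ValueError(f"no row covering {x} in [{col_lo},{col_hi})")
    return float(vals[i])


# ---------------------------------------------------------------------------
# Screening sensitivity: size bins x age bins per sequence


def lookup_sensitivity(table: pd.DataFrame, size: float, age: float, sequence: str) -> float:
    def build(df):
        out = {}
        for seq, sub in df.groupby("sequence"):
            s_edges = np.sort(sub["size_lo"].unique())
            a_edges = np.sort(sub["age_lo"].unique())
            mat = np.full((len(s_edges), len(a_edges)), np.nan)
            for _, row in sub.iterrows():
                i = int(np.searchsorted(s_edges, row["size_lo"]))
                j = int(np.searchsorted(a_edges, row["age_lo"]))
                mat[i, j] = row["sensitivity"]
            out[str(seq)] = (
                s_edges,
                a_edges,
                mat,
                float(sub["size_hi"].max()),
                float(sub["age_hi"].max()),
            )
        return out

    data = _cached(table, "sensitivity", build)
    if sequence not in data:
        raise ValueError(f"sensitivity table has no sequence {sequence!r}")
    s_edges, a_edges, mat, smax, amax = data[sequence]
    if size >= smax or age >= amax:
        raise ValueError(f"sensitivity table does not cover size {size}, age {age}")
    i = int(np.searchsorted(s_edges, size, side="right")) - 1
    j = int(np.searchsorted(a_edges, age, side="right")) - 1
    if i < 0 or j < 0 or np.isnan(mat[i, j]):
        raise ValueError(
            f"sensitivity table has no cell for size {size:.2f} cm, age {age:.0f}, "
            f"sequence {sequence!r}"
        )
    return float(mat[i, j])


# ---------------------------------------------------------------------------
# Life table survival CDF


def life_table_cdf(table: pd.DataFrame):
    def build(df):
        lt = df.sort_values("age")
        qx = lt["qx"].to_numpy(float)
        ages = lt["age"].to_numpy(float)
        surv = np.cumprod(1.0 - qx)
        return ages, qx, 1.0 - surv

    return _cached(table, "life_cdf", build)


# ---------------------------------------------------------------------------
# Categorical strata (N | N*,T and biology)


def n_distribution_rows(table: pd.DataFrame):
    """dict (nstar_lo, nstar_hi, T) -> (categories, probs); plus top bins."""

    def build(df):
        rows = {}
        for (nlo, nhi, t), grp in df.groupby(["nstar_lo", "nstar_hi", "t"]):
            rows[(float(nlo), float(nhi), str(t))] = (
                grp["n_category"].to_numpy(),
                grp["prob"].to_numpy(float),
            )
        return rows

    return _cached(table, "ndist", build)


def biology_strata(table: pd.DataFrame):
    """dict stratum tuple -> (er_pr, her2, grade arrays, probs)."""

    def build(df):
        rows = {}
        for key, grp in df.groupby(["t", "n", "m", "age_group", "brca", "hrt"]):
            rows[key] = (
                grp["er_pr"].to_numpy(),
                grp["her2"].to_numpy(),
                grp["grade"].to_numpy(int),
                grp["prob"].to_numpy(float),
            )
        return rows

    return _cached(table, "biology", build)


def single_row(table: pd.DataFrame) -> dict[str, float]:
    """First row of a one-row coefficient table, as a plain dict."""

    def build(df):
        return {c: float(df[c].iloc[0]) for c in df.columns}

    return _cached(table, "single_row", build)


def growth_mixture(table: pd.DataFrame):
    """dict tumour_type -> (normalised proportions, list of row dicts)."""

    def build(df):
        out = {}
        for ttype, sub in df.groupby("tumour_type"):
            props = sub["proportion"].to_numpy(float)
            rows = sub.to_dict("records")
            out[str(ttype)] = (props / props.sum(), rows)
        return out

    return _cached(table, "growth_mixture", build)


def detection_knots(table: pd.DataFrame):
    """(sizes, hazards) arrays prefixed with the (0, 0) continuity knot."""

    def build(df):
        xs = np.concatenate([[0.0], df["size_cm"].to_numpy(float)])
        ys = np.concatenate([[0.0], df["hazard"].to_numpy(float)])
        return xs, ys

    return _cached(table, "detection_knots", build)


def age_group(age: float) -> str:
    """Coarse age grouping used by the biology strata."""
    if age < 50:
        return "<50"
    if age < 70:
        return "50-69"
    return "70+"


def interp_knots(sizes: np.ndarray, hazards: np.ndarray, size) -> float | np.ndarray:
    """Linear interpolation between detection-hazard knots.

    Below the smallest knot the hazard ramps linearly from zero at size 0
    (continuity; sub-2 mm tumours do not exist in-model).  Above the
    largest knot the hazard is clamped at the last knot's value.
    """
    xs = np.concatenate([[0.0], np.asarray(sizes, float)])
    ys = np.concatenate([[0.0], np.asarray(hazards, float)])
    return np.interp(size, xs, ys)
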