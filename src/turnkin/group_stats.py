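"""Group-comparison tables: summaries, t-tests, percent differences.

Two percent-difference conventions coexist in this analysis and are easy
to conflate:

* :func:`pct_diff_reference` — plain relative difference
  ``(a − ref)/ref × 100``, used for whole-turn group contrasts ("the SS
  group was 67% larger");
* :func:`pct_change_symmetric` — midpoint-referenced change
  ``(x2 − x1)/((x1 + x2)/2) × 100``, used for the partition-comparison
  columns of the spatial tables.  This convention is bounded by ±200 for
  same-sign inputs and antisymmetric under swapping its arguments, which
  is why published partition drops can exceed −100.

Group comparisons use the unpaired two-tailed t-test at α = 0.05, pooled
variance by default (Welch selectable).  No multiple-testing correction is
applied — each parameter is tested at α individually; a documented
limitation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from . import reference_values as ref

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05


@dataclass
class ComparisonRow:
    """One parameter's two-group summary and test result."""

    parameter: str
    placement: str
    direction: str
    scheme: str
    partition_index: int
    mean_ss: float
    sd_ss: float
    mean_hi: float
    sd_hi: float
    t_stat: float
    p_value: float
    significant: bool


def ttest_unpaired(a, b, alpha: float = ALPHA_DEFAULT,
                   variant: str = "pooled") -> tuple[float, float, bool]:
    """Two-sample two-tailed t-test.

    ``variant="pooled"`` is Student's t with pooled variance;
    ``variant="welch"`` drops the equal-variance assumption.  Degenerate
    input with zero variance in both groups and equal means returns
    ``(0.0, 1.0, False)`` by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in t-test input")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    t, p = _stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(t), float(p), bool(p < alpha)


def pct_diff_reference(a: float, ref_value: float) -> float:
    """Plain percent difference of *a* relative to *ref_value*."""
    if ref_value == 0.0:
        logger.warning("percent difference undefined: reference is 0")
        return float("nan")
    return (a - ref_value) / ref_value * 100.0


def pct_change_symmetric(x1: float, x2: float) -> float:
    """Symmetric (midpoint-referenced) percent change from *x1* to *x2*."""
    mid = (x1 + x2) / 2.0
    if mid == 0.0:
        logger.warning("symmetric percent change undefined: x1 + x2 = 0")
        return float("nan")
    return (x2 - x1) / mid * 100.0


# ---------------------------------------------------------------------------
# table construction

def _group_values(df: pd.DataFrame, parameter, placement, direction,
                  scheme, partition_index, group):
    sel = df[
        (df["parameter"] == parameter) & (df["placement"] == placement)
        & (df["direction"] == direction) & (df["scheme"] == scheme)
        & (df["partition_index"] == partition_index) & (df["group"] == group)
    ]["value"].to_numpy(dtype=float)
    return sel[np.isfinite(sel)]


def compare_parameter(df: pd.DataFrame, parameter, placement, direction,
                      scheme, partition_index, alpha=ALPHA_DEFAULT,
                      variant="pooled") -> ComparisonRow:
    """Summarize and test one parameter between the two groups."""
    vals = {g: _group_values(df, parameter, placement, direction, scheme,
                             partition_index, g) for g in ("SS", "HI")}
    missing = [g for g, v in vals.items() if v.size == 0]
    if missing:
        logger.warning("parameter %s/%s/%s missing group(s) %s",
                       parameter, placement, direction, missing)
        t = p = float("nan")
        sig = False
    else:
        t, p, sig = ttest_unpaired(vals["SS"], vals["HI"], alpha, variant)

    def m(g):
        return float(np.mean(vals[g])) if vals[g].size else float("nan")

    def s(g):
        return float(np.std(vals[g], ddof=1)) if vals[g].size > 1 else float("nan")

    return ComparisonRow(
        parameter=parameter, placement=placement, direction=direction,
        scheme=scheme, partition_index=partition_index,
        mean_ss=m("SS"), sd_ss=s("SS"), mean_hi=m("HI"), sd_hi=s("HI"),
        t_stat=t, p_value=p, significant=sig)


#: rows of the whole-turn (temporal) comparison table, in published order
TEMPORAL_TABLE_ROWS = [
    (r["parameter"], r["placement"], r["direction"])
    for r in ref.TEMPORAL_SUMMARY
]

#: rows of the spatial angular-velocity table
SPATIAL_AV_ROWS = [
    ("angular_velocity", p, "flexext")
    for p in ("sternum", "sacrum", "shank_leading", "shank_trailing")
] + [
    ("angular_velocity", p, "rotation")
    for p in ("sternum", "sacrum", "shank_leading", "shank_trailing")
] + [
    ("angular_velocity", p, "lateral") for p in ("sternum", "sacrum")
]

#: rows of the spatial range-of-motion table
SPATIAL_ROM_ROWS = [
    ("rom", p, "flexext")
    for p in ("sternum", "sacrum", "shank_leading", "shank_trailing")
] + [
    ("rom", p, "lateral") for p in ("sacrum", "sternum")
]

#: rows of the spatial relative/ratio table
SPATIAL_RELATIVE_ROWS = [
    ("angular_velocity", "leading_over_trailing", "flexext"),
    ("angular_velocity", "leading_over_trailing", "rotation"),
    ("rom", "leading_over_trailing", "flexext"),
    ("rom", "sternum_minus_sacrum", "rotation"),
    ("rom", "sternum_minus_sacrum", "lateral"),
    ("rom", "sternum_minus_sacrum", "flexext"),
    ("angular_velocity", "sternum_minus_sacrum", "rotation"),
    ("angular_velocity", "sternum_minus_sacrum", "lateral"),
    ("angular_velocity", "sternum_minus_sacrum", "flexext"),
]


def temporal_table(df: pd.DataFrame, alpha=ALPHA_DEFAULT,
                   variant="pooled") -> pd.DataFrame:
    """Whole-turn group-comparison table (one row per parameter)."""
    rows = []
    for parameter, placement, direction in TEMPORAL_TABLE_ROWS:
        row = compare_parameter(df, parameter, placement, direction,
                                "temporal", -1, alpha, variant)
        d = row.__dict__.copy()
        d["pct_diff_vs_other"] = pct_diff_reference(
            max(row.mean_ss, row.mean_hi), min(row.mean_ss, row.mean_hi))
        d["larger_group"] = "SS" if row.mean_ss >= row.mean_hi else "HI"
        rows.append(d)
    return pd.DataFrame(rows).drop(columns=["scheme", "partition_index"])


def spatial_table(df: pd.DataFrame, row_spec, ks=(2, 4),
                  alpha=ALPHA_DEFAULT, variant="pooled") -> pd.DataFrame:
    """Per-partition group means with partition-comparison columns.

    One output row per (parameter, group); per-partition means/SDs for each
    requested ``k``, the symmetric percent change between consecutive
    partitions, and the between-group p-value per partition.
    """
    ks = [k for k in ks
          if f"spatial_k{k}" in set(df["scheme"].unique())]
    rows = []
    for parameter, placement, direction in row_spec:
        per_group: dict = {g: {} for g in ("SS", "HI")}
        pvals = {}
        for k in ks:
            scheme = f"spatial_k{k}"
            for j in range(k):
                cmp_row = compare_parameter(df, parameter, placement,
                                            direction, scheme, j, alpha,
                                            variant)
                per_group["SS"][(k, j)] = (cmp_row.mean_ss, cmp_row.sd_ss)
                per_group["HI"][(k, j)] = (cmp_row.mean_hi, cmp_row.sd_hi)
                pvals[(k, j)] = cmp_row.p_value
        for g in ("SS", "HI"):
            d = {"parameter": parameter, "placement": placement,
                 "direction": direction, "group": g}
            for k in ks:
                means = [per_group[g][(k, j)][0] for j in range(k)]
                for j in range(k):
                    d[f"k{k}_part{j + 1}_mean"] = means[j]
                    d[f"k{k}_part{j + 1}_sd"] = per_group[g][(k, j)][1]
                for j in range(k - 1):
                    d[f"k{k}_cmp_{j + 2}_{j + 1}"] = pct_change_symmetric(
                        means[j], means[j + 1])
                for j in range(k):
                    d[f"k{k}_p_part{j + 1}"] = pvals[(k, j)]
                    d[f"k{k}_sig_part{j + 1}"] = bool(
                        pvals[(k, j)] < alpha) if math.isfinite(
                            pvals[(k, j)]) else False
            rows.append(d)
    return pd.DataFrame(rows)


def build_tables(features: pd.DataFrame, alpha: float = ALPHA_DEFAULT,
                 variant: str = "pooled", ks=(2, 4)) -> dict:
    """Build all four comparison tables from a long-format feature frame.

    Returns a dict of DataFrames: ``temporal_summary``,
    ``spatial_angular_velocity``, ``spatial_rom``, ``spatial_relative`` —
    mirroring the published whole-turn and per-partition table layouts,
    with significance flags in place of typographic bolding.
    """
    for g in ("SS", "HI"):
        if not (features["group"] == g).any():
            raise ValueError(f"group {g} absent from feature table")
    return {
        "temporal_summary": temporal_table(features, alpha, variant),
        "spatial_angular_velocity": spatial_table(
            features, SPATIAL_AV_ROWS, ks, alpha, variant),
        "spatial_rom": spatial_table(
            features, SPATIAL_ROM_ROWS, ks, alpha, variant),
        "spatial_relative": spatial_table(
            features, SPATIAL_RELATIVE_ROWS, ks, alpha, variant),
    }


def write_tables(tables: dict, out_dir) -> list:
    """Write each comparison table as ``<name>.csv`` under *out_dir*."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, frame in tables.items():
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths.append(path)
    return paths
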