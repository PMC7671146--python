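"""Size-bin assignment, density, and per-zone size structure.

The field survey binned carapace widths into four classes — up to 7 mm,
7–10 mm, 10–13 mm, and above 13 mm — and expressed abundance as crabs per
m² of rock under-surface.  The same binning and summaries apply to
individual-based simulation output, enabling like-for-like comparison of
simulated and surveyed size structure.

The printed bin labels leave the measurement-resolution gaps (7.0–7.1 mm
etc.) undefined; bins here are half-open with inclusive upper edges, so
they partition (0, ∞) exactly: B1 (0, 7], B2 (7, 10], B3 (10, 13],
B4 (13, ∞).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "BIN_LABELS",
    "BIN_EDGES",
    "assign_size_bin",
    "bin_spans",
    "survey_density",
    "zone_size_structure",
]

BIN_LABELS = ("B1", "B2", "B3", "B4")
BIN_EDGES = (7.0, 10.0, 13.0)

#: survey-frame columns
SURVEY_COLUMNS = [
    "rock_id", "date", "zone", "surface_area_cm2",
    "n_bin1", "n_bin2", "n_bin3", "n_bin4",
]


def assign_size_bin(cw):
    """Map carapace width (mm) to its size-bin label.

    Upper edges are inclusive: 7.0 → B1, 10.0 → B2, 13.0 → B3.
    Vectorized; widths must be positive.
    """
    arr = np.asarray(cw, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("carapace width must be positive")
    idx = np.digitize(arr, BIN_EDGES, right=True)
    labels = np.asarray(BIN_LABELS)[idx]
    return str(labels) if arr.ndim == 0 else labels


def bin_spans(cw_min: float = 4.0, cw_max: float = 21.0):
    """The four bins' spans intersected with the population size range —
    the intervals used to seed simulated crabs uniformly per bin."""
    edges = [cw_min, *BIN_EDGES, cw_max]
    spans = [(max(lo, cw_min), min(hi, cw_max)) for lo, hi in zip(edges, edges[1:])]
    if any(lo >= hi for lo, hi in spans):
        raise ValueError("size range too narrow to populate all four bins")
    return dict(zip(BIN_LABELS, spans))


def survey_density(survey: pd.Series | dict) -> dict:
    """Crab density (crabs/m²) for one rock survey: counts divided by the
    rock's top surface area (cm² converted to m²).  Returns total and
    per-bin densities; per-bin values sum to the total."""
    area_cm2 = float(survey["surface_area_cm2"])
    if area_cm2 <= 0:
        raise ValueError("surface area must be positive")
    area_m2 = area_cm2 * 1e-4
    out = {}
    total = 0.0
    for i, label in enumerate(BIN_LABELS, start=1):
        count = float(survey[f"n_bin{i}"])
        if count < 0:
            raise ValueError("counts must be non-negative")
        out[label] = count / area_m2
        total += count
    out["total"] = total / area_m2
    return out


def zone_size_structure(data) -> pd.DataFrame:
    """Per-zone size structure from either survey rows or IBM output.

    Parameters
    ----------
    data
        Either a survey frame (columns ``zone, surface_area_cm2,
        n_bin1..n_bin4``, one row per sampled rock) or an IBM count frame
        (columns ``zone, bin, count``; e.g. ``SimResult.final_counts``
        aggregated over replicates).

    Returns
    -------
    DataFrame with one row per zone × bin: pooled ``count``, the zone's
    proportional size structure ``proportion`` (NaN and flagged via
    ``empty_zone`` when the zone holds no crabs), and — for survey input —
    mean and SE across rocks of per-rock density (crabs/m²).
    """
    if {"bin", "count"}.issubset(data.columns):
        counts = (
            data.groupby(["zone", "bin"], observed=True)["count"]
            .sum()
            .reset_index()
        )
        per_rock = None
    else:
        missing = [c for c in SURVEY_COLUMNS[2:] if c not in data.columns]
        if missing:
            raise ValueError(f"survey frame missing column(s): {missing}")
        long = data.melt(
            id_vars=["zone", "surface_area_cm2"],
            value_vars=[f"n_bin{i}" for i in range(1, 5)],
            var_name="bin",
            value_name="count",
        )
        long["bin"] = long["bin"].map(
            {f"n_bin{i}": lab for i, lab in enumerate(BIN_LABELS, start=1)}
        )
        long["density"] = long["count"] / (long["surface_area_cm2"] * 1e-4)
        counts = long.groupby(["zone", "bin"], observed=True)["count"].sum().reset_index()
        per_rock = (
            long.groupby(["zone", "bin"], observed=True)["density"]
            .agg(density_mean="mean", density_se=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
            .reset_index()
        )

    totals = counts.groupby("zone", observed=True)["count"].transform("sum")
    counts["proportion"] = np.where(totals > 0, counts["count"] / totals, np.nan)
    counts["empty_zone"] = totals == 0
    if per_rock is not None:
        counts = counts.merge(per_rock, on=["zone", "bin"], how="left")
    return counts.sort_values(["zone", "bin"]).reset_index(drop=True)
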