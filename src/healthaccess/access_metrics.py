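"""Access outcomes from a travel-time surface: binary access masks, access
population coverage (APC), travel-time summaries, red-zone population, the
four-band heatmap classification, and the stratified access report.

Threshold comparisons are inclusive: "within 30 minutes" means
``travel_time <= 30``.  Unreachable cells (``+inf``) count as not covered at
every threshold and sit in the upper quantile tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .facilities import round_half_up
from .raster_core import Raster, require_aligned

__all__ = [
    "HEATMAP_BANDS",
    "binary_access_mask",
    "apc",
    "weighted_quantile",
    "travel_time_summary",
    "red_zone_population",
    "classify_heatmap",
    "build_report",
]

# class code -> (label, upper bound in minutes, inclusive)
HEATMAP_BANDS = {
    1: ("blue", 15.0),
    2: ("green", 30.0),
    3: ("yellow", 60.0),
    4: ("red", math.inf),
}


def binary_access_mask(tt: Raster, threshold_min: float) -> Raster:
    """Mask with 1 where ``travel_time <= threshold_min``, 0 elsewhere;
    nodata travel-time cells propagate as the mask nodata code."""
    if tt.kind != "travel_time":
        raise ValueError(f"expected travel_time raster, got {tt.kind!r}")
    if not threshold_min > 0:
        raise ValueError(f"threshold must be > 0, got {threshold_min}")
    v = tt.values
    out = np.where(v <= threshold_min, 1, 0).astype(np.int32)
    out[np.isnan(v)] = int(tt.spec.nodata)
    return Raster(tt.spec, out, "mask")


def _stratum_selector(
    tt: Raster, pop: Raster, stratum_mask: Raster | None
) -> np.ndarray:
    require_aligned(tt, pop)
    sel = pop.valid_mask & ~np.isnan(tt.values)
    if stratum_mask is not None:
        require_aligned(tt, stratum_mask)
        sel &= stratum_mask.valid_mask & (stratum_mask.values == 1)
    return sel


def apc(
    tt: Raster,
    pop: Raster,
    threshold_min: float,
    stratum_mask: Raster | None = None,
    rounded: bool = True,
) -> float:
    """Access population coverage: percentage of the stratum's population in
    cells with travel time within the threshold.

    Raises ``ValueError`` when the stratum holds zero population.
    """
    sel = _stratum_selector(tt, pop, stratum_mask)
    p = pop.values
    total = float(np.nansum(p[sel]))
    if total <= 0:
        raise ValueError("stratum population is zero; APC undefined")
    covered = float(np.nansum(p[sel & (tt.values <= threshold_min)]))
    pct = 100.0 * covered / total
    return round_half_up(pct, 1) if rounded else pct


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Smallest value v whose cumulative weight reaches ``q`` of the total
    (left-continuous step inverse).  ``+inf`` values are legal and occupy the
    upper tail."""
    if not 0 <= q <= 1:
        raise ValueError(f"q must be in [0, 1], got {q}")
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0 or weights.sum() <= 0:
        raise ValueError("empty or zero-weight sample")
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w)
    target = q * cum[-1]
    idx = int(np.searchsorted(cum, target, side="left"))
    idx = min(idx, v.size - 1)
    return float(v[idx])


def travel_time_summary(
    tt: Raster,
    pop: Raster | None = None,
    stratum_mask: Raster | None = None,
    weighting: str = "population",
) -> dict[str, float]:
    """Mean, SD, median and quartiles of travel time over a stratum.

    ``weighting="population"`` weights each cell by its population count and
    restricts to cells with population > 0; ``weighting="pixel"`` weights
    every non-nodata cell equally.  Returns a dict with keys ``mean``, ``sd``,
    ``median``, ``q1``, ``q3``, ``weight_total``.
    """
    if weighting not in ("population", "pixel"):
        raise ValueError("weighting must be 'population' or 'pixel'")
    if tt.kind != "travel_time":
        raise ValueError(f"expected travel_time raster, got {tt.kind!r}")
    if weighting == "population":
        if pop is None:
            raise ValueError("population weighting requires a population raster")
        sel = _stratum_selector(tt, pop, stratum_mask) & (pop.values > 0)
        weights = pop.values[sel]
    else:
        sel = ~np.isnan(tt.values)
        if stratum_mask is not None:
            require_aligned(tt, stratum_mask)
            sel &= stratum_mask.valid_mask & (stratum_mask.values == 1)
        weights = np.ones(int(sel.sum()))
    values = tt.values[sel]
    if values.size == 0 or weights.sum() <= 0:
        raise ValueError("empty stratum: no contributing cells")

    wsum = float(weights.sum())
    finite = np.isfinite(values)
    if finite.all():
        mean = float((values * weights).sum() / wsum)
        sd = float(math.sqrt(((values - mean) ** 2 * weights).sum() / wsum))
    else:
        mean, sd = math.inf, math.inf
    return {
        "mean": mean,
        "sd": sd,
        "median": weighted_quantile(values, weights, 0.5),
        "q1": weighted_quantile(values, weights, 0.25),
        "q3": weighted_quantile(values, weights, 0.75),
        "weight_total": wsum,
    }


def red_zone_population(tt: Raster, pop: Raster) -> float:
    """Total population in cells more than 60 minutes from the nearest source."""
    sel = _stratum_selector(tt, pop, None)
    return float(np.nansum(pop.values[sel & (tt.values > 60.0)]))


def classify_heatmap(tt: Raster) -> Raster:
    """Four-band classification of a travel-time surface.

    Class 1 (blue): tt <= 15; 2 (green): 15 < tt <= 30; 3 (yellow):
    30 < tt <= 60; 4 (red): tt > 60.  Nodata propagates.
    """
    if tt.kind != "travel_time":
        raise ValueError(f"expected travel_time raster, got {tt.kind!r}")
    v = tt.values
    out = np.full(v.shape, int(tt.spec.nodata), dtype=np.int32)
    known = ~np.isnan(v)
    out[known & (v <= 15.0)] = 1
    out[known & (v > 15.0) & (v <= 30.0)] = 2
    out[known & (v > 30.0) & (v <= 60.0)] = 3
    out[known & (v > 60.0)] = 4
    return Raster(tt.spec, out, "heatmap_class")


def _zone_codes(zone_raster: Raster) -> list[int]:
    codes = np.unique(zone_raster.values[zone_raster.valid_mask])
    return [int(z) for z in codes]


def build_report(
    tt: Raster,
    pop: Raster,
    zone_raster: Raster | None = None,
    urban_mask: Raster | None = None,
    thresholds: tuple[float, ...] = (30.0, 60.0, 120.0),
    weighting: str = "population",
) -> pd.DataFrame:
    """Stratified access report: one row per (national + zone) x settlement.

    Columns: ``zone``, ``settlement``, ``population``, ``mean_tt``, ``sd_tt``,
    ``median_tt``, ``q1_tt``, ``q3_tt`` and ``apc_<t>`` per threshold.  Zones
    (or strata) with zero population are kept as flagged rows (metrics NaN,
    ``flag='zero_population'``) rather than dropped.
    """
    require_aligned(tt, pop)
    if tuple(thresholds) != tuple(sorted(thresholds)) or any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive and increasing")
    if urban_mask is not None:
        require_aligned(tt, urban_mask)
        if urban_mask.kind != "mask":
            raise ValueError("urban_mask must be a mask raster")
    if zone_raster is not None:
        require_aligned(tt, zone_raster)
        if zone_raster.kind != "zone":
            raise ValueError("zone_raster must be a zone raster")

    strata: list[tuple[object, str, np.ndarray]] = []
    pop_valid = pop.valid_mask
    urban = None
    if urban_mask is not None:
        urban = urban_mask.valid_mask & (urban_mask.values == 1)

    def add_zone(zone_label, zone_sel: np.ndarray) -> None:
        strata.append((zone_label, "total", zone_sel))
        if urban is not None:
            strata.append((zone_label, "rural", zone_sel & ~urban))
            strata.append((zone_label, "urban", zone_sel & urban))

    everywhere = np.ones(tt.spec.shape, dtype=bool)
    add_zone("national", everywhere)
    if zone_raster is not None:
        for code in _zone_codes(zone_raster):
            add_zone(code, zone_raster.values == code)

    rows = []
    for zone_label, settlement, sel in strata:
        mask_raster = Raster(
            tt.spec, sel.astype(np.int32), "mask"
        )
        row: dict = {"zone": zone_label, "settlement": settlement, "flag": ""}
        stratum_pop = float(np.nansum(pop.values[sel & pop_valid]))
        row["population"] = stratum_pop
        if stratum_pop <= 0:
            row["flag"] = "zero_population"
            for key in ("mean_tt", "sd_tt", "median_tt", "q1_tt", "q3_tt"):
                row[key] = math.nan
            for t in thresholds:
                row[f"apc_{t:g}"] = math.nan
        else:
            summ = travel_time_summary(tt, pop, mask_raster, weighting=weighting)
            row["mean_tt"] = summ["mean"]
            row["sd_tt"] = summ["sd"]
            row["median_tt"] = summ["median"]
            row["q1_tt"] = summ["q1"]
            row["q3_tt"] = summ["q3"]
            for t in thresholds:
                row[f"apc_{t:g}"] = apc(tt, pop, t, mask_raster)
        rows.append(row)

    cols = ["zone", "settlement", "population", "mean_tt", "sd_tt",
            "median_tt", "q1_tt", "q3_tt"]
    cols += [f"apc_{t:g}" for t in thresholds] + ["flag"]
    return pd.DataFrame(rows, columns=cols)
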