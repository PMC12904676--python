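"""Facility registry: CSV ingestion, validation, deduplication, service
summaries, zone shares, and centre density."""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, box, shape
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep

from .raster_core import Raster

__all__ = [
    "TIERS",
    "TRI_STATES",
    "COST_CATEGORIES",
    "Facility",
    "FacilitySet",
    "ServiceSummary",
    "load_facilities",
    "parse_boundary",
    "bounds_filter",
    "dedupe",
    "summarize_services",
    "facility_zone_shares",
    "density_per_10m",
    "round_half_up",
]

TIERS = ("PCC", "TH", "DH", "CHC", "PHC")
TRI_STATES = ("yes", "no", "unknown")
COST_CATEGORIES = ("free", "free_for_poor", "paid", "unknown")

_TRI_ATTRS = ("outpatient", "inpatient", "homecare", "trained_worker", "morphine")


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero, matching conventional table reporting."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Facility:
    """A point facility with tier, service flags, and cost category."""

    id: str
    name: str
    x: float
    y: float
    tier: str
    outpatient: str = "unknown"
    inpatient: str = "unknown"
    homecare: str = "unknown"
    trained_worker: str = "unknown"
    morphine: str = "unknown"
    cost_category: str = "unknown"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"facility {self.id!r}: coordinates must be finite")
        if self.tier not in TIERS:
            raise ValueError(f"facility {self.id!r}: unknown tier {self.tier!r}")
        for attr in _TRI_ATTRS:
            if getattr(self, attr) not in TRI_STATES:
                raise ValueError(
                    f"facility {self.id!r}: {attr} must be one of {TRI_STATES}"
                )
        if self.cost_category not in COST_CATEGORIES:
            raise ValueError(
                f"facility {self.id!r}: cost_category must be one of {COST_CATEGORIES}"
            )


@dataclass
class FacilitySet:
    """An ordered collection of facilities with unique ids."""

    facilities: list[Facility]
    source_label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for fac in self.facilities:
            if fac.id in seen:
                raise ValueError(f"duplicate facility id {fac.id!r} in set {self.source_label!r}")
            seen.add(fac.id)

    def __len__(self) -> int:
        return len(self.facilities)

    def __iter__(self):
        return iter(self.facilities)

    def __getitem__(self, i: int) -> Facility:
        return self.facilities[i]

    def coords(self) -> np.ndarray:
        """(n, 2) array of x, y coordinates in input order."""
        return np.array([(f.x, f.y) for f in self.facilities], dtype=float).reshape(-1, 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": f.id,
                    "name": f.name,
                    "x": f.x,
                    "y": f.y,
                    "tier": f.tier,
                    "outpatient": f.outpatient,
                    "inpatient": f.inpatient,
                    "homecare": f.homecare,
                    "trained_worker": f.trained_worker,
                    "morphine": f.morphine,
                    "cost_category": f.cost_category,
                }
                for f in self.facilities
            ],
            columns=[
                "id", "name", "x", "y", "tier",
                "outpatient", "inpatient", "homecare", "trained_worker",
                "morphine", "cost_category",
            ],
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ServiceSummary:
    """Per-attribute counts and percentages over a facility set.

    ``denominator_policy`` records whether percentages divide by the full set
    size (``"all"``) or only by records whose value is known (``"known"``).
    Percentages are rounded half-up to one decimal; an empty denominator
    yields ``None``.
    """

    total: int
    denominator_policy: str
    counts: dict[str, dict[str, int | float | None]]

    def percentage(self, attribute: str) -> float | None:
        return self.counts[attribute]["percentage"]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"attribute": attr, **vals, "denominator_policy": self.denominator_policy}
            for attr, vals in self.counts.items()
        ]
        return pd.DataFrame(rows)


_ALIASES = {
    "lon": "x", "longitude": "x", "x": "x",
    "lat": "y", "latitude": "y", "y": "y",
}


def _norm_tri(raw) -> str:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return "unknown"
    s = str(raw).strip().lower()
    if s in ("", "na", "nan", "unknown", "?"):
        return "unknown"
    if s in ("yes", "y", "true", "1"):
        return "yes"
    if s in ("no", "n", "false", "0"):
        return "no"
    raise ValueError(f"cannot interpret tri-state value {raw!r}")


def load_facilities(
    path: str | os.PathLike, tier: str, source_label: str | None = None
) -> tuple[FacilitySet, pd.DataFrame]:
    """Load one tier's registry from CSV.

    Required columns: ``id``, ``lon``/``x``, ``lat``/``y``.  Optional service
    columns default to ``unknown``.  Rows with unparseable coordinates are
    collected into the returned rejection report, not silently dropped.

    Returns ``(facility_set, rejections)`` where ``rejections`` has columns
    ``row``, ``id``, ``reason``.
    """
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}")
    df = pd.read_csv(path, dtype={"id": str, "name": str})
    df = df.rename(columns={c: _ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns})
    missing = {"id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"{path}: duplicate ids {dups}")

    facilities: list[Facility] = []
    rejects: list[dict] = []
    for idx, row in df.iterrows():
        try:
            x = float(row["x"])
            y = float(row["y"])
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError("non-finite coordinate")
        except (TypeError, ValueError):
            rejects.append({"row": int(idx), "id": row["id"], "reason": "unparseable coordinates"})
            continue
        try:
            fac = Facility(
                id=str(row["id"]),
                name=str(row.get("name", row["id"])),
                x=x,
                y=y,
                tier=tier,
                outpatient=_norm_tri(row.get("outpatient")),
                inpatient=_norm_tri(row.get("inpatient")),
                homecare=_norm_tri(row.get("homecare")),
                trained_worker=_norm_tri(row.get("trained_worker")),
                morphine=_norm_tri(row.get("morphine")),
                cost_category=_norm_cost(row.get("cost_category")),
            )
        except ValueError as exc:
            rejects.append({"row": int(idx), "id": row["id"], "reason": str(exc)})
            continue
        facilities.append(fac)
    fs = FacilitySet(facilities, source_label or os.fspath(path))
    return fs, pd.DataFrame(rejects, columns=["row", "id", "reason"])


def _norm_cost(raw) -> str:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return "unknown"
    s = str(raw).strip().lower()
    if s in ("", "na", "nan", "unknown", "?"):
        return "unknown"
    if s in COST_CATEGORIES:
        return s
    raise ValueError(f"cannot interpret cost_category value {raw!r}")


def parse_boundary(boundary) -> BaseGeometry:
    """Accept a shapely geometry, a ``"minx,miny,maxx,maxy"`` bbox string, a
    4-tuple, or a GeoJSON file path, and return a shapely geometry."""
    if isinstance(boundary, BaseGeometry):
        geom = boundary
    elif isinstance(boundary, (tuple, list)) and len(boundary) == 4:
        geom = box(*[float(v) for v in boundary])
    elif isinstance(boundary, str) and os.path.exists(boundary):
        with open(boundary) as fh:
            gj = json.load(fh)
        if gj.get("type") == "FeatureCollection":
            geoms = [shape(feat["geometry"]) for feat in gj["features"]]
            from shapely.ops import unary_union

            geom = unary_union(geoms)
        elif gj.get("type") == "Feature":
            geom = shape(gj["geometry"])
        else:
            geom = shape(gj)
    elif isinstance(boundary, str):
        parts = [float(v) for v in boundary.split(",")]
        if len(parts) != 4:
            raise ValueError(f"bbox string must be 'minx,miny,maxx,maxy', got {boundary!r}")
        geom = box(*parts)
    else:
        raise TypeError(f"cannot interpret boundary {boundary!r}")
    if geom.is_empty or not geom.is_valid:
        raise ValueError("boundary geometry is empty or invalid")
    return geom


def bounds_filter(fs: FacilitySet, boundary) -> tuple[FacilitySet, int]:
    """Keep facilities whose point lies inside or on the boundary.

    Returns ``(kept_set, n_removed)``.
    """
    geom = parse_boundary(boundary)
    prepared = prep(geom)
    kept = [f for f in fs if prepared.intersects(Point(f.x, f.y))]
    removed = len(fs) - len(kept)
    return FacilitySet(kept, fs.source_label), removed


def dedupe(
    fs: FacilitySet, tolerance_m: float = 0.0
) -> tuple[FacilitySet, pd.DataFrame]:
    """Greedy first-wins coordinate deduplication.

    A facility is dropped iff it lies within ``tolerance_m`` of an earlier
    *retained* facility (Euclidean distance in projected meters; tolerance 0
    removes exact coordinate duplicates only).  Returns the retained set and a
    merge log with columns ``dropped_id``, ``kept_id``, ``distance_m``.
    """
    if tolerance_m < 0:
        raise ValueError(f"tolerance_m must be >= 0, got {tolerance_m}")
    kept: list[Facility] = []
    kept_xy: list[tuple[float, float]] = []
    log: list[dict] = []
    for fac in fs:
        match = None
        for j, (kx, ky) in enumerate(kept_xy):
            d = math.hypot(fac.x - kx, fac.y - ky)
            if d <= tolerance_m:
                match = (j, d)
                break
        if match is None:
            kept.append(fac)
            kept_xy.append((fac.x, fac.y))
        else:
            j, d = match
            log.append({"dropped_id": fac.id, "kept_id": kept[j].id, "distance_m": d})
    return (
        FacilitySet(kept, fs.source_label),
        pd.DataFrame(log, columns=["dropped_id", "kept_id", "distance_m"]),
    )


def summarize_services(
    fs: FacilitySet, denominator: str = "known"
) -> ServiceSummary:
    """Tabulate service availability over a facility set.

    ``denominator="known"`` divides by records with a known value for each
    attribute; ``denominator="all"`` divides by the full set size.  For the
    cost category, the numerator counts ``free`` (and ``free_for_poor`` is
    reported separately).
    """
    if denominator not in ("known", "all"):
        raise ValueError("denominator must be 'known' or 'all'")
    total = len(fs)
    counts: dict[str, dict] = {}

    def entry(n_yes: int, n_known: int) -> dict:
        denom = n_known if denominator == "known" else total
        pct = round_half_up(100.0 * n_yes / denom, 1) if denom > 0 else None
        return {"numerator": n_yes, "denominator": denom, "percentage": pct}

    for attr in _TRI_ATTRS:
        vals = [getattr(f, attr) for f in fs]
        n_yes = sum(v == "yes" for v in vals)
        n_known = sum(v != "unknown" for v in vals)
        counts[attr] = entry(n_yes, n_known)

    cost_vals = [f.cost_category for f in fs]
    n_cost_known = sum(v != "unknown" for v in cost_vals)
    counts["free"] = entry(sum(v == "free" for v in cost_vals), n_cost_known)
    counts["free_for_poor"] = entry(
        sum(v == "free_for_poor" for v in cost_vals), n_cost_known
    )
    return ServiceSummary(total=total, denominator_policy=denominator, counts=counts)


def facility_zone_shares(fs: FacilitySet, zone_raster: Raster) -> pd.DataFrame:
    """Count facilities per zone and their percentage share of the whole set.

    Facilities outside the grid or on nodata zone cells land in zone code -1.
    Percentages are rounded half-up to one decimal.
    """
    if zone_raster.kind != "zone":
        raise ValueError(f"expected a zone raster, got kind {zone_raster.kind!r}")
    spec = zone_raster.spec
    zone_of: list[int] = []
    nodata = int(spec.nodata)
    for fac in fs:
        r, c = spec.world_to_cell(fac.x, fac.y)
        if spec.contains_cell(r, c) and zone_raster.values[r, c] != nodata:
            zone_of.append(int(zone_raster.values[r, c]))
        else:
            zone_of.append(-1)
    ser = pd.Series(zone_of, name="zone")
    tab = ser.value_counts().sort_index().rename("n_centres").reset_index()
    total = len(fs)
    tab["share_pct"] = [
        round_half_up(100.0 * n / total, 1) if total else None for n in tab["n_centres"]
    ]
    return tab


def density_per_10m(n_centres: int, population: float) -> float:
    """Centres per ten million people, rounded half-up to one decimal."""
    if n_centres < 0:
        raise ValueError("n_centres must be >= 0")
    if not population > 0:
        raise ValueError(f"population must be > 0, got {population}")
    return round_half_up(1e7 * n_centres / population, 1)
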