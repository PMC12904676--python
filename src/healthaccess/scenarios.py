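"""Facility-network scenarios: tier unions, per-scenario travel-time runs,
and the comparative access report.

The four default scenarios mirror a staged integration of services into the
public health system:

* ``I``   — directory centres + teaching hospitals + district hospitals
* ``II``  — scenario I + community health centres
* ``III`` — scenario II + primary health centres
* ``IV``  — scenario III minus the directory centres (public system only)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .access_metrics import build_report, red_zone_population
from .facilities import TIERS, FacilitySet, dedupe
from .raster_core import Raster
from .traveltime import accumulate_cost, rasterize_facilities

__all__ = [
    "Scenario",
    "DEFAULT_SCENARIOS",
    "ScenarioComparison",
    "ConsistencyError",
    "build_scenario_set",
    "run_scenarios",
]


class ConsistencyError(RuntimeError):
    """An internal invariant (e.g. nested-scenario monotonicity) failed."""


@dataclass(frozen=True)
class Scenario:
    """A named union of facility tiers."""

    name: str
    tiers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.tiers:
            raise ValueError(f"scenario {self.name!r}: tiers must be nonempty")
        for t in self.tiers:
            if t not in TIERS:
                raise ValueError(f"scenario {self.name!r}: unknown tier {t!r}")

    def is_nested_in(self, other: "Scenario") -> bool:
        return set(self.tiers) <= set(other.tiers)


DEFAULT_SCENARIOS: tuple[Scenario, ...] = (
    Scenario("I", ("PCC", "TH", "DH")),
    Scenario("II", ("PCC", "TH", "DH", "CHC")),
    Scenario("III", ("PCC", "TH", "DH", "CHC", "PHC")),
    Scenario("IV", ("TH", "DH", "CHC", "PHC")),
)


@dataclass
class ScenarioComparison:
    """Per-scenario reports plus the red-zone population trajectory."""

    reports: dict[str, pd.DataFrame]
    red_zone: dict[str, float]
    travel_times: dict[str, Raster]
    facility_counts: dict[str, int]

    def long_table(self) -> pd.DataFrame:
        """Long-format table: scenario x stratum rows with all metrics."""
        frames = []
        for name, rep in self.reports.items():
            rep = rep.copy()
            rep.insert(0, "scenario", name)
            frames.append(rep)
        return pd.concat(frames, ignore_index=True)

    def red_zone_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"scenario": list(self.red_zone), "red_zone_population": list(self.red_zone.values())}
        )


def build_scenario_set(
    scenario: Scenario,
    registry: Mapping[str, FacilitySet],
    dedupe_tolerance_m: float = 100.0,
) -> tuple[FacilitySet, pd.DataFrame]:
    """Union the scenario's tier sets and deduplicate.

    Tiers are concatenated in the fixed order PCC, TH, DH, CHC, PHC so the
    greedy first-wins dedup gives directory centres precedence on coordinate
    ties.  Returns the retained set plus the merge log.
    """
    missing = [t for t in scenario.tiers if t not in registry]
    if missing:
        raise KeyError(f"scenario {scenario.name!r}: registry missing tiers {missing}")
    ordered = [t for t in TIERS if t in scenario.tiers]
    union: list = []
    for tier in ordered:
        union.extend(registry[tier].facilities)
    combined = FacilitySet(union, source_label=f"scenario-{scenario.name}")
    return dedupe(combined, dedupe_tolerance_m)


def run_scenarios(
    scenarios: Sequence[Scenario],
    registry: Mapping[str, FacilitySet],
    friction: Raster,
    pop: Raster,
    zone_raster: Raster | None = None,
    urban_mask: Raster | None = None,
    thresholds: tuple[float, ...] = (30.0, 60.0, 120.0),
    dedupe_tolerance_m: float = 100.0,
    connectivity: int = 8,
    weighting: str = "population",
    check_nesting: bool = True,
) -> ScenarioComparison:
    """Run the full travel-time + report pipeline for each scenario.

    For every nested pair of scenarios the pointwise travel-time monotonicity
    invariant is verified; a violation can only arise from a bug and raises
    :class:`ConsistencyError`.
    """
    if not scenarios:
        raise ValueError("scenario list is empty")
    reports: dict[str, pd.DataFrame] = {}
    red: dict[str, float] = {}
    tts: dict[str, Raster] = {}
    counts: dict[str, int] = {}
    source_cells: dict[str, frozenset] = {}
    for sc in scenarios:
        fset, _log = build_scenario_set(sc, registry, dedupe_tolerance_m)
        if len(fset) == 0:
            raise ValueError(f"scenario {sc.name!r}: facility set empty after dedup")
        sources = rasterize_facilities(fset, friction.spec, friction)
        source_cells[sc.name] = frozenset(sources.cells)
        tt = accumulate_cost(friction, sources, connectivity=connectivity)
        tts[sc.name] = tt
        counts[sc.name] = len(fset)
        reports[sc.name] = build_report(
            tt, pop, zone_raster, urban_mask, thresholds=thresholds, weighting=weighting
        )
        red[sc.name] = red_zone_population(tt, pop)

    if check_nesting:
        # The tier-level nesting only implies pointwise monotonicity when the
        # dedup/snap pipeline kept A's source cells inside B's.
        for a in scenarios:
            for b in scenarios:
                if (
                    a.name != b.name
                    and a.is_nested_in(b)
                    and source_cells[a.name] <= source_cells[b.name]
                ):
                    worse = tts[b.name].values > tts[a.name].values + 1e-9
                    if np.any(worse & ~np.isnan(tts[a.name].values)):
                        raise ConsistencyError(
                            f"travel time increased from scenario {a.name} to "
                            f"superset scenario {b.name}"
                        )
    return ScenarioComparison(
        reports=reports, red_zone=red, travel_times=tts, facility_counts=counts
    )
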