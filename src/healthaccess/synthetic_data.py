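"""Seeded generator for a miniature synthetic country.

Produces, from one integer seed, a mutually consistent bundle of inputs with
the spatial structure the accessibility pipeline assumes: a friction surface
with fast road corridors over a slower, spatially-correlated background; a
population raster with dense urban clusters on a sparse rural field; a
Voronoi zone partition with one deliberately over-served ("favored") zone;
and per-tier facility registries whose abundance rises and urban bias falls
from teaching hospitals down to primary health centres.

All randomness flows from ``numpy`` Generators spawned off a single
``SeedSequence``, so every artifact is bit-reproducible per seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .facilities import COST_CATEGORIES, TIERS, Facility, FacilitySet
from .raster_core import GridSpec, Raster, write_raster

__all__ = [
    "SynthConfig",
    "gen_zones",
    "gen_friction",
    "gen_population",
    "gen_facilities",
    "generate_world",
    "write_world",
]


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for the synthetic world; defaults give a ~1 s, 96x96 country."""

    seed: int = 42
    n_rows: int = 96
    n_cols: int = 96
    cell_size_m: float = 1000.0
    x_origin: float = 500_000.0
    y_origin: float = 3_000_000.0
    crs_id: str = "LOCAL:synthetic-equal-area"
    n_zones: int = 6
    n_urban_clusters: int = 8
    total_population: float = 5_000_000.0
    urban_share: float = 0.3
    urban_sigma_cells: float = 2.5
    road_count: int = 10
    road_friction: float = 0.012    # ~83 km/h
    offroad_friction: float = 0.04  # 25 km/h
    rough_friction: float = 0.12    # 5 km/h
    roughness_smooth_cells: float = 6.0
    roughness_amplitude: float = 1.0  # 0 => constant offroad background
    facility_counts: dict = field(
        default_factory=lambda: {"PCC": 60, "TH": 12, "DH": 25, "CHC": 80, "PHC": 300}
    )
    urban_bias: dict = field(
        default_factory=lambda: {"PCC": 0.8, "TH": 0.95, "DH": 0.7, "CHC": 0.45, "PHC": 0.25}
    )
    favored_zone: int = 0
    favored_share: float = 0.445
    service_yes_prob: dict = field(
        default_factory=lambda: {
            "outpatient": 0.78, "inpatient": 0.62, "homecare": 0.72,
            "trained_worker": 0.91, "morphine": 0.66,
        }
    )
    service_unknown_prob: float = 0.04
    free_prob: float = 0.73

    def __post_init__(self) -> None:
        if not (self.road_friction < self.offroad_friction < self.rough_friction):
            raise ValueError("friction triple must satisfy road < offroad < rough")
        if not 0 < self.urban_share < 1:
            raise ValueError(f"urban_share must be in (0, 1), got {self.urban_share}")
        if any(v < 0 for v in self.facility_counts.values()):
            raise ValueError("facility counts must be >= 0")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            cell_size_m=self.cell_size_m,
            x_origin=self.x_origin,
            y_origin=self.y_origin,
            crs_id=self.crs_id,
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


# Child-stream indices off the master SeedSequence; fixed so each stage is
# reproducible independently of the others.
_STREAMS = {"zones": 0, "clusters": 1, "friction": 2, "population": 3, "facilities": 4}


def _rng(cfg: SynthConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(cfg.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[stream]])


def _cluster_centers(cfg: SynthConfig) -> np.ndarray:
    """(k, 2) row/col urban cluster centers, shared by friction and population."""
    rng = _rng(cfg, "clusters")
    rows = rng.integers(4, cfg.n_rows - 4, size=cfg.n_urban_clusters)
    cols = rng.integers(4, cfg.n_cols - 4, size=cfg.n_urban_clusters)
    return np.stack([rows, cols], axis=1)


def gen_zones(cfg: SynthConfig) -> Raster:
    """Voronoi partition of the grid into ``n_zones`` labelled zones."""
    n_cells = cfg.n_rows * cfg.n_cols
    if cfg.n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    if cfg.n_zones > n_cells:
        raise ValueError(f"n_zones {cfg.n_zones} exceeds cell count {n_cells}")
    rng = _rng(cfg, "zones")
    sites = np.stack(
        [rng.uniform(0, cfg.n_rows, cfg.n_zones), rng.uniform(0, cfg.n_cols, cfg.n_zones)],
        axis=1,
    )
    rr, cc = np.meshgrid(
        np.arange(cfg.n_rows) + 0.5, np.arange(cfg.n_cols) + 0.5, indexing="ij"
    )
    # distance to each site; argmin takes the lowest site index on ties
    d2 = (rr[..., None] - sites[:, 0]) ** 2 + (cc[..., None] - sites[:, 1]) ** 2
    labels = np.argmin(d2, axis=2).astype(np.int32)
    return Raster(cfg.grid, labels, "zone")


def _draw_segment(mask: np.ndarray, r0: int, c0: int, r1: int, c1: int) -> None:
    """Mark a supercover line of cells between two cell centers."""
    n = int(max(abs(r1 - r0), abs(c1 - c0))) * 2 + 1
    rs = np.rint(np.linspace(r0, r1, n)).astype(int)
    cs = np.rint(np.linspace(c0, c1, n)).astype(int)
    mask[rs, cs] = True


def gen_friction(cfg: SynthConfig) -> Raster:
    """Friction surface: smooth roughness field plus fast road corridors.

    Background values interpolate between ``offroad_friction`` and
    ``rough_friction`` through a Gaussian-smoothed noise field; road cells are
    set to ``road_friction`` exactly.  Roads run between randomly chosen
    pairs of urban cluster centers, with a bend at a random waypoint.
    """
    rng = _rng(cfg, "friction")
    noise = rng.standard_normal((cfg.n_rows, cfg.n_cols))
    smooth = ndimage.gaussian_filter(noise, sigma=cfg.roughness_smooth_cells)
    span = smooth.max() - smooth.min()
    unit = (smooth - smooth.min()) / span if span > 0 else np.zeros_like(smooth)
    values = cfg.offroad_friction + unit * cfg.roughness_amplitude * (
        cfg.rough_friction - cfg.offroad_friction
    )

    centers = _cluster_centers(cfg)
    road_mask = np.zeros(values.shape, dtype=bool)
    k = len(centers)
    for _ in range(cfg.road_count):
        i, j = rng.choice(k, size=2, replace=False) if k >= 2 else (0, 0)
        waypoint = (
            int(rng.integers(0, cfg.n_rows)),
            int(rng.integers(0, cfg.n_cols)),
        )
        _draw_segment(road_mask, centers[i, 0], centers[i, 1], *waypoint)
        _draw_segment(road_mask, *waypoint, centers[j, 0], centers[j, 1])
    values[road_mask] = cfg.road_friction
    return Raster(cfg.grid, values, "friction")


def gen_population(cfg: SynthConfig) -> tuple[Raster, Raster]:
    """Population raster plus the urban mask.

    Urban population (``urban_share`` of the total) is spread over Gaussian
    kernels at the cluster centers; the remainder is a lognormal rural
    background.  The urban mask is kernel membership (within 2 sigma of a
    center), so the rural/urban partition is exact by construction and the
    total population is conserved to rounding.
    """
    rng = _rng(cfg, "population")
    centers = _cluster_centers(cfg)
    rr, cc = np.meshgrid(np.arange(cfg.n_rows), np.arange(cfg.n_cols), indexing="ij")
    sigma = cfg.urban_sigma_cells

    d2 = (rr[..., None] - centers[:, 0]) ** 2 + (cc[..., None] - centers[:, 1]) ** 2
    kernel = np.exp(-d2 / (2 * sigma**2)).sum(axis=2)
    urban_mask = (d2.min(axis=2) <= (2 * sigma) ** 2).astype(np.int32)

    urban_total = cfg.urban_share * cfg.total_population
    rural_total = cfg.total_population - urban_total

    urban_w = np.where(urban_mask == 1, kernel, 0.0)
    urban_pop = urban_w / urban_w.sum() * urban_total

    rural_w = np.where(urban_mask == 0, rng.lognormal(mean=0.0, sigma=1.0, size=kernel.shape), 0.0)
    rural_pop = rural_w / rural_w.sum() * rural_total

    pop = Raster(cfg.grid, urban_pop + rural_pop, "population")
    return pop, Raster(cfg.grid, urban_mask, "mask")


def _sample_cells(
    rng: np.random.Generator,
    candidates: np.ndarray,
    n: int,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Sample ``n`` cell indices (with replacement) from an (m, 2) candidate
    array, optionally weighted."""
    if len(candidates) == 0:
        raise ValueError("no candidate cells to place facilities on")
    p = None
    if weights is not None:
        total = weights.sum()
        p = weights / total if total > 0 else None
    idx = rng.choice(len(candidates), size=n, replace=True, p=p)
    return candidates[idx]


def gen_facilities(
    cfg: SynthConfig,
    zones: Raster,
    urban_mask: Raster,
    population: Raster | None = None,
) -> dict[str, FacilitySet]:
    """Per-tier facility registries.

    For each tier, an ``urban_bias`` fraction of facilities lands on urban
    cells (population-weighted when a population raster is given), the rest
    uniformly on rural cells.  The PCC tier additionally concentrates a
    ``favored_share`` fraction inside ``favored_zone``.  Coordinates are
    jittered inside their cell; service flags follow the configured yes /
    no / unknown probabilities.
    """
    rng = _rng(cfg, "facilities")
    spec = cfg.grid
    urban = urban_mask.values == 1
    if any(b > 0 for b in cfg.urban_bias.values()) and not urban.any():
        raise ValueError("urban mask is empty but urban_bias is positive")
    zone_vals = zones.values
    pop_vals = population.values if population is not None else None

    def candidates(want_urban: bool, zone: int | None) -> tuple[np.ndarray, np.ndarray | None]:
        sel = urban if want_urban else ~urban
        if zone is not None:
            zsel = sel & (zone_vals == zone) if zone >= 0 else sel & (zone_vals != cfg.favored_zone)
            if zsel.any():
                sel = zsel
        cells = np.argwhere(sel)
        w = None
        if want_urban and pop_vals is not None:
            w = pop_vals[sel]
        return cells, w

    registries: dict[str, FacilitySet] = {}
    for tier in TIERS:
        n = int(cfg.facility_counts.get(tier, 0))
        if n == 0:
            registries[tier] = FacilitySet([], source_label=f"synthetic-{tier}")
            continue
        n_urban = int(round(cfg.urban_bias.get(tier, 0.0) * n))
        placements: list[tuple[int, int]] = []

        if tier == "PCC" and cfg.n_zones > 1:
            n_favored = int(round(cfg.favored_share * n))
            plan = [(cfg.favored_zone, n_favored), (-1, n - n_favored)]
        else:
            plan = [(None, n)]

        for zone, n_zone in plan:
            if n_zone <= 0:
                continue
            nu = int(round(n_urban * n_zone / n))
            nr = n_zone - nu
            if nu > 0:
                cells, w = candidates(True, zone)
                placements.extend(map(tuple, _sample_cells(rng, cells, nu, w)))
            if nr > 0:
                cells, _ = candidates(False, zone)
                placements.extend(map(tuple, _sample_cells(rng, cells, nr)))

        facilities = []
        for k, (r, c) in enumerate(placements):
            cx, cy = spec.cell_center(int(r), int(c))
            jx, jy = rng.uniform(-0.45, 0.45, size=2) * spec.cell_size_m
            flags = {}
            for attr, p_yes in cfg.service_yes_prob.items():
                u = rng.random()
                if u < cfg.service_unknown_prob:
                    flags[attr] = "unknown"
                else:
                    flags[attr] = "yes" if rng.random() < p_yes else "no"
            u = rng.random()
            if u < cfg.service_unknown_prob:
                cost = "unknown"
            else:
                cost = "free" if rng.random() < cfg.free_prob else rng.choice(["free_for_poor", "paid"])
            facilities.append(
                Facility(
                    id=f"{tier}-{k:04d}",
                    name=f"{tier} facility {k}",
                    x=cx + jx,
                    y=cy + jy,
                    tier=tier,
                    cost_category=str(cost),
                    **flags,
                )
            )
        registries[tier] = FacilitySet(facilities, source_label=f"synthetic-{tier}")
    return registries


def generate_world(cfg: SynthConfig) -> dict:
    """All synthetic inputs in one shot.

    Returns a dict with keys ``zones``, ``friction``, ``population``,
    ``urban_mask`` (Rasters) and ``facilities`` (tier -> FacilitySet).
    """
    zones = gen_zones(cfg)
    friction = gen_friction(cfg)
    pop, urban = gen_population(cfg)
    registries = gen_facilities(cfg, zones, urban, pop)
    return {
        "zones": zones,
        "friction": friction,
        "population": pop,
        "urban_mask": urban,
        "facilities": registries,
    }


def write_world(cfg: SynthConfig, outdir: str | os.PathLike) -> dict[str, str]:
    """Write the synthetic world to disk in the pipeline's input formats.

    Emits four GeoTIFFs, one CSV per facility tier, and the config as JSON.
    Returns a manifest mapping artifact names to paths.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    world = generate_world(cfg)
    manifest: dict[str, str] = {}
    for key in ("zones", "friction", "population", "urban_mask"):
        path = os.path.join(outdir, f"{key}.tif")
        write_raster(world[key], path)
        manifest[key] = path
    for tier, fset in world["facilities"].items():
        path = os.path.join(outdir, f"facilities_{tier}.csv")
        fset.to_csv(path)
        manifest[f"facilities_{tier}"] = path
    cfg_path = os.path.join(outdir, "synth_config.json")
    with open(cfg_path, "w") as fh:
        fh.write(cfg.to_json())
    manifest["config"] = cfg_path
    return manifest
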