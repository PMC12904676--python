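"""Multi-source least-cost travel-time accumulation over a friction surface.

Each cell of the friction raster carries a cost in minutes per meter.  The
edge between two adjacent cells ``a`` and ``b`` costs

    ((friction(a) + friction(b)) / 2) * distance(a, b)

with distance equal to ``cell_size_m`` for the 4 orthogonal neighbours,
``cell_size_m * sqrt(2)`` for diagonals, and ``cell_size_m * sqrt(5)`` for
knight moves under 16-connectivity.  Nodata friction cells are impassable.
The accumulated surface gives, per cell, the minimum total minutes along any
path to the nearest source cell.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .facilities import FacilitySet
from .raster_core import GridSpec, Raster, require_aligned

__all__ = [
    "SourceCells",
    "neighbor_offsets",
    "rasterize_facilities",
    "accumulate_cost",
    "oracle_accumulate",
]

_ORTHO = [(-1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0), (1, 0, 1.0)]
_DIAG = [(-1, -1, math.sqrt(2)), (-1, 1, math.sqrt(2)), (1, -1, math.sqrt(2)), (1, 1, math.sqrt(2))]
_KNIGHT = [
    (dr, dc, math.sqrt(5))
    for dr in (-2, -1, 1, 2)
    for dc in (-2, -1, 1, 2)
    if abs(dr) != abs(dc)
]


def neighbor_offsets(connectivity: int) -> list[tuple[int, int, float]]:
    """(dr, dc, unit distance) triples for 4-, 8-, or 16-connected grids."""
    if connectivity == 4:
        return list(_ORTHO)
    if connectivity == 8:
        return _ORTHO + _DIAG
    if connectivity == 16:
        return _ORTHO + _DIAG + _KNIGHT
    raise ValueError(f"connectivity must be 4, 8, or 16, got {connectivity}")


@dataclass
class SourceCells:
    """Facility source cells on a grid: cell indices plus contributing ids."""

    spec: GridSpec
    cell_to_ids: dict[tuple[int, int], list[str]]
    snap_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["id", "from_row", "from_col", "to_row", "to_col", "reason"]
        )
    )
    unplaceable: list[str] = field(default_factory=list)

    @property
    def cells(self) -> list[tuple[int, int]]:
        return sorted(self.cell_to_ids)

    def __len__(self) -> int:
        return len(self.cell_to_ids)

    def validate_against(self, friction: Raster) -> None:
        for (r, c) in self.cell_to_ids:
            if not self.spec.contains_cell(r, c):
                raise ValueError(f"source cell ({r}, {c}) outside grid bounds")
            if not np.isfinite(friction.values[r, c]):
                raise ValueError(f"source cell ({r}, {c}) lies on nodata friction")


def rasterize_facilities(
    fs: FacilitySet,
    spec: GridSpec,
    friction: Raster,
    snap_radius: int = 5,
) -> SourceCells:
    """Bind each facility to its containing grid cell.

    Facilities whose cell has nodata friction are snapped to the nearest
    valid cell (Euclidean distance between cell centers, deterministic
    row-major tie-break) within ``snap_radius`` cells; failing that, or when
    the facility falls outside the grid, it is reported unplaceable.
    Multiple facilities may share one source cell.
    """
    if friction.kind != "friction":
        raise ValueError(f"expected friction raster, got {friction.kind!r}")
    if not spec.aligned_with(friction.spec):
        raise ValueError("grid spec and friction raster are not aligned")
    valid = friction.valid_mask
    cell_to_ids: dict[tuple[int, int], list[str]] = {}
    snap_rows: list[dict] = []
    unplaceable: list[str] = []

    for fac in fs:
        r, c = spec.world_to_cell(fac.x, fac.y)
        if not spec.contains_cell(r, c):
            unplaceable.append(fac.id)
            snap_rows.append(
                {"id": fac.id, "from_row": r, "from_col": c,
                 "to_row": -1, "to_col": -1, "reason": "outside grid"}
            )
            continue
        if not valid[r, c]:
            target = _nearest_valid(valid, r, c, snap_radius)
            if target is None:
                unplaceable.append(fac.id)
                snap_rows.append(
                    {"id": fac.id, "from_row": r, "from_col": c,
                     "to_row": -1, "to_col": -1, "reason": "no valid cell in snap radius"}
                )
                continue
            snap_rows.append(
                {"id": fac.id, "from_row": r, "from_col": c,
                 "to_row": target[0], "to_col": target[1], "reason": "nodata friction"}
            )
            r, c = target
        cell_to_ids.setdefault((r, c), []).append(fac.id)

    return SourceCells(
        spec=spec,
        cell_to_ids=cell_to_ids,
        snap_log=pd.DataFrame(
            snap_rows,
            columns=["id", "from_row", "from_col", "to_row", "to_col", "reason"],
        ),
        unplaceable=unplaceable,
    )


def _nearest_valid(
    valid: np.ndarray, r: int, c: int, radius: int
) -> tuple[int, int] | None:
    n_rows, n_cols = valid.shape
    best = None
    best_d2 = math.inf
    for rr in range(max(0, r - radius), min(n_rows, r + radius + 1)):
        for cc in range(max(0, c - radius), min(n_cols, c + radius + 1)):
            if valid[rr, cc]:
                d2 = (rr - r) ** 2 + (cc - c) ** 2
                if d2 < best_d2 or (d2 == best_d2 and (rr, cc) < best):
                    best, best_d2 = (rr, cc), d2
    return best


def accumulate_cost(
    friction: Raster, sources: SourceCells, connectivity: int = 8
) -> Raster:
    """Exact multi-source Dijkstra over the friction grid.

    Ties on the heap key break deterministically toward the lowest
    ``(row, col)``, so the output is bit-reproducible.  Cells with no path to
    any source (or nodata friction) come back as ``+inf``.
    """
    if friction.kind != "friction":
        raise ValueError(f"expected friction raster, got {friction.kind!r}")
    if len(sources) == 0:
        raise ValueError("source set is empty")
    if not friction.spec.aligned_with(sources.spec):
        raise ValueError("friction raster and sources are not aligned")
    sources.validate_against(friction)

    f = friction.values
    n_rows, n_cols = f.shape
    step = friction.spec.cell_size_m
    offsets = neighbor_offsets(connectivity)
    valid = np.isfinite(f)

    dist = np.full((n_rows, n_cols), np.inf)
    done = np.zeros((n_rows, n_cols), dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for (r, c) in sources.cells:
        dist[r, c] = 0.0
        heapq.heappush(heap, (0.0, r, c))

    while heap:
        d, r, c = heapq.heappop(heap)
        if done[r, c] or d > dist[r, c]:
            continue
        done[r, c] = True
        fr = f[r, c]
        for dr, dc, unit in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols and valid[rr, cc] and not done[rr, cc]:
                nd = d + 0.5 * (fr + f[rr, cc]) * unit * step
                if nd < dist[rr, cc]:
                    dist[rr, cc] = nd
                    heapq.heappush(heap, (nd, rr, cc))

    return Raster(friction.spec, dist, "travel_time")


def oracle_accumulate(
    friction: Raster, sources: SourceCells, connectivity: int = 8
) -> Raster:
    """Reference implementation: repeated edge relaxation to fixpoint.

    Same contract as :func:`accumulate_cost` but computed Bellman–Ford style
    with no priority queue, no early exit, and no shared traversal machinery.
    Guarded to grids of at most 64x64 cells; intended for tests only.
    """
    if friction.kind != "friction":
        raise ValueError(f"expected friction raster, got {friction.kind!r}")
    if len(sources) == 0:
        raise ValueError("source set is empty")
    if friction.spec.n_rows > 64 or friction.spec.n_cols > 64:
        raise ValueError("oracle_accumulate is limited to grids <= 64x64")
    if not friction.spec.aligned_with(sources.spec):
        raise ValueError("friction raster and sources are not aligned")
    sources.validate_against(friction)

    f = friction.values
    n_rows, n_cols = f.shape
    step = friction.spec.cell_size_m
    offsets = neighbor_offsets(connectivity)

    dist = {
        (r, c): math.inf
        for r in range(n_rows)
        for c in range(n_cols)
        if math.isfinite(f[r, c])
    }
    for cell in sources.cells:
        dist[cell] = 0.0

    changed = True
    while changed:
        changed = False
        for (r, c) in dist:
            base = dist[(r, c)]
            if base == math.inf:
                continue
            for dr, dc, unit in offsets:
                nb = (r + dr, c + dc)
                if nb in dist:
                    cand = base + 0.5 * (f[r, c] + f[nb]) * unit * step
                    if cand < dist[nb]:
                        dist[nb] = cand
                        changed = True

    out = np.full((n_rows, n_cols), np.inf)
    for (r, c), d in dist.items():
        out[r, c] = d
    return Raster(friction.spec, out, "travel_time")
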