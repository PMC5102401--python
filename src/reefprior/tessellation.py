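"""Nested planning-unit grids clipped to reef.

Two square tessellations are laid over the reefscape raster: small units of
1 km^2 and large units of 25 km^2, aligned to the raster origin so that 25
small units nest exactly inside each large one.  Units whose footprint
contains no reef are dropped; units on reef edges keep their square
footprint but their *area* is the reef they contain (the clipped area), so
edge units have fractional areas.

The module also intersects the grids with the reef-class layers to produce
Marxan-style feature-amount tables, and aggregates cell cost surfaces to
per-unit cost vectors (the uniform layer is reef area by definition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reefscape import CostSurface, Reefscape

__all__ = [
    "PlanningUnit",
    "PUGrid",
    "build_grids",
    "intersect_features",
    "compute_costs",
    "LARGE_ID_OFFSET",
]

#: large-unit ids start here so small and large ids never collide
LARGE_ID_OFFSET = 1_000_000


@dataclass(frozen=True)
class PlanningUnit:
    pu_id: int
    size_class: str  # "S" or "L"
    row0: int  # top-left cell of the square footprint
    col0: int
    span: int  # cells per side
    reef_area_km2: float
    parent_id: int | None  # enclosing large unit (small units only)
    is_edge: bool  # footprint not fully reef


@dataclass
class PUGrid:
    """Both planning-unit tessellations plus the large->small nesting map."""

    units: dict[int, PlanningUnit]
    nesting: dict[int, list[int]]
    cell_size_km: float
    small_span: int
    large_span: int

    def ids(self, size_class: str) -> list[int]:
        return sorted(u.pu_id for u in self.units.values() if u.size_class == size_class)

    @property
    def small_ids(self) -> list[int]:
        return self.ids("S")

    @property
    def large_ids(self) -> list[int]:
        return self.ids("L")

    def areas(self, size_class: str) -> pd.Series:
        ids = self.ids(size_class)
        return pd.Series(
            [self.units[i].reef_area_km2 for i in ids], index=ids, name="reef_area_km2"
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pu_id": u.pu_id,
                "size_class": u.size_class,
                "row0": u.row0,
                "col0": u.col0,
                "span": u.span,
                "reef_area_km2": u.reef_area_km2,
                "parent_id": u.parent_id if u.parent_id is not None else -1,
                "is_edge": u.is_edge,
            }
            for u in self.units.values()
        ]
        return pd.DataFrame(rows).sort_values("pu_id").reset_index(drop=True)


def build_grids(reefscape: Reefscape) -> PUGrid:
    """Build the nested small (1 km^2) and large (25 km^2) grids.

    The raster dimensions must be an exact multiple of the large-unit span
    (no ragged tiling).  Zero-reef squares are dropped; every retained
    small unit records its enclosing large unit.
    """
    cs = reefscape.cell_size_km
    small_span = round(1.0 / cs)
    large_span = 5 * small_span
    rows, cols = reefscape.shape
    if rows % large_span or cols % large_span:
        raise ValueError(
            f"grid {rows}x{cols} is not divisible by the large-unit span "
            f"{large_span}; ragged tilings are not supported"
        )
    frac = reefscape.reef_fraction
    cell_area = reefscape.cell_area_km2
    n_small_cols = cols // small_span

    units: dict[int, PlanningUnit] = {}
    nesting: dict[int, list[int]] = {}

    for lr in range(rows // large_span):
        for lc in range(cols // large_span):
            r0, c0 = lr * large_span, lc * large_span
            block = frac[r0 : r0 + large_span, c0 : c0 + large_span]
            area = float(block.sum() * cell_area)
            if area <= 0:
                continue
            lid = LARGE_ID_OFFSET + lr * (cols // large_span) + lc + 1
            units[lid] = PlanningUnit(
                pu_id=lid,
                size_class="L",
                row0=r0,
                col0=c0,
                span=large_span,
                reef_area_km2=area,
                parent_id=None,
                is_edge=bool((block < 1.0).any()),
            )
            children: list[int] = []
            for sr in range(5):
                for sc in range(5):
                    sr0 = r0 + sr * small_span
                    sc0 = c0 + sc * small_span
                    sblock = frac[sr0 : sr0 + small_span, sc0 : sc0 + small_span]
                    sarea = float(sblock.sum() * cell_area)
                    if sarea <= 0:
                        continue
                    sid = (sr0 // small_span) * n_small_cols + (sc0 // small_span) + 1
                    units[sid] = PlanningUnit(
                        pu_id=sid,
                        size_class="S",
                        row0=sr0,
                        col0=sc0,
                        span=small_span,
                        reef_area_km2=sarea,
                        parent_id=lid,
                        is_edge=bool((sblock < 1.0).any()),
                    )
                    children.append(sid)
            nesting[lid] = children

    if not units:
        warnings.warn("reefscape contains no reef: planning-unit grid is empty")
    return PUGrid(
        units=units,
        nesting=nesting,
        cell_size_km=cs,
        small_span=small_span,
        large_span=large_span,
    )


def intersect_features(
    reefscape: Reefscape, grid: PUGrid, level: int
) -> pd.DataFrame:
    """Feature-amount table at one thematic level, for both unit sizes.

    Returns rows ``(pu_id, level, class_id, amount_km2)`` where the amount
    is the reef area of the class inside the unit; zero amounts are not
    recorded.  Per level, amounts sum to the total reef area within each
    size class.
    """
    if not 1 <= level <= 5:
        raise ValueError("level must be in 1..5")
    lab = reefscape.labels[level - 1]
    frac = reefscape.reef_fraction
    cell_area = reefscape.cell_area_km2
    rows_out: list[tuple[int, int, int, float]] = []
    for u in grid.units.values():
        block_lab = lab[u.row0 : u.row0 + u.span, u.col0 : u.col0 + u.span]
        block_frac = frac[u.row0 : u.row0 + u.span, u.col0 : u.col0 + u.span]
        reef = block_lab >= 0
        if not reef.any():
            continue
        amounts = np.bincount(
            block_lab[reef], weights=block_frac[reef] * cell_area
        )
        for cid in np.nonzero(amounts > 0)[0]:
            rows_out.append((u.pu_id, level, int(cid), float(amounts[cid])))
    df = pd.DataFrame(rows_out, columns=["pu_id", "level", "class_id", "amount_km2"])
    return df.sort_values(["pu_id", "class_id"]).reset_index(drop=True)


def compute_costs(
    grid: PUGrid, cost_surface: CostSurface, reefscape: Reefscape,
    aggregation: str = "area_weighted_sum",
) -> pd.DataFrame:
    """Per-unit cost vector: uniform (= reef area) and variable layers.

    The variable layer aggregates the cell cost surface over the unit.
    ``aggregation`` is one of:

    - ``"area_weighted_sum"`` (default): sum of cell cost x reef_fraction x
      cell area, so variable cost also scales with reef content and a
      constant surface reduces to cost proportional to area;
    - ``"mean"``: plain mean of cell costs over the footprint;
    - ``"centroid"``: cost of the footprint's central cell.
    """
    if aggregation not in {"area_weighted_sum", "mean", "centroid"}:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    surf = cost_surface.variable_cost
    if surf.shape != reefscape.shape:
        raise ValueError("cost surface does not cover the grid")
    frac = reefscape.reef_fraction
    cell_area = reefscape.cell_area_km2
    recs = []
    for u in grid.units.values():
        sl = (slice(u.row0, u.row0 + u.span), slice(u.col0, u.col0 + u.span))
        if aggregation == "area_weighted_sum":
            var = float((surf[sl] * frac[sl]).sum() * cell_area)
        elif aggregation == "mean":
            var = float(surf[sl].mean())
        else:
            mid = (u.row0 + u.span // 2, u.col0 + u.span // 2)
            var = float(surf[mid])
        if var <= 0:
            raise ValueError(f"non-positive variable cost for unit {u.pu_id}")
        recs.append(
            {
                "pu_id": u.pu_id,
                "size_class": u.size_class,
                "uniform_cost": u.reef_area_km2,
                "variable_cost": var,
            }
        )
    df = pd.DataFrame(recs).sort_values("pu_id").reset_index(drop=True)
    if (df["uniform_cost"] <= 0).any():
        raise ValueError("non-positive uniform cost")
    return df
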