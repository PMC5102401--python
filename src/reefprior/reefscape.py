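"""Synthetic raster reefscapes with hierarchical geomorphic classes.

A reefscape is a regular grid of square cells.  Reef occurs in a set of
contiguous (4-connected) patches; each reef cell carries a *reef fraction*
(the share of the cell's area that is actually reef, so that planning units
clipped to reef edges have continuous areas) and a five-level class path
``(l1, l2, l3, l4, l5)`` emulating a hierarchical geomorphic classification:
level 1 is coarsest (a handful of broad classes), level 5 finest (many narrow
classes).  Levels 1-3 and 5 are strictly hierarchical; a configurable
fraction of level-4 labels is *shared* between different level-3 parents,
i.e. the level-4 layer is not uniquely hierarchical within level 3.

Class regions are produced by recursive spatial subdivision (a weighted
Voronoi split of each parent region), so classes are spatially coherent
blocks, and the per-seed weights are drawn from a heavy-tailed distribution
so class extents are left-skewed: many restricted classes, few extensive
ones — the rarity structure typical of geomorphic reef maps.

Costs: the spatially uniform cost layer is simply reef area (handled at the
planning-unit level); the spatially variable layer built here is a proxy for
fishing opportunity cost, a population-weighted linear distance decay from
fisher population centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReefscapeConfig",
    "Reefscape",
    "FisherPopulation",
    "CostSurface",
    "generate_reefscape",
    "generate_fishers",
    "generate_variable_cost",
]

#: floor applied to the linear distance decay so costs stay strictly positive
COST_FLOOR = 1e-6


@dataclass(frozen=True)
class ReefscapeConfig:
    """Parameters of the synthetic reefscape generator.

    Parameters
    ----------
    grid_rows, grid_cols
        Cell counts of the raster.
    cell_size_km
        Side length of one cell in km.  Must divide 1 km evenly so that a
        1 km^2 planning unit is an integer number of cells per side
        (default 0.2 km -> 5 cells).
    reef_fraction_target
        Fraction of grid cells that are reef, in (0, 1].
    n_patches
        Number of contiguous reef patches grown (patches may touch and
        merge on crowded grids; each grown patch is 4-connected).
    classes_per_level
        Five non-decreasing class counts, coarse to fine.  The level-4
        entry is the number of level-4 *branches*; when ``level4_sharing``
        is positive some branches reuse labels of branches under other
        level-3 parents, so the count of distinct level-4 labels may fall
        below it.
    level4_sharing
        Fraction in [0, 1] of level-4 branches relabelled to reuse a label
        from a different level-3 parent.
    rarity_skew
        Positive Pareto shape for the seed weights of the spatial splits;
        smaller values give a heavier tail, i.e. more unequal (left-skewed)
        class-extent distributions.
    class_patchiness
        Average number of disjoint spatial chunks making up one class
        region.  1 gives single-blob classes; larger values let a class
        recur in several places inside its parent region, the way real
        geomorphic classes (e.g. an atoll rim) recur across a reefscape.
    seed
        RNG seed; generation is deterministic given the config.
    """

    grid_rows: int
    grid_cols: int
    cell_size_km: float = 0.2
    reef_fraction_target: float = 0.6
    n_patches: int = 4
    classes_per_level: tuple[int, int, int, int, int] = (2, 11, 25, 43, 120)
    level4_sharing: float = 0.25
    rarity_skew: float = 1.2
    class_patchiness: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if not 0.0 < self.reef_fraction_target <= 1.0:
            raise ValueError("reef_fraction_target must be in (0, 1]")
        if self.n_patches < 1:
            raise ValueError("n_patches must be >= 1")
        cpl = tuple(int(c) for c in self.classes_per_level)
        if len(cpl) != 5 or any(c < 1 for c in cpl):
            raise ValueError("classes_per_level must be five positive counts")
        if any(cpl[i] > cpl[i + 1] for i in range(4)):
            raise ValueError("classes_per_level must be non-decreasing")
        if not 0.0 <= self.level4_sharing <= 1.0:
            raise ValueError("level4_sharing must be in [0, 1]")
        if self.rarity_skew <= 0:
            raise ValueError("rarity_skew must be positive")
        if self.class_patchiness < 1:
            raise ValueError("class_patchiness must be >= 1")
        per_side = 1.0 / self.cell_size_km
        if abs(per_side - round(per_side)) > 1e-9:
            raise ValueError(
                "cell_size_km must divide 1 km evenly so a 1 km^2 planning "
                f"unit is a whole number of cells (got {self.cell_size_km})"
            )
        object.__setattr__(self, "classes_per_level", cpl)

    @property
    def cells_per_km(self) -> int:
        return round(1.0 / self.cell_size_km)

    def to_dict(self) -> dict:
        return {
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "cell_size_km": self.cell_size_km,
            "reef_fraction_target": self.reef_fraction_target,
            "n_patches": self.n_patches,
            "classes_per_level": list(self.classes_per_level),
            "level4_sharing": self.level4_sharing,
            "rarity_skew": self.rarity_skew,
            "class_patchiness": self.class_patchiness,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReefscapeConfig":
        d = dict(d)
        if "classes_per_level" in d:
            d["classes_per_level"] = tuple(d["classes_per_level"])
        return cls(**d)


@dataclass
class Reefscape:
    """Raster reefscape: reef fractions plus a five-level class labelling.

    ``labels`` has shape (5, rows, cols) with -1 on non-reef cells; labels
    are 0-based integers, unique within a level (level-4 labels may recur
    under several level-3 parents when sharing is enabled).
    """

    reef_fraction: np.ndarray
    labels: np.ndarray
    cell_size_km: float

    def __post_init__(self) -> None:
        self.reef_fraction = np.asarray(self.reef_fraction, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (5, *self.reef_fraction.shape):
            raise ValueError("labels must have shape (5, rows, cols)")
        mask = self.reef_fraction > 0
        if (self.labels[:, mask] < 0).any():
            raise ValueError("reef cells must carry a full class path")
        if (self.labels[:, ~mask] >= 0).any():
            raise ValueError("non-reef cells must not carry class labels")
        # generated reefscapes always contain reef; an all-zero raster is
        # representable so downstream code can handle the degenerate case

    @property
    def shape(self) -> tuple[int, int]:
        return self.reef_fraction.shape

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    @property
    def reef_mask(self) -> np.ndarray:
        return self.reef_fraction > 0

    @property
    def total_reef_area_km2(self) -> float:
        return float(self.reef_fraction.sum() * self.cell_area_km2)

    def class_extents(self, level: int) -> pd.Series:
        """Total reef area (km^2) per class at ``level`` (1-based)."""
        if not 1 <= level <= 5:
            raise ValueError("level must be in 1..5")
        lab = self.labels[level - 1]
        mask = self.reef_mask
        areas = self.reef_fraction[mask] * self.cell_area_km2
        s = pd.Series(areas).groupby(lab[mask]).sum()
        s.index.name = "class_id"
        s.name = f"extent_km2_l{level}"
        return s

    def parent_map(self, level: int) -> dict[int, set[int]]:
        """Map each class at ``level`` (2..5) to its set of parent labels.

        The parent level is ``level - 1`` except for level 5, whose parent
        is the (level-3, level-4) branch encoded as a tuple.
        """
        if not 2 <= level <= 5:
            raise ValueError("level must be in 2..5")
        mask = self.reef_mask
        child = self.labels[level - 1][mask]
        if level == 5:
            l3 = self.labels[2][mask]
            l4 = self.labels[3][mask]
            parent = list(zip(l3.tolist(), l4.tolist()))
        else:
            parent = self.labels[level - 2][mask].tolist()
        out: dict[int, set] = {}
        for c, p in zip(child.tolist(), parent):
            out.setdefault(c, set()).add(p)
        return out


@dataclass(frozen=True)
class FisherPopulation:
    """Fisher population centres as (row, col, population_size) triples."""

    centres: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        if len(self.centres) == 0:
            raise ValueError("at least one fisher population centre required")
        for r, c, p in self.centres:
            if p < 1:
                raise ValueError("population sizes must be >= 1")

    def validate_on(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        for r, c, _ in self.centres:
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(f"fisher centre ({r}, {c}) lies outside the grid")


@dataclass
class CostSurface:
    """Per-cell spatially variable cost (arbitrary units, > 0 everywhere)."""

    variable_cost: np.ndarray

    def __post_init__(self) -> None:
        self.variable_cost = np.asarray(self.variable_cost, dtype=float)
        if not np.isfinite(self.variable_cost).all():
            raise ValueError("cost surface must be finite")
        if (self.variable_cost <= 0).any():
            raise ValueError("cost surface must be strictly positive")


# ---------------------------------------------------------------------------
# generation


def _grow_patches(cfg: ReefscapeConfig, rng: np.random.Generator) -> np.ndarray:
    """Grow ``n_patches`` 4-connected reef patches to the target cell count."""
    rows, cols = cfg.grid_rows, cfg.grid_cols
    n_cells = rows * cols
    target = int(round(cfg.reef_fraction_target * n_cells))
    target = max(target, 1)
    if target < cfg.n_patches:
        raise ValueError(
            f"reef_fraction_target {cfg.reef_fraction_target} yields only "
            f"{target} reef cells: cannot host {cfg.n_patches} patches"
        )
    mask = np.zeros((rows, cols), dtype=bool)
    starts = rng.choice(n_cells, size=cfg.n_patches, replace=False)
    frontiers: list[list[tuple[int, int]]] = []
    # fixed heavy-tailed growth weights give unequal patch sizes
    weights = rng.pareto(cfg.rarity_skew, size=cfg.n_patches) + 1.0
    count = 0
    for s in starts:
        r, c = divmod(int(s), cols)
        if not mask[r, c]:
            mask[r, c] = True
            count += 1
        frontiers.append([(r, c)])
    alive = list(range(cfg.n_patches))
    while count < target and alive:
        w = weights[alive]
        p = int(rng.choice(alive, p=w / w.sum()))
        grown = False
        frontier = frontiers[p]
        while frontier and not grown:
            i = int(rng.integers(len(frontier)))
            r, c = frontier[i]
            nbrs = [
                (rr, cc)
                for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
                if 0 <= rr < rows and 0 <= cc < cols and not mask[rr, cc]
            ]
            if not nbrs:
                frontier[i] = frontier[-1]
                frontier.pop()
                continue
            rr, cc = nbrs[int(rng.integers(len(nbrs)))]
            mask[rr, cc] = True
            count += 1
            frontier.append((rr, cc))
            grown = True
        if not grown:
            alive.remove(p)
    if count < target:
        raise ValueError("could not reach reef_fraction_target")  # pragma: no cover
    return mask


def _allocate_children(
    sizes: np.ndarray, total: int, rng: np.random.Generator
) -> np.ndarray:
    """Distribute ``total`` child classes among parents, >= 1 each and no
    more than a parent's cell count, roughly proportional to parent size."""
    n = len(sizes)
    caps = sizes.astype(int)
    if total < n:
        raise ValueError(
            f"cannot allocate {total} child classes to {n} parents (need >= 1 each)"
        )
    if total > caps.sum():
        raise ValueError(
            f"cannot allocate {total} child classes: only {caps.sum()} cells available"
        )
    alloc = np.ones(n, dtype=int)
    for _ in range(total - n):
        room = caps - alloc
        w = sizes * (room > 0)
        alloc[int(rng.choice(n, p=w / w.sum()))] += 1
    return alloc


def _partition(
    cells_rc: np.ndarray, k: int, rng: np.random.Generator, skew: float
) -> np.ndarray:
    """Split a region into ``k`` spatially coherent parts (weighted Voronoi).

    Seeds own their cells, so every part is non-empty; Pareto seed weights
    make part sizes left-skewed.
    """
    m = len(cells_rc)
    if k == 1:
        return np.zeros(m, dtype=int)
    idx = rng.choice(m, size=k, replace=False)
    seeds = cells_rc[idx]
    w = rng.pareto(skew, size=k) + 1.0
    d = np.sqrt(((cells_rc[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2))
    lab = np.argmin(d / w[None, :], axis=1)
    lab[idx] = np.arange(k)
    return lab


def _partition_classes(
    cells_rc: np.ndarray,
    k: int,
    rng: np.random.Generator,
    skew: float,
    patchiness: int,
) -> np.ndarray:
    """Assign the cells of one parent region to ``k`` child classes.

    The region is first split into up to ``k * patchiness`` spatial chunks;
    chunks are then grouped into classes (every class gets at least one
    chunk, the rest are dealt out with heavy-tailed weights), so one class
    may recur as several disjoint blocks inside its parent.
    """
    m_chunks = min(len(cells_rc), k * patchiness)
    chunk_lab = _partition(cells_rc, m_chunks, rng, skew)
    class_of_chunk = np.empty(m_chunks, dtype=int)
    perm = rng.permutation(m_chunks)
    class_of_chunk[perm[:k]] = np.arange(k)
    if m_chunks > k:
        w = rng.pareto(skew, size=k) + 1.0
        class_of_chunk[perm[k:]] = rng.choice(
            k, size=m_chunks - k, p=w / w.sum()
        )
    return class_of_chunk[chunk_lab]


def generate_reefscape(config: ReefscapeConfig) -> Reefscape:
    """Generate a seeded synthetic reefscape from ``config``.

    Patches are grown by stochastic 4-connected accretion; reef cells on
    patch boundaries get fractional reef cover; class labels are assigned
    by recursive weighted-Voronoi subdivision so that finer levels nest
    spatially inside coarser ones, with optional level-4 label sharing
    across level-3 parents.
    """
    rng = np.random.default_rng(config.seed)
    mask = _grow_patches(config, rng)

    frac = np.zeros(mask.shape, dtype=float)
    interior = mask.copy()
    # a cell is boundary if any in-grid 4-neighbour is non-reef
    interior[:-1] &= mask[1:]
    interior[1:] &= mask[:-1]
    interior[:, :-1] &= mask[:, 1:]
    interior[:, 1:] &= mask[:, :-1]
    boundary = mask & ~interior
    frac[interior] = 1.0
    frac[boundary] = rng.uniform(0.3, 1.0, size=int(boundary.sum()))

    n1, n2, n3, n4, n5 = config.classes_per_level
    reef_rc = np.argwhere(mask)
    labels = np.full((5, *mask.shape), -1, dtype=np.int64)

    def assign(level_index: int, lab_per_region: list[np.ndarray], regions: list[np.ndarray]):
        for reg, lab in zip(regions, lab_per_region):
            rr, cc = reef_rc[reg, 0], reef_rc[reg, 1]
            labels[level_index, rr, cc] = lab

    # strictly hierarchical levels 1..3
    regions = [np.arange(len(reef_rc))]
    for li, n_level in enumerate((n1, n2, n3)):
        sizes = np.array([len(r) for r in regions], dtype=float)
        alloc = _allocate_children(sizes, n_level, rng)
        new_regions: list[np.ndarray] = []
        next_label = 0
        for reg, k in zip(regions, alloc):
            part = _partition_classes(
                reef_rc[reg], int(k), rng, config.rarity_skew, config.class_patchiness
            )
            labs = part + next_label
            assign(li, [labs], [reg])
            for j in range(int(k)):
                new_regions.append(reg[part == j])
            next_label += int(k)
        regions = new_regions

    # level 4: branches within level-3 regions, then label sharing
    l3_of_region = list(range(len(regions)))
    sizes = np.array([len(r) for r in regions], dtype=float)
    alloc4 = _allocate_children(sizes, n4, rng)
    branches: list[np.ndarray] = []
    branch_l3: list[int] = []
    for reg, k, l3 in zip(regions, alloc4, l3_of_region):
        part = _partition_classes(
            reef_rc[reg], int(k), rng, config.rarity_skew, config.class_patchiness
        )
        for j in range(int(k)):
            branches.append(reg[part == j])
            branch_l3.append(l3)
    n_branch = len(branches)
    branch_label = np.arange(n_branch)
    if config.level4_sharing > 0 and len(set(branch_l3)) > 1:
        n_share = max(1, int(round(config.level4_sharing * n_branch)))
        shared = rng.choice(n_branch, size=min(n_share, n_branch - 1), replace=False)
        for b in shared:
            donors = [i for i in range(n_branch) if branch_l3[i] != branch_l3[b]]
            branch_label[b] = branch_label[int(rng.choice(donors))]
    for b, reg in enumerate(branches):
        assign(3, [np.full(len(reg), branch_label[b])], [reg])

    # level 5 nests inside branches (not shared labels)
    sizes = np.array([len(r) for r in branches], dtype=float)
    alloc5 = _allocate_children(sizes, n5, rng)
    next_label = 0
    for reg, k in zip(branches, alloc5):
        part = _partition_classes(
            reef_rc[reg], int(k), rng, config.rarity_skew, config.class_patchiness
        )
        assign(4, [part + next_label], [reg])
        next_label += int(k)

    return Reefscape(reef_fraction=frac, labels=labels, cell_size_km=config.cell_size_km)


def generate_fishers(
    reefscape: Reefscape,
    n_centres: int,
    seed: int,
    population_range: tuple[float, float] = (5.0, 200.0),
) -> FisherPopulation:
    """Place fisher population centres at random grid cells.

    Population sizes are drawn log-uniformly over ``population_range`` —
    a crude stand-in for the skewed village-size distributions of census
    data.
    """
    if n_centres < 1:
        raise ValueError("n_centres must be >= 1")
    rng = np.random.default_rng(seed)
    rows, cols = reefscape.shape
    flat = rng.choice(rows * cols, size=n_centres, replace=False)
    lo, hi = population_range
    pops = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_centres))
    centres = tuple(
        (int(f // cols), int(f % cols), float(p)) for f, p in zip(flat, pops)
    )
    return FisherPopulation(centres=centres)


def generate_variable_cost(
    reefscape: Reefscape,
    fishers: FisherPopulation,
    decay_radius_km: float,
) -> CostSurface:
    """Population-weighted linear distance-decay cost surface.

    Cell cost is ``sum_over_centres pop * max(eps, 1 - d / decay_radius_km)``
    with ``d`` the Euclidean centre-to-centre distance in km: cost is
    maximal adjacent to large fisher populations and declines linearly with
    distance, floored at ``eps = 1e-6`` so it never truncates to zero.
    """
    if decay_radius_km <= 0:
        raise ValueError("decay_radius_km must be positive")
    fishers.validate_on(reefscape.shape)
    rows, cols = reefscape.shape
    cs = reefscape.cell_size_km
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x = (cc + 0.5) * cs
    y = (rr + 0.5) * cs
    cost = np.zeros((rows, cols), dtype=float)
    for r, c, pop in fishers.centres:
        d = np.hypot(x - (c + 0.5) * cs, y - (r + 0.5) * cs)
        cost += pop * np.maximum(COST_FLOOR, 1.0 - d / decay_radius_km)
    return CostSurface(variable_cost=cost)
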