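"""Spatial nestedness of priorities and incidental representation.

Nestedness: the percentage of high-priority small planning units from a
fine-resolution "test" scenario (selection frequency at or above a
threshold of 50 or 75 out of 100) that fall inside high-priority areas of a
coarse large-unit scenario (large units broadcast their frequency to their
nested small units).  The denominator is always the test set, so the
measure is directional.

Incidental representation: large-unit selection frequencies are converted
to selection probabilities P = frequency / R; the expected reserved area of
each finest-level (level 5) reef class is the probability-weighted sum of
the class areas over planning units.  Each class also gets its rarity,
``(1 - class_extent / total_planning_extent) * 100``, which is large for
restricted classes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annealer import SelectionFrequency
from .stats import rasterize_to_small

__all__ = [
    "HighPrioritySet",
    "NestednessResult",
    "high_priority",
    "nestedness",
    "nestedness_grid",
    "expected_contributions",
    "expected_representation",
    "rarity",
    "round3",
]

DEFAULT_THRESHOLDS = (50, 75)
DEFAULT_TEST_CODES = ("S5U", "S5V")


def round3(x: float) -> float:
    """Round half away from zero to 3 decimals (export convention; avoids
    float banker's-rounding surprises like 0.17775 -> 0.177)."""
    return math.floor(abs(x) * 1000 + 0.5) / 1000 * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class HighPrioritySet:
    """Small planning units whose selection frequency meets a threshold."""

    code: str
    threshold: int
    small_pu_ids: frozenset[int]


@dataclass(frozen=True)
class NestednessResult:
    test_code: str
    coarse_code: str
    threshold: int
    percent_nested: float


def high_priority(
    frequency: SelectionFrequency | pd.Series,
    threshold: int,
    nesting: dict[int, list[int]] | None = None,
    small_ids=None,
    code: str = "",
) -> HighPrioritySet:
    """Units with selection frequency >= threshold (inclusive).

    For large-unit scenarios pass the nesting map (and the small-unit id
    universe): frequencies are broadcast to component small units first, so
    the returned set is always at small-unit resolution.  An empty set is
    returned with a warning.
    """
    counts = frequency.counts if isinstance(frequency, SelectionFrequency) else frequency
    R = frequency.R if isinstance(frequency, SelectionFrequency) else None
    if threshold <= 0 or (R is not None and threshold > R):
        raise ValueError(f"threshold must be in (0, R]; got {threshold}")
    if nesting is not None:
        if small_ids is None:
            raise ValueError("small_ids required when broadcasting large units")
        counts = rasterize_to_small(counts, nesting, small_ids)
    members = frozenset(int(i) for i, v in counts.items() if v >= threshold)
    if not members:
        warnings.warn(
            f"high-priority set for {code or 'scenario'} at threshold {threshold} "
            "is empty; nestedness against it is undefined"
        )
    return HighPrioritySet(code=code, threshold=threshold, small_pu_ids=members)


def nestedness(test: HighPrioritySet, coarse: HighPrioritySet) -> NestednessResult:
    """Percent of the test set contained in the coarse set.

    Directional: the denominator is the test set.  An empty test set is an
    error (distinct from a genuine 0%).
    """
    if not test.small_pu_ids:
        raise ValueError(
            f"nestedness of an empty test set ({test.code}) is undefined"
        )
    inter = len(test.small_pu_ids & coarse.small_pu_ids)
    return NestednessResult(
        test_code=test.code,
        coarse_code=coarse.code,
        threshold=test.threshold,
        percent_nested=100.0 * inter / len(test.small_pu_ids),
    )


def nestedness_grid(
    results,
    grid,
    test_codes=DEFAULT_TEST_CODES,
    thresholds=None,
) -> pd.DataFrame:
    """Nestedness of each test scenario inside every large-unit scenario, at
    every threshold (by default the 10 x 2 x 2 comparison grid).

    Default thresholds are 50 and 75 counts out of R = 100 replicates,
    scaled proportionally when R differs.
    """
    small_ids = grid.small_ids
    coarse_codes = [c for c in sorted(results) if c.startswith("L")]
    if thresholds is None:
        R = next(iter(results.values())).frequency.R
        thresholds = tuple(
            max(1, round(t * R / 100)) for t in DEFAULT_THRESHOLDS
        )
    rows = []
    for thr in thresholds:
        tests = {
            t: high_priority(results[t].frequency, thr, code=t) for t in test_codes
        }
        for c in coarse_codes:
            coarse = high_priority(
                results[c].frequency,
                thr,
                nesting=grid.nesting,
                small_ids=small_ids,
                code=c,
            )
            for t in test_codes:
                r = nestedness(tests[t], coarse)
                rows.append(
                    {
                        "test": t,
                        "coarse": c,
                        "threshold": thr,
                        "percent_nested": r.percent_nested,
                    }
                )
    return pd.DataFrame(rows)


def expected_contributions(
    frequency: SelectionFrequency, features: pd.DataFrame
) -> pd.DataFrame:
    """Per (planning unit, class) expected reserved area.

    Columns: pu_id, class_id, frequency, probability (= frequency / R),
    amount_km2 and expected_km2 = probability x amount.  Full precision is
    kept; apply :func:`round3` only at export.
    """
    counts = frequency.counts
    df = features[["pu_id", "class_id", "amount_km2"]].copy()
    df["frequency"] = df["pu_id"].map(counts).fillna(0.0)
    df["probability"] = df["frequency"] / frequency.R
    df["expected_km2"] = df["probability"] * df["amount_km2"]
    return df[
        ["pu_id", "class_id", "frequency", "probability", "amount_km2", "expected_km2"]
    ]


def expected_representation(
    frequency: SelectionFrequency,
    features: pd.DataFrame,
    target_prop: float = 0.30,
) -> pd.DataFrame:
    """Expected reserved area per finest-level class, with rarity.

    ``features`` is the level-5 feature table of the same grid the
    frequencies refer to (large units, before any broadcasting).  Returns
    one row per class: expected_area_km2, percent_of_class, rarity_percent
    and whether the expected area meets ``target_prop`` of the class total.
    """
    contrib = expected_contributions(frequency, features)
    expected = contrib.groupby("class_id")["expected_km2"].sum()
    totals = features.groupby("class_id")["amount_km2"].sum()
    total_extent = float(totals.sum())
    out = pd.DataFrame(
        {
            "class_id": totals.index,
            "class_total_km2": totals.to_numpy(),
            "expected_area_km2": expected.reindex(totals.index).fillna(0.0).to_numpy(),
        }
    )
    out["percent_of_class"] = 100.0 * out["expected_area_km2"] / out["class_total_km2"]
    out["rarity_percent"] = [
        rarity(e, total_extent) for e in out["class_total_km2"]
    ]
    out["meets_target"] = out["expected_area_km2"] >= target_prop * out["class_total_km2"]
    return out.reset_index(drop=True)


def rarity(class_extent_km2: float, total_planning_extent_km2: float) -> float:
    """Rarity percentage: (1 - class extent / total planning extent) x 100.

    Strictly decreasing in class extent; 0 for a class covering the whole
    planning extent, approaching 100 for vanishingly restricted classes.
    """
    if class_extent_km2 <= 0:
        raise ValueError("class extent must be positive")
    if class_extent_km2 > total_planning_extent_km2:
        raise ValueError("class extent cannot exceed the planning extent")
    return (1.0 - class_extent_km2 / total_planning_extent_km2) * 100.0
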