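"""Marxan-style minimum-set reserve selection.

The problem: choose a subset of planning units that represents at least a
target amount ``T_f = prop * total_f`` of every feature (reef class) at
least total cost.  The objective minimised is

    score(S) = sum_{i in S} c_i  +  sum_f spf_f * s_f / T_f

where ``s_f = max(0, T_f - R_f)`` is the representation shortfall of
feature ``f`` and ``spf_f`` its species penalty factor.  Normalising the
shortfall by the target makes the penalty scale-free across thematic
levels; calibration (doubling any spf whose feature misses its target in
any replicate) drives all shortfalls to zero, after which the score of a
solution is exactly its cost.

Optimisation is simulated annealing (uniform single-unit flip proposals,
geometric cooling, Metropolis acceptance) followed by strict-descent
iterative improvement sweeps, as in the Marxan family of tools; an
exhaustive-enumeration oracle is provided for small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._kernels import anneal_kernel

__all__ = [
    "Problem",
    "Solution",
    "AnnealSchedule",
    "SelectionFrequency",
    "CalibrationResult",
    "CalibrationError",
    "objective",
    "anneal",
    "brute_force_optimum",
    "run_replicates",
    "calibrate_spf",
    "min_proportion_met",
]

#: default proportion of each feature's total amount that must be represented
DEFAULT_TARGET_PROP = 0.30

_SEED_MASK = 0x7FFFFFFF


@dataclass
class Problem:
    """A minimum-set instance in CSR form.

    ``indptr``/``feat_idx``/``feat_amt`` give, for each unit (in ``pu_ids``
    order), the features it contains and the amounts; ``areas`` are reef
    areas (km^2) used for reserve-extent reporting and may differ from
    ``costs`` (variable-cost scenarios).
    """

    pu_ids: np.ndarray
    costs: np.ndarray
    areas: np.ndarray
    feature_ids: np.ndarray
    indptr: np.ndarray
    feat_idx: np.ndarray
    feat_amt: np.ndarray
    prop: float = DEFAULT_TARGET_PROP
    spf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pu_ids = np.asarray(self.pu_ids, dtype=np.int64)
        self.costs = np.asarray(self.costs, dtype=np.float64)
        self.areas = np.asarray(self.areas, dtype=np.float64)
        self.feature_ids = np.asarray(self.feature_ids)
        self.indptr = np.asarray(self.indptr, dtype=np.int64)
        self.feat_idx = np.asarray(self.feat_idx, dtype=np.int64)
        self.feat_amt = np.asarray(self.feat_amt, dtype=np.float64)
        if (self.costs <= 0).any():
            raise ValueError("every unit must have positive cost")
        if not 0 < self.prop <= 1:
            raise ValueError("target proportion must be in (0, 1]")
        if (self.totals <= 0).any():
            raise ValueError("every feature must have positive total amount")
        if self.spf is None:
            self.spf = np.full(self.n_features, float(self.costs.mean()))
        self.spf = np.asarray(self.spf, dtype=np.float64)
        if (self.spf < 0).any():
            raise ValueError("spf must be non-negative")

    @property
    def n_units(self) -> int:
        return self.pu_ids.size

    @property
    def n_features(self) -> int:
        return self.feature_ids.size

    @property
    def totals(self) -> np.ndarray:
        return np.bincount(
            self.feat_idx, weights=self.feat_amt, minlength=self.n_features
        )

    @property
    def targets(self) -> np.ndarray:
        return self.prop * self.totals

    @classmethod
    def from_tables(
        cls,
        features: pd.DataFrame,
        costs: pd.Series,
        areas: pd.Series,
        prop: float = DEFAULT_TARGET_PROP,
        spf: np.ndarray | None = None,
    ) -> "Problem":
        """Build from a feature table ``(pu_id, class_id, amount_km2)`` plus
        per-unit cost and reef-area series indexed by pu_id."""
        pu_ids = np.asarray(sorted(costs.index), dtype=np.int64)
        fids = np.asarray(sorted(features["class_id"].unique()))
        fpos = {f: i for i, f in enumerate(fids.tolist())}
        ppos = {p: i for i, p in enumerate(pu_ids.tolist())}
        by_unit: list[list[tuple[int, float]]] = [[] for _ in pu_ids]
        for p, f, a in features[["pu_id", "class_id", "amount_km2"]].itertuples(
            index=False
        ):
            if p not in ppos:
                raise ValueError(f"feature table references unknown unit {p}")
            if a > 0:
                by_unit[ppos[p]].append((fpos[f], float(a)))
        indptr = np.zeros(len(pu_ids) + 1, dtype=np.int64)
        feat_idx: list[int] = []
        feat_amt: list[float] = []
        for i, lst in enumerate(by_unit):
            for fi, a in lst:
                feat_idx.append(fi)
                feat_amt.append(a)
            indptr[i + 1] = len(feat_idx)
        return cls(
            pu_ids=pu_ids,
            costs=costs.loc[pu_ids].to_numpy(),
            areas=areas.loc[pu_ids].to_numpy(),
            feature_ids=fids,
            indptr=indptr,
            feat_idx=np.asarray(feat_idx, dtype=np.int64),
            feat_amt=np.asarray(feat_amt, dtype=np.float64),
            prop=prop,
            spf=spf,
        )

    def with_spf(self, spf: np.ndarray) -> "Problem":
        return replace(self, spf=np.asarray(spf, dtype=np.float64))

    def _mask_from_ids(self, selected: Iterable[int]) -> np.ndarray:
        sel_set = set(int(i) for i in selected)
        unknown = sel_set - set(self.pu_ids.tolist())
        if unknown:
            raise ValueError(f"selected ids not in problem: {sorted(unknown)}")
        return np.isin(self.pu_ids, list(sel_set))

    def representation(self, mask: np.ndarray) -> np.ndarray:
        rep = np.zeros(self.n_features)
        for i in np.nonzero(mask)[0]:
            sl = slice(self.indptr[i], self.indptr[i + 1])
            np.add.at(rep, self.feat_idx[sl], self.feat_amt[sl])
        return rep


@dataclass(frozen=True)
class Solution:
    """A selected-unit set with its metrics."""

    selected: np.ndarray  # sorted pu ids
    total_cost: float
    total_extent_km2: float
    representation: pd.Series  # per feature id
    shortfall: pd.Series
    objective_value: float
    seed: int | None = None


@dataclass(frozen=True)
class AnnealSchedule:
    """Annealing schedule: geometric cooling from t_initial to t_final over
    n_iterations flips, then up to improvement_passes descent sweeps."""

    n_iterations: int = 100_000
    t_initial: float = 1.0
    t_final: float = 1e-6
    improvement_passes: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not self.t_initial >= self.t_final > 0:
            raise ValueError("need t_initial >= t_final > 0")
        if self.improvement_passes < 1:
            raise ValueError("improvement_passes must be >= 1")

    @property
    def cooling(self) -> float:
        return (self.t_final / self.t_initial) ** (1.0 / self.n_iterations)

    @classmethod
    def for_problem(
        cls, problem: Problem, n_iterations: int = 100_000, seed: int = 0
    ) -> "AnnealSchedule":
        """Scale the temperature range to the problem's cost magnitude.

        The walk starts warm enough to accept typical single-unit cost
        increases (2x the mean unit cost) and freezes at 5% of it, where
        only near-neutral moves still pass.
        """
        scale = float(problem.costs.mean())
        return cls(
            n_iterations=n_iterations,
            t_initial=2.0 * scale,
            t_final=0.05 * scale,
            seed=seed,
        )


@dataclass(frozen=True)
class SelectionFrequency:
    """Count of replicate solutions (out of R) selecting each unit."""

    counts: pd.Series  # indexed by pu_id
    R: int

    def __post_init__(self) -> None:
        if ((self.counts < 0) | (self.counts > self.R)).any():
            raise ValueError("frequencies must lie in [0, R]")


class CalibrationError(RuntimeError):
    def __init__(self, feature_ids: Sequence, rounds: int):
        self.feature_ids = list(feature_ids)
        super().__init__(
            f"spf calibration failed after {rounds} rounds for features "
            f"{self.feature_ids}"
        )


@dataclass
class CalibrationResult:
    spf: np.ndarray
    rounds: int
    solutions: list[Solution]
    frequency: SelectionFrequency
    min_proportion: float


def objective(problem: Problem, selected: Iterable[int]) -> float:
    """Score of a selection: total cost plus normalised shortfall penalties.

    Zero-shortfall selections score exactly their cost.
    """
    mask = problem._mask_from_ids(selected)
    rep = problem.representation(mask)
    targets = problem.targets
    short = np.maximum(0.0, targets - rep)
    return float(problem.costs[mask].sum() + (problem.spf * short / targets).sum())


def _solution_from_mask(
    problem: Problem, mask: np.ndarray, seed: int | None
) -> Solution:
    rep = problem.representation(mask)
    targets = problem.targets
    short = np.maximum(0.0, targets - rep)
    score = float(problem.costs[mask].sum() + (problem.spf * short / targets).sum())
    return Solution(
        selected=np.sort(problem.pu_ids[mask]),
        total_cost=float(problem.costs[mask].sum()),
        total_extent_km2=float(problem.areas[mask].sum()),
        representation=pd.Series(rep, index=problem.feature_ids),
        shortfall=pd.Series(short, index=problem.feature_ids),
        objective_value=score,
        seed=seed,
    )


def anneal(
    problem: Problem,
    schedule: AnnealSchedule | None = None,
    seed: int | None = None,
    init_prob: float = 0.5,
) -> Solution:
    """Run one annealing replicate (plus iterative improvement).

    ``seed`` overrides ``schedule.seed``; the run is deterministic given
    (problem, schedule, seed).
    """
    if schedule is None:
        schedule = AnnealSchedule.for_problem(problem)
    use_seed = schedule.seed if seed is None else seed
    sel = anneal_kernel(
        problem.costs,
        problem.indptr,
        problem.feat_idx,
        problem.feat_amt,
        problem.targets,
        problem.spf,
        schedule.n_iterations,
        schedule.t_initial,
        schedule.cooling,
        schedule.improvement_passes,
        init_prob,
        int(use_seed) & _SEED_MASK,
    )
    return _solution_from_mask(problem, sel.astype(bool), use_seed)


def brute_force_optimum(problem: Problem, max_units: int = 20) -> Solution:
    """Exhaustive enumeration oracle for small instances (<= 20 units).

    Ties on the objective are broken toward fewer units, then toward the
    lexicographically smallest id set.
    """
    n = problem.n_units
    if n > max_units:
        raise ValueError(f"brute force refused: {n} units > {max_units}")
    amounts = np.zeros((n, problem.n_features))
    for i in range(n):
        sl = slice(problem.indptr[i], problem.indptr[i + 1])
        np.add.at(amounts[i], problem.feat_idx[sl], problem.feat_amt[sl])
    targets = problem.targets
    wf = problem.spf / targets

    best_score = np.inf
    candidates: list[int] = []
    tol = 1e-9
    chunk = 1 << 16
    total = 1 << n
    shifts = np.arange(n)
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total), dtype=np.int64)
        bits = ((idx[:, None] >> shifts) & 1).astype(np.float64)
        cost = bits @ problem.costs
        short = np.clip(targets[None, :] - bits @ amounts, 0.0, None)
        score = cost + short @ wf
        m = float(score.min())
        if m < best_score - tol:
            best_score = m
            candidates = []
        keep = np.nonzero(score <= best_score + tol)[0]
        candidates.extend((idx[keep]).tolist())

    def key(maskint: int):
        ids = tuple(
            int(problem.pu_ids[i]) for i in range(n) if (maskint >> i) & 1
        )
        return (len(ids), ids)

    best = min(candidates, key=key)
    mask = np.array([(best >> i) & 1 for i in range(n)], dtype=bool)
    return _solution_from_mask(problem, mask, None)


def run_replicates(
    problem: Problem,
    R: int,
    base_seed: int,
    schedule: AnnealSchedule | None = None,
) -> tuple[list[Solution], SelectionFrequency]:
    """R independent replicates (seed ``base_seed + r``) plus the selection
    frequency of every unit across them."""
    if R < 1:
        raise ValueError("R must be >= 1")
    if schedule is None:
        schedule = AnnealSchedule.for_problem(problem)
    solutions = [anneal(problem, schedule, seed=base_seed + r) for r in range(R)]
    counts = np.zeros(problem.n_units, dtype=int)
    pos = {int(p): i for i, p in enumerate(problem.pu_ids)}
    for s in solutions:
        for p in s.selected:
            counts[pos[int(p)]] += 1
    freq = SelectionFrequency(
        counts=pd.Series(counts, index=pd.Index(problem.pu_ids, name="pu_id")), R=R
    )
    return solutions, freq


def min_proportion_met(problem: Problem, solutions: Sequence[Solution]) -> float:
    """Min over features and solutions of achieved/target representation."""
    targets = problem.targets
    return min(
        float((s.representation.to_numpy() / targets).min()) for s in solutions
    )


def calibrate_spf(
    problem: Problem,
    R_cal: int = 100,
    criterion: float = 0.999,
    base_seed: int = 0,
    schedule: AnnealSchedule | None = None,
    max_rounds: int = 20,
    growth: float = 2.0,
) -> CalibrationResult:
    """Calibrate species penalty factors until every feature exceeds the
    representation criterion in every one of ``R_cal`` replicates.

    Starting from spf equal to the mean unit cost, each round runs R_cal
    replicates; any feature whose minimum achieved proportion of target is
    <= ``criterion`` has its spf multiplied by ``growth``.  Fails loudly
    (naming the offending features) if the criterion is not reached within
    ``max_rounds``.
    """
    if not 0 < criterion <= 1:
        raise ValueError("criterion must be in (0, 1]")
    spf = np.full(problem.n_features, float(problem.costs.mean()))
    targets = problem.targets
    for rounds in range(1, max_rounds + 1):
        prob = problem.with_spf(spf)
        solutions, freq = run_replicates(prob, R_cal, base_seed, schedule)
        props = np.vstack(
            [s.representation.to_numpy() / targets for s in solutions]
        )
        min_props = props.min(axis=0)
        failing = min_props <= criterion
        if not failing.any():
            return CalibrationResult(
                spf=spf,
                rounds=rounds,
                solutions=solutions,
                frequency=freq,
                min_proportion=float(min_props.min()),
            )
        spf = spf.copy()
        spf[failing] *= growth
    raise CalibrationError(
        problem.feature_ids[np.nonzero(failing)[0]].tolist(), max_rounds
    )
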