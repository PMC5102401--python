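"""Minimum-set solver: objective, annealing, oracle, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reefprior.annealer import (
    AnnealSchedule,
    CalibrationError,
    Problem,
    anneal,
    brute_force_optimum,
    calibrate_spf,
    min_proportion_met,
    objective,
    run_replicates,
)

from conftest import random_toy_problem


def toy3(prop=0.3, spf=1.0):
    """Three units (costs 1, 2, 3); one feature with amounts 10, 0, 20."""
    feats = pd.DataFrame(
        {"pu_id": [1, 3], "class_id": [0, 0], "amount_km2": [10.0, 20.0]}
    )
    ids = pd.Index([1, 2, 3])
    costs = pd.Series([1.0, 2.0, 3.0], index=ids)
    return Problem.from_tables(feats, costs, costs, prop=prop, spf=np.array([spf]))


def test_objective_empty_selection_pays_full_penalty():
    p = toy3(spf=1.0)
    assert objective(p, []) == pytest.approx(1.0)


def test_objective_saturation_is_total_cost():
    p = toy3(spf=1.0)
    assert objective(p, [1, 2, 3]) == pytest.approx(6.0)


def test_objective_toy_hand_value():
    # target 0.3 * 30 = 9; unit 1 alone holds 10 >= 9 -> score is just cost 1
    p = toy3(spf=1.0)
    assert objective(p, [1]) == pytest.approx(1.0)


@given(st.integers(0, 50))
def test_increasing_spf_never_decreases_score(seed):
    rng = np.random.default_rng(seed)
    p = random_toy_problem(rng, n_range=(5, 10), spf=1.0)
    sel = [int(i) for i in p.pu_ids[rng.random(p.n_units) < 0.4]]
    base = objective(p, sel)
    bumped = p.with_spf(p.spf * rng.uniform(1.0, 10.0, p.n_features))
    assert objective(bumped, sel) >= base - 1e-12


def test_brute_force_prefers_cheap_sufficient_unit():
    feats = pd.DataFrame(
        {"pu_id": [1, 2], "class_id": [0, 0], "amount_km2": [10.0, 10.0]}
    )
    ids = pd.Index([1, 2])
    costs = pd.Series([1.0, 5.0], index=ids)
    p = Problem.from_tables(feats, costs, costs, spf=np.array([100.0]))
    sol = brute_force_optimum(p)
    assert sol.selected.tolist() == [1]


def test_brute_force_toy_with_high_target():
    # target 25 of 30 forces both feature-bearing units: {1, 3}, score 4
    p = toy3(prop=25 / 30, spf=100.0)
    sol = brute_force_optimum(p)
    assert sol.selected.tolist() == [1, 3]
    assert sol.objective_value == pytest.approx(4.0)


def test_brute_force_refuses_large_instances():
    rng = np.random.default_rng(0)
    p = random_toy_problem(rng, n_range=(21, 22))
    with pytest.raises(ValueError, match="brute force"):
        brute_force_optimum(p)


def test_anneal_forced_single_unit():
    feats = pd.DataFrame({"pu_id": [1], "class_id": [0], "amount_km2": [10.0]})
    ids = pd.Index([1])
    costs = pd.Series([1.0], index=ids)
    p = Problem.from_tables(feats, costs, costs, spf=np.array([100.0]))
    sol = anneal(p, AnnealSchedule.for_problem(p, 1000), seed=5)
    assert sol.selected.tolist() == [1]
    assert sol.objective_value == pytest.approx(1.0)


def test_anneal_deterministic_given_seed():
    rng = np.random.default_rng(4)
    p = random_toy_problem(rng)
    sched = AnnealSchedule.for_problem(p, 5000)
    a = anneal(p, sched, seed=77)
    b = anneal(p, sched, seed=77)
    assert np.array_equal(a.selected, b.selected)
    assert a.objective_value == b.objective_value


def test_anneal_never_beats_oracle():
    rng = np.random.default_rng(8)
    for i in range(10):
        p = random_toy_problem(rng, n_range=(8, 13))
        bf = brute_force_optimum(p)
        an = anneal(p, AnnealSchedule.for_problem(p, 5000), seed=i)
        assert an.objective_value >= bf.objective_value - 1e-9


def test_zero_temperature_reduces_to_strict_descent():
    # with t_initial = t_final = 1e-12, acceptance is pure descent: the
    # result must be single-flip locally optimal
    rng = np.random.default_rng(12)
    p = random_toy_problem(rng, n_range=(8, 12))
    sched = AnnealSchedule(n_iterations=5000, t_initial=1e-12, t_final=1e-12)
    sol = anneal(p, sched, seed=3)
    sel = set(sol.selected.tolist())
    for u in p.pu_ids.tolist():
        assert objective(p, sel ^ {u}) >= sol.objective_value - 1e-9


def test_global_optimum_is_single_flip_stable():
    rng = np.random.default_rng(21)
    for _ in range(10):
        p = random_toy_problem(rng, n_range=(8, 14))
        bf = brute_force_optimum(p)
        sel = set(bf.selected.tolist())
        for u in p.pu_ids.tolist():
            assert objective(p, sel ^ {u}) >= bf.objective_value - 1e-12


def test_replicates_single_run_is_indicator():
    rng = np.random.default_rng(30)
    p = random_toy_problem(rng)
    sols, freq = run_replicates(p, R=1, base_seed=9)
    assert freq.R == 1
    sel = set(sols[0].selected.tolist())
    for pu, f in freq.counts.items():
        assert f == (1 if pu in sel else 0)


def test_replicates_forced_unit_has_full_frequency():
    feats = pd.DataFrame({"pu_id": [1], "class_id": [0], "amount_km2": [10.0]})
    ids = pd.Index([1])
    costs = pd.Series([1.0], index=ids)
    p = Problem.from_tables(feats, costs, costs, spf=np.array([100.0]))
    _, freq = run_replicates(p, R=20, base_seed=1, schedule=AnnealSchedule.for_problem(p, 500))
    assert freq.counts[1] == 20


def test_calibration_noop_when_already_satisfied():
    # cheap unit covers the target under the initial spf (mean cost):
    # selecting it saves the penalty, so round 1 already passes
    feats = pd.DataFrame(
        {"pu_id": [1, 2], "class_id": [0, 0], "amount_km2": [10.0, 10.0]}
    )
    ids = pd.Index([1, 2])
    costs = pd.Series([0.2, 5.0], index=ids)
    p = Problem.from_tables(feats, costs, costs)
    cal = calibrate_spf(p, R_cal=10, base_seed=0, schedule=AnnealSchedule.for_problem(p, 2000))
    assert cal.rounds == 1
    assert cal.spf == pytest.approx(np.array([costs.mean()]))


def test_calibrated_spf_exceeds_needed_unit_cost():
    # the single feature lives only in a unit of cost 10; all-or-nothing
    # representation means every local optimum includes it only once
    # spf >= 10, so calibration must push spf at least that high
    feats = pd.DataFrame({"pu_id": [1], "class_id": [0], "amount_km2": [1.0]})
    ids = pd.Index([1, 2, 3, 4])
    costs = pd.Series([10.0, 0.1, 0.1, 0.1], index=ids)
    p = Problem.from_tables(feats, costs, costs)
    cal = calibrate_spf(p, R_cal=10, base_seed=0, schedule=AnnealSchedule.for_problem(p, 2000))
    assert cal.spf[0] >= 10.0
    assert cal.min_proportion > 0.999


def test_calibration_failure_names_features():
    feats = pd.DataFrame({"pu_id": [1], "class_id": [7], "amount_km2": [1.0]})
    ids = pd.Index([1, 2])
    costs = pd.Series([10.0, 0.1], index=ids)
    p = Problem.from_tables(feats, costs, costs)
    with pytest.raises(CalibrationError, match="7"):
        calibrate_spf(
            p,
            R_cal=5,
            base_seed=0,
            schedule=AnnealSchedule.for_problem(p, 500),
            max_rounds=1,
        )


def test_min_proportion_met_after_calibration():
    rng = np.random.default_rng(55)
    p = random_toy_problem(rng, spf=1.0)
    cal = calibrate_spf(
        p, R_cal=20, base_seed=3, schedule=AnnealSchedule.for_problem(p, 5000)
    )
    assert min_proportion_met(p.with_spf(cal.spf), cal.solutions) > 0.999


def test_problem_validation():
    feats = pd.DataFrame({"pu_id": [1], "class_id": [0], "amount_km2": [1.0]})
    ids = pd.Index([1])
    with pytest.raises(ValueError, match="positive cost"):
        Problem.from_tables(feats, pd.Series([0.0], index=ids), pd.Series([1.0], index=ids))
    with pytest.raises(ValueError, match="proportion"):
        Problem.from_tables(
            feats, pd.Series([1.0], index=ids), pd.Series([1.0], index=ids), prop=1.5
        )
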