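"""Multivariate pipeline: broadcasting, Hellinger, UPGMA, RDA, permutation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.cluster.hierarchy import cophenet

from reefprior.stats import (
    average_linkage_cluster,
    euclidean_distance,
    hellinger,
    permutation_test,
    rasterize_to_small,
    rda,
)


# ---------------------------------------------------------------------------
# broadcasting to small-unit resolution


def test_large_unit_broadcasts_frequency_to_components():
    nesting = {1000001: list(range(1, 26))}
    out = rasterize_to_small(pd.Series({1000001: 50}), nesting, range(1, 26))
    assert (out == 50).all() and len(out) == 25


def test_partial_large_unit_broadcasts_to_its_edge_components():
    nesting = {1000001: list(range(1, 13))}
    out = rasterize_to_small(pd.Series({1000001: 1}), nesting, range(1, 31))
    assert out.loc[1:12].eq(1).all()
    assert out.loc[13:30].eq(0).all()


def test_small_rows_pass_through_unchanged():
    vals = pd.Series({2: 3.0, 5: 7.0})
    out = rasterize_to_small(vals, {}, range(1, 7))
    assert out[2] == 3.0 and out[5] == 7.0 and out.sum() == 10.0


def test_orphan_unit_is_rejected():
    with pytest.raises(KeyError, match="neither"):
        rasterize_to_small(pd.Series({42: 1.0}), {}, range(1, 6))


# ---------------------------------------------------------------------------
# Hellinger + distances


def test_hellinger_hand_rows():
    out = hellinger(np.array([[1.0, 0.0, 0.0]]))
    assert np.allclose(out, [[1, 0, 0]])
    out = hellinger(np.array([[1.0, 1.0, 1.0, 1.0]]))
    assert np.allclose(out, 0.5)


@given(st.integers(0, 100))
def test_hellinger_rows_have_unit_norm(seed):
    rng = np.random.default_rng(seed)
    m = rng.uniform(0, 5, size=(6, 9)) * (rng.random((6, 9)) < 0.5)
    m[:, 0] += 0.01  # no all-zero rows
    h = hellinger(m)
    assert np.allclose((h**2).sum(axis=1), 1.0, atol=1e-12)


def test_hellinger_rejects_all_zero_rows():
    with pytest.raises(ValueError, match="all-zero"):
        hellinger(np.array([[1.0, 2.0], [0.0, 0.0]]))


def test_hellinger_euclidean_bounded_by_sqrt2_on_binary_rows():
    rng = np.random.default_rng(17)
    m = (rng.random((40, 25)) < 0.3).astype(float)
    m[:, 0] = 1.0
    d = euclidean_distance(hellinger(m))
    assert d.max() <= np.sqrt(2) + 1e-12


def test_distance_hand_values_and_oracle():
    h = np.array([[1.0, 0, 0], [0, 1.0, 0], [1.0, 0, 0]])
    d = euclidean_distance(h)
    assert d[0, 2] == 0.0
    assert d[0, 1] == pytest.approx(np.sqrt(2))
    rng = np.random.default_rng(3)
    m = rng.random((10, 6))
    d = euclidean_distance(m)
    naive = np.zeros((10, 10))
    for i in range(10):
        for j in range(10):
            naive[i, j] = np.sqrt(((m[i] - m[j]) ** 2).sum())
    assert np.allclose(d, naive)
    assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


# ---------------------------------------------------------------------------
# UPGMA


def naive_upgma_cophenetic(dist: np.ndarray) -> np.ndarray:
    """O(n^3) UPGMA oracle returning the cophenetic distance matrix.

    Ties are broken toward the lowest cluster-pair index.
    """
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {
        (i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)
    }
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        (a, b), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        merged = clusters.pop(a) + clusters.pop(b)
        new = {}
        for (i, j), v in d.items():
            if a in (i, j) or b in (i, j):
                continue
            new[(i, j)] = v
        for c, members in clusters.items():
            avg = np.mean([dist[i, j] for i in merged for j in members])
            new[(min(c, next_id), max(c, next_id))] = avg
        clusters[next_id] = merged
        d = new
        next_id += 1
    return coph


def test_two_points_merge_at_their_distance():
    d = np.array([[0.0, 3.0], [3.0, 0.0]])
    dend = average_linkage_cluster(d)
    assert dend.heights.tolist() == [3.0]


def test_three_point_hand_merge_order():
    d = np.array([[0.0, 1.0, 5.0], [1.0, 0.0, 5.0], [5.0, 5.0, 0.0]])
    dend = average_linkage_cluster(d)
    assert np.allclose(dend.heights, [1.0, 5.0])
    assert sorted(dend.linkage[0, :2]) == [0, 1]


def test_upgma_matches_naive_oracle_on_random_points():
    rng = np.random.default_rng(7)
    pts = rng.random((15, 4))
    d = euclidean_distance(pts)
    dend = average_linkage_cluster(d)
    assert np.allclose(cophenet(dend.linkage), euclidean_distance_condensed(d))


def euclidean_distance_condensed(d):
    from scipy.spatial.distance import squareform

    return squareform(naive_upgma_cophenetic(d), checks=False)


def test_merge_heights_non_decreasing_and_newick_roundtrips():
    rng = np.random.default_rng(9)
    d = euclidean_distance(rng.random((12, 3)))
    dend = average_linkage_cluster(d, labels=[f"s{i}" for i in range(12)])
    assert (np.diff(dend.heights) >= -1e-12).all()
    nwk = dend.to_newick()
    assert nwk.endswith(";") and nwk.count("s1") >= 1
    assert sorted(dend.leaf_order) == list(range(12))


# ---------------------------------------------------------------------------
# RDA


def two_factor_labels(n):
    return pd.DataFrame(
        {
            "cost": np.tile(["U", "V"], n // 2),
            "pu_size": np.repeat(["S", "L"], n // 2),
            "level": np.tile(np.repeat([1, 2, 3], n // 6), 2),
        }
    )


def test_rda_perfectly_explained_single_factor():
    g = np.repeat([0, 1], 6)
    Y = np.column_stack([g * 2.0, -g * 1.0, np.full(12, 3.0)])
    fac = pd.DataFrame({"group": np.where(g == 0, "a", "b")})
    res = rda(Y, fac, factor_order=("group",))
    assert res.residual_variance == pytest.approx(0.0, abs=1e-12)
    assert res.proportion_axes12 == pytest.approx(1.0)


def test_rda_constrained_equals_between_group_variance():
    rng = np.random.default_rng(5)
    Y = rng.normal(size=(30, 4))
    g = np.repeat([0, 1, 2], 10)
    fac = pd.DataFrame({"group": g.astype(str)})
    res = rda(Y, fac, factor_order=("group",))
    Yc = Y - Y.mean(axis=0)
    between = sum(
        10 * (Yc[g == k].mean(axis=0) ** 2).sum() for k in range(3)
    ) / (30 - 1)
    assert res.constrained_variance == pytest.approx(between, rel=1e-12)


def test_rda_variance_partition():
    rng = np.random.default_rng(11)
    Y = rng.normal(size=(24, 8))
    res = rda(Y, two_factor_labels(24))
    assert res.constrained_variance + res.residual_variance == pytest.approx(
        res.total_variance, rel=1e-9
    )
    eig = res.eigenvalues
    assert (eig >= 0).all() and (np.diff(eig) <= 1e-12).all()
    assert 0 <= res.proportion_axes12 <= 1
    for name, cent in res.centroids.items():
        assert len(cent) == len(set(two_factor_labels(24)[name]))


def test_rda_rejects_aliased_design():
    fac = two_factor_labels(24)
    fac["pu_size"] = fac["cost"].map({"U": "S", "V": "L"})  # perfectly aliased
    rng = np.random.default_rng(2)
    with pytest.raises(ValueError, match="alias"):
        rda(rng.normal(size=(24, 3)), fac)


def test_rda_and_permutation_match_vegan_reference():
    """Sequential variance decomposition and pseudo-F frozen from R vegan
    (rda + anova by='terms') on this exact fixture."""
    rng = np.random.default_rng(42)
    n = 24
    fac = two_factor_labels(n)
    Y = rng.normal(size=(n, 6)) + fac["level"].to_numpy()[:, None] * 0.5
    res = permutation_test(Y, fac, n_perm=199, seed=1)
    expected_var = [0.302187518965986, 0.10345970547523, 1.4156465582752]
    expected_F = [1.45894014780199, 0.499496201941324, 3.41732114885571]
    assert np.allclose(res.table["variance"], expected_var, rtol=1e-9)
    assert np.allclose(res.table["F"], expected_F, rtol=1e-9)
    r = rda(Y, fac)
    assert r.residual_variance == pytest.approx(3.93543413621448, rel=1e-9)


# ---------------------------------------------------------------------------
# permutation test


def test_permutation_degrees_of_freedom_and_floor():
    rng = np.random.default_rng(23)
    n = 40
    fac = pd.DataFrame(
        {
            "cost": np.tile(["U", "V"], n // 2),
            "pu_size": np.repeat(["S", "L"], n // 2),
            "level": np.tile(np.arange(5), n // 5),
        }
    )
    Y = rng.normal(size=(n, 5)) + (fac["cost"] == "V").to_numpy()[:, None] * 3
    res = permutation_test(Y, fac, n_perm=199, seed=0)
    assert res.table["df"].tolist() == [1, 1, 4]
    assert (res.table["p"] >= 1 / 200).all()
    assert res.table.loc["cost", "p"] == pytest.approx(1 / 200)


def test_permutation_deterministic_given_seed():
    rng = np.random.default_rng(31)
    Y = rng.normal(size=(24, 4))
    fac = two_factor_labels(24)
    a = permutation_test(Y, fac, n_perm=199, seed=9).table
    b = permutation_test(Y, fac, n_perm=199, seed=9).table
    pd.testing.assert_frame_equal(a, b)
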