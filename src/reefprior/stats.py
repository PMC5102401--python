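"""Multivariate comparison of reserve solutions as community data.

Individual reserve solutions are treated like ecological sampling sites and
small planning units like recorded species: the solutions x units matrix is
binary for individual solutions or holds selection frequencies (0..R) for
scenario rows.  Large-unit solutions are first rasterised to small-unit
resolution (each large unit broadcasts its value to its nested small
units).  Because the matrix is zero-inflated, rows are Hellinger-transformed
(square root of relative abundance) before Euclidean distances, average-
linkage clustering, redundancy analysis (RDA) constrained on the three
design factors, and a sequential permutation test of those factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .scenarios import ScenarioResult
from .tessellation import PUGrid

__all__ = [
    "rasterize_to_small",
    "compile_solution_matrix",
    "compile_frequency_matrix",
    "hellinger",
    "euclidean_distance",
    "average_linkage_cluster",
    "Dendrogram",
    "rda",
    "RDAResult",
    "permutation_test",
    "PermutationTestResult",
    "FACTOR_ORDER",
]

#: sequential decomposition order of the design factors
FACTOR_ORDER = ("cost", "pu_size", "level")


def rasterize_to_small(
    values: pd.Series, nesting: dict[int, list[int]], small_ids
) -> pd.Series:
    """Convert a per-unit vector to small-unit resolution.

    Small-unit entries pass through unchanged; a large unit broadcasts its
    value to every nested small unit (a large unit with selection frequency
    50 yields up-to-25 small entries of 50).  Units absent from the vector
    get 0.  Ids that are neither small units nor large units of the nesting
    map are rejected.
    """
    small_ids = list(small_ids)
    small_set = set(small_ids)
    out = pd.Series(0.0, index=pd.Index(small_ids, name="pu_id"))
    for pu, val in values.items():
        pu = int(pu)
        if pu in small_set:
            out.loc[pu] = val
        elif pu in nesting:
            for child in nesting[pu]:
                if child not in small_set:
                    raise KeyError(
                        f"small unit {child} of large unit {pu} missing from grid"
                    )
                out.loc[child] = val
        else:
            raise KeyError(f"unit {pu} is neither a small unit nor a known large unit")
    return out


def _factor_frame(res: ScenarioResult) -> dict:
    return {
        "scenario": res.code,
        "pu_size": res.scenario.pu_size,
        "level": res.scenario.level,
        "cost": res.scenario.cost,
    }


def compile_solution_matrix(
    results: dict[str, ScenarioResult], grid: PUGrid
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack all individual solutions into a binary solutions x small-units
    matrix plus the per-row factor labels."""
    small_ids = grid.small_ids
    rows, labels = [], []
    for code in sorted(results):
        res = results[code]
        for r, sol in enumerate(res.solutions):
            sel = pd.Series(1.0, index=pd.Index(sol.selected.tolist()))
            rows.append(rasterize_to_small(sel, grid.nesting, small_ids).to_numpy())
            labels.append({**_factor_frame(res), "replicate": r})
    Y = pd.DataFrame(
        np.vstack(rows),
        columns=pd.Index(small_ids, name="pu_id"),
        index=pd.Index(
            [f"{l['scenario']}_{l['replicate']:03d}" for l in labels], name="solution"
        ),
    )
    return Y, pd.DataFrame(labels, index=Y.index)


def compile_frequency_matrix(
    results: dict[str, ScenarioResult], grid: PUGrid
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One selection-frequency row per scenario (20 x small-units)."""
    small_ids = grid.small_ids
    rows, labels = [], []
    for code in sorted(results):
        res = results[code]
        rows.append(
            rasterize_to_small(
                res.frequency.counts, grid.nesting, small_ids
            ).to_numpy()
        )
        labels.append(_factor_frame(res))
    Y = pd.DataFrame(
        np.vstack(rows),
        columns=pd.Index(small_ids, name="pu_id"),
        index=pd.Index([l["scenario"] for l in labels], name="scenario"),
    )
    return Y, pd.DataFrame(labels, index=Y.index)


# ---------------------------------------------------------------------------
# transforms and distances


def _as_array(matrix) -> tuple[np.ndarray, object]:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), matrix
    return np.asarray(matrix, dtype=float), None


def hellinger(matrix):
    """Hellinger transform: entry' = sqrt(entry / row_sum).

    Every transformed row has unit Euclidean norm; all-zero rows (no
    relative abundances to form) are rejected.
    """
    arr, frame = _as_array(matrix)
    if (arr < 0).any():
        raise ValueError("entries must be non-negative")
    sums = arr.sum(axis=1)
    if (sums <= 0).any():
        bad = np.nonzero(sums <= 0)[0].tolist()
        raise ValueError(f"all-zero rows cannot be Hellinger-transformed: {bad}")
    out = np.sqrt(arr / sums[:, None])
    if frame is not None:
        return pd.DataFrame(out, index=frame.index, columns=frame.columns)
    return out


def euclidean_distance(matrix) -> np.ndarray:
    """Square symmetric Euclidean distance matrix between rows."""
    arr, _ = _as_array(matrix)
    return squareform(pdist(arr, metric="euclidean"))


@dataclass
class Dendrogram:
    """Average-linkage merge tree (UPGMA on a precomputed distance matrix)."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[int]:
        return hierarchy.leaves_list(self.linkage).tolist()

    def to_newick(self) -> str:
        """Export as a Newick string with merge-height branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def average_linkage_cluster(dist: np.ndarray, labels=None) -> Dendrogram:
    """UPGMA (unweighted average linkage) on a square distance matrix."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("need a square distance matrix")
    if not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    if labels is None:
        labels = [str(i) for i in range(dist.shape[0])]
    return Dendrogram(linkage=Z, labels=list(labels))


# ---------------------------------------------------------------------------
# constrained ordination


def _design_blocks(
    factors: pd.DataFrame, factor_order=FACTOR_ORDER
) -> tuple[np.ndarray, list[tuple[str, slice, int]]]:
    """Reference-coded design matrix (intercept first) plus per-factor
    column blocks in sequential order.  df per factor = levels - 1."""
    n = len(factors)
    cols = [np.ones((n, 1))]
    blocks: list[tuple[str, slice, int]] = []
    start = 1
    for name in factor_order:
        if name not in factors.columns:
            raise ValueError(f"factor {name!r} missing from labels")
        levels = sorted(pd.unique(factors[name]))
        if len(levels) < 2:
            raise ValueError(f"factor {name!r} has a single level: aliased term")
        dummies = np.column_stack(
            [(factors[name] == lev).to_numpy(float) for lev in levels[1:]]
        )
        cols.append(dummies)
        df = len(levels) - 1
        blocks.append((name, slice(start, start + df), df))
        start += df
    X = np.hstack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient design: aliased terms among "
            + ", ".join(b[0] for b in blocks)
        )
    return X, blocks


def _sequential_basis(
    X: np.ndarray, blocks
) -> list[tuple[str, np.ndarray, int]]:
    """Orthonormal bases of each factor's column block after removing the
    intercept and all preceding factors (sequential, type-I)."""
    n = X.shape[0]
    Qprev = X[:, :1] / np.sqrt(n)
    out = []
    for name, sl, df in blocks:
        B = X[:, sl]
        B = B - Qprev @ (Qprev.T @ B)
        Qb, Rb = np.linalg.qr(B)
        if np.abs(np.diag(Rb)).min() < 1e-10:
            raise ValueError(f"factor {name!r} is aliased with preceding terms")
        out.append((name, Qb, df))
        Qprev = np.hstack([Qprev, Qb])
    return out


@dataclass
class RDAResult:
    """Redundancy analysis of a (transformed) response matrix on the design.

    Eigenvalues and variances are on the covariance scale (sums of squares
    divided by n - 1).  ``proportion_axes12`` is the share of *constrained*
    variance carried by the first two ordination axes.
    """

    eigenvalues: np.ndarray
    site_scores: pd.DataFrame  # axes RDA1, RDA2
    centroids: dict[str, pd.DataFrame]  # factor -> level centroids on axes 1-2
    factor_variance: pd.Series  # sequential variance per factor
    constrained_variance: float
    residual_variance: float
    total_variance: float
    proportion_axes12: float


def rda(
    matrix, factors: pd.DataFrame, factor_order=FACTOR_ORDER
) -> RDAResult:
    """RDA: PCA of the fitted values of a multivariate regression of the
    (column-centred) response on the reference-coded design factors."""
    arr, frame = _as_array(matrix)
    n = arr.shape[0]
    if len(factors) != n:
        raise ValueError("factor labels must match matrix rows")
    Yc = arr - arr.mean(axis=0, keepdims=True)
    X, blocks = _design_blocks(factors, factor_order)
    Q, _ = np.linalg.qr(X)
    fitted = Q @ (Q.T @ Yc)

    denom = n - 1
    total = float((Yc**2).sum()) / denom
    constrained = float((fitted**2).sum()) / denom
    residual = total - constrained

    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    eig = s**2 / denom
    keep = eig > max(1e-12, eig[0] * 1e-12) if eig.size else eig > 0
    eig = eig[keep]
    n_axes = min(2, eig.size)
    scores = U[:, :n_axes] * s[:n_axes]
    index = frame.index if frame is not None else pd.RangeIndex(n)
    site_scores = pd.DataFrame(
        scores, index=index, columns=[f"RDA{i + 1}" for i in range(n_axes)]
    )

    centroids = {}
    for name in factor_order:
        centroids[name] = site_scores.groupby(factors[name].to_numpy()).mean()

    seq = _sequential_basis(X, blocks)
    fv = pd.Series(
        {name: float(((Qb.T @ Yc) ** 2).sum()) / denom for name, Qb, _ in seq},
        name="variance",
    )
    prop12 = float(eig[:2].sum() / eig.sum()) if eig.size else 0.0
    return RDAResult(
        eigenvalues=eig,
        site_scores=site_scores,
        centroids=centroids,
        factor_variance=fv,
        constrained_variance=constrained,
        residual_variance=residual,
        total_variance=total,
        proportion_axes12=prop12,
    )


@dataclass
class PermutationTestResult:
    """Sequential (type-I) permutation test of the design factors.

    ``table`` has one row per factor (in sequential order) with df,
    variance (SS / (n-1)), pseudo-F and the permutation p-value
    ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)``.
    """

    table: pd.DataFrame
    n_permutations: int
    seed: int


def permutation_test(
    matrix,
    factors: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    factor_order=FACTOR_ORDER,
) -> PermutationTestResult:
    """Test each design factor by freely permuting the rows of the response.

    Terms are added sequentially in ``factor_order``; per term
    F = (SS_term / df_term) / (SS_resid / df_resid).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    arr, _ = _as_array(matrix)
    n = arr.shape[0]
    Yc = arr - arr.mean(axis=0, keepdims=True)
    X, blocks = _design_blocks(factors, factor_order)
    seq = _sequential_basis(X, blocks)
    names = [name for name, _, _ in seq]
    dfs = np.array([df for _, _, df in seq])
    df_resid = n - 1 - int(dfs.sum())
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    Qall = np.hstack([Qb for _, Qb, _ in seq])
    bounds = np.concatenate([[0], np.cumsum(dfs)])

    total_ss = float((Yc**2).sum())

    def term_F(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        proj = Qall.T @ Y
        ss = np.array(
            [
                float((proj[bounds[k] : bounds[k + 1]] ** 2).sum())
                for k in range(len(names))
            ]
        )
        resid = total_ss - ss.sum()
        F = (ss / dfs) / (resid / df_resid)
        return ss, F

    obs_ss, obs_F = term_F(Yc)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names), dtype=int)
    for _ in range(n_perm):
        _, F = term_F(Yc[rng.permutation(n)])
        exceed += F >= obs_F
    pvals = (1 + exceed) / (1 + n_perm)
    table = pd.DataFrame(
        {
            "df": dfs,
            "variance": obs_ss / (n - 1),
            "F": obs_F,
            "p": pvals,
        },
        index=pd.Index(names, name="factor"),
    )
    return PermutationTestResult(table=table, n_permutations=n_perm, seed=seed)
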