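"""Multivariate partitioning of distance matrices.

PERMANOVA (permutational multivariate ANOVA computed directly from squared
dissimilarities via Gower centering), classical PCoA with per-OTU scores,
UPGMA ultrametric clustering, and jackknife branch support by rarefied
re-clustering.  All four are implemented here from the distance matrix; no
external statistics engine is called.

PERMANOVA follows the McArdle-Anderson trace formulation: with
``G = -1/2 J D^2 J`` (J the centering matrix), the total sum of squares is
``tr(G) = (1/n) sum_{i<j} d_ij^2``, and each term's SS is the increment in
``tr(H G)`` as its dummy-coded columns join the model (sequential SS).  The
permutation test freely permutes sample labels and recomputes each term's
pseudo-F against the residual; p uses the (c+1)/(m+1) estimator.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import DistanceMatrix, pairwise_distances, rarefy
from .table import OTUTable

__all__ = [
    "PermanovaResult",
    "PCoAResult",
    "TreeNode",
    "permanova",
    "pcoa",
    "otu_scores",
    "upgma",
    "jackknife_support",
]


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    """Sequential PERMANOVA table: one row per factor plus residual/total."""

    factors: tuple[str, ...]
    df: dict[str, int]
    ss: dict[str, float]
    pseudo_f: dict[str, float]
    r2: dict[str, float]
    p: dict[str, float]
    residual_df: int
    residual_ss: float
    total_ss: float
    n_permutations: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "Source": f,
                "Df": self.df[f],
                "SS": self.ss[f],
                "F Model": self.pseudo_f[f],
                "R2": self.r2[f],
                "P": self.p[f],
            }
            for f in self.factors
        ]
        rows.append(
            {
                "Source": "Residuals",
                "Df": self.residual_df,
                "SS": self.residual_ss,
                "F Model": np.nan,
                "R2": self.residual_ss / self.total_ss if self.total_ss else np.nan,
                "P": np.nan,
            }
        )
        rows.append(
            {
                "Source": "Total",
                "Df": self.residual_df + sum(self.df.values()),
                "SS": self.total_ss,
                "F Model": np.nan,
                "R2": 1.0,
                "P": np.nan,
            }
        )
        return pd.DataFrame(rows)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _dummy(labels) -> np.ndarray:
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    return np.column_stack([(labels == lv).astype(float) for lv in levels])


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def permanova(
    dm: DistanceMatrix,
    factors: pd.DataFrame | dict,
    n_perm: int = 10_000,
    seed=None,
) -> PermanovaResult:
    """Sequential PERMANOVA of a distance matrix on categorical factors.

    Parameters
    ----------
    dm
        Symmetric distance matrix.
    factors
        Mapping / DataFrame of factor name -> per-sample labels, ordered (or
        indexed) like ``dm.ids``.  Terms enter the model in the given order;
        for a balanced crossed design the decomposition is order-independent
        and a warning is emitted otherwise.
    n_perm
        Number of free label permutations, or the string ``"exact"`` to
        enumerate all n! permutations (small n only).
    """
    d = dm.values
    n = d.shape[0]
    fx = pd.DataFrame(factors)
    if isinstance(fx.index, pd.Index) and set(fx.index.astype(str)) == set(dm.ids):
        fx = fx.loc[list(dm.ids)]
    if len(fx) != n:
        raise ValueError("factor labels do not match the distance matrix samples")

    g = _gower_center(d)
    total_ss = float(np.trace(g))

    names = list(fx.columns)
    x = np.ones((n, 1))
    hats, dfs = [], []
    prev_rank = 1
    for name in names:
        x = np.column_stack([x, _dummy(fx[name])])
        rank = int(np.linalg.matrix_rank(x))
        dfs.append(rank - prev_rank)
        hats.append(_hat(x))
        prev_rank = rank
    if prev_rank > n:
        raise ValueError("rank-deficient design: more parameters than samples")
    residual_df = n - prev_rank
    if residual_df <= 0:
        raise ValueError("no residual degrees of freedom")

    if _is_unbalanced(fx):
        warnings.warn(
            "unbalanced design: sequential sums of squares depend on term order",
            stacklevel=2,
        )

    ss_tol = 1e-12 * max(abs(total_ss), 1.0)

    def term_stats(gm: np.ndarray) -> tuple[np.ndarray, float]:
        cum = np.array([np.trace(h @ gm) for h in hats])
        ss = np.diff(np.concatenate([[0.0], cum]))
        res = float(np.trace(gm)) - cum[-1]
        return ss, res if res > ss_tol else 0.0

    ss, residual_ss = term_stats(g)
    with np.errstate(divide="ignore"):
        f_obs = np.array(
            [
                (ss[k] / dfs[k]) / (residual_ss / residual_df)
                if residual_ss > 0
                else np.inf
                for k in range(len(names))
            ]
        )

    # permutation test: freely permute sample labels (rows/cols of G)
    if n_perm == "exact":
        perms = list(itertools.permutations(range(n)))[1:]
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(int(n_perm))]
    exceed = np.zeros(len(names))
    for p in perms:
        gp = g[np.ix_(p, p)]
        ss_p, res_p = term_stats(gp)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_p = np.where(
                res_p > 1e-12,
                (ss_p / np.array(dfs)) / (res_p / residual_df),
                np.inf,
            )
        exceed += f_p >= f_obs - 1e-12
    m = len(perms)
    pvals = (exceed + 1) / (m + 1)

    return PermanovaResult(
        factors=tuple(names),
        df={nm: dfs[k] for k, nm in enumerate(names)},
        ss={nm: float(ss[k]) for k, nm in enumerate(names)},
        pseudo_f={nm: float(f_obs[k]) for k, nm in enumerate(names)},
        r2={nm: float(ss[k] / total_ss) for k, nm in enumerate(names)},
        p={nm: float(pvals[k]) for k, nm in enumerate(names)},
        residual_df=residual_df,
        residual_ss=float(residual_ss),
        total_ss=total_ss,
        n_permutations=m,
    )


def _is_unbalanced(fx: pd.DataFrame) -> bool:
    if fx.shape[1] < 2:
        counts = fx.iloc[:, 0].value_counts()
        return counts.nunique() > 1
    cell = fx.astype(str).agg("|".join, axis=1).value_counts()
    return cell.nunique() > 1


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix."""

    ids: tuple[str, ...]
    eigenvalues: np.ndarray          # all eigenvalues, descending
    coordinates: pd.DataFrame        # samples x positive axes, sqrt-eigenvalue scaled
    proportion_explained: np.ndarray  # per positive axis
    negative_eigenvalues: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Gower double-centering of -1/2 d^2 followed by eigendecomposition.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    eigenvalues; negative eigenvalues (non-Euclidean metrics) are reported
    and their axes excluded, with no correction applied.
    """
    if dm.n < 3:
        raise ValueError("PCoA needs at least three samples")
    g = _gower_center(dm.values)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-10
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    axes = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    coordinates = pd.DataFrame(coords, index=list(dm.ids), columns=axes)
    pos_sum = vals[pos].sum()
    return PCoAResult(
        ids=dm.ids,
        eigenvalues=vals,
        coordinates=coordinates,
        proportion_explained=vals[pos] / pos_sum if pos_sum > 0 else vals[pos],
        negative_eigenvalues=vals[vals < -tol],
    )


def otu_scores(table: OTUTable, result: PCoAResult, n_axes: int = 2) -> pd.DataFrame:
    """Project OTUs into PCoA space as abundance-weighted sample centroids.

    Each OTU's score on an axis is the average of the sample coordinates
    weighted by the fraction of that OTU's reads in each sample (the common
    biplot convention; the projection choice is recorded in output metadata).
    OTUs with zero total reads are omitted with a warning.
    """
    if list(table.sample_ids) != list(result.ids):
        raise ValueError("table samples do not match the PCoA result")
    n_axes = min(n_axes, result.n_axes)
    coords = result.coordinates.iloc[:, :n_axes].to_numpy()
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"omitting {int(zero.sum())} OTU(s) with zero total reads from scores",
            stacklevel=2,
        )
    weights = counts[:, ~zero] / totals[~zero]
    scores = weights.T @ coords
    out = pd.DataFrame(
        scores,
        index=[o for o, z in zip(table.otu_ids, zero) if not z],
        columns=list(result.coordinates.columns[:n_axes]),
    )
    out.attrs["projection"] = "abundance-weighted average of sample coordinates"
    return out


# ---------------------------------------------------------------------------
# UPGMA + jackknife support
# ---------------------------------------------------------------------------

class TreeNode:
    """Rooted ultrametric tree node; internal nodes carry height and support."""

    __slots__ = ("name", "children", "height", "support")

    def __init__(self, name=None, children=None, height=0.0, support=None):
        self.name = name
        self.children = children or []
        self.height = height
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def internal_nodes(self) -> list["TreeNode"]:
        if self.is_leaf:
            return []
        out = [self]
        for c in self.children:
            out.extend(c.internal_nodes())
        return out

    def bipartitions(self) -> set[frozenset]:
        """Unrooted-style leaf bipartitions of every internal node, each
        normalized to the lexicographically smaller side."""
        all_leaves = frozenset(self.leaves())
        parts = set()
        for node in self.internal_nodes():
            side = frozenset(node.leaves())
            parts.add(_normalize_bipartition(side, all_leaves))
        return parts

    def newick(self, include_support: bool = True) -> str:
        return self._newick(parent_height=None, include_support=include_support) + ";"

    def _newick(self, parent_height, include_support) -> str:
        if self.is_leaf:
            label = self.name
        else:
            inner = ",".join(
                c._newick(self.height, include_support) for c in self.children
            )
            sup = (
                f"{self.support:.2f}"
                if include_support and self.support is not None
                else ""
            )
            label = f"({inner}){sup}"
        if parent_height is None:
            return label
        return f"{label}:{parent_height - self.height:.6g}"


def _normalize_bipartition(side: frozenset, universe: frozenset) -> frozenset:
    other = universe - side
    return min(side, other, key=lambda s: (len(s), sorted(s)))


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage (size-weighted) agglomerative clustering.

    Repeatedly merges the closest pair of clusters; the merged node sits at
    half the merge dissimilarity so leaf depths are equal (ultrametric).
    Distance ties are broken by the lexicographically smallest pair of
    cluster member ids, making the tree independent of input order.
    """
    if dm.n < 2:
        raise ValueError("UPGMA needs at least two samples")
    nodes: dict[int, TreeNode] = {i: TreeNode(name=s) for i, s in enumerate(dm.ids)}
    sizes = {i: 1 for i in nodes}
    mins = {i: dm.ids[i] for i in nodes}  # lexicographically smallest member id
    dist = {
        (i, j): float(dm.values[i, j])
        for i in range(dm.n)
        for j in range(i + 1, dm.n)
    }
    next_id = dm.n
    while len(nodes) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted((mins[kv[0][0]], mins[kv[0][1]])))),
        )
        (a, b), d_ab = best
        if mins[b] < mins[a]:
            a, b = b, a
        merged = TreeNode(children=[nodes[a], nodes[b]], height=d_ab / 2.0)
        del nodes[a], nodes[b]
        # size-weighted arithmetic mean over all cross pairs
        new_dist = {
            other: (
                sizes[a] * dist[(min(a, other), max(a, other))]
                + sizes[b] * dist[(min(b, other), max(b, other))]
            )
            / (sizes[a] + sizes[b])
            for other in nodes
        }
        for key in [k for k in dist if a in k or b in k]:
            del dist[key]
        for other, d_new in new_dist.items():
            dist[(min(next_id, other), max(next_id, other))] = d_new
        nodes[next_id] = merged
        sizes[next_id] = sizes[a] + sizes[b]
        mins[next_id] = min(mins[a], mins[b])
        next_id += 1
    return next(iter(nodes.values()))


def jackknife_support(
    table: OTUTable,
    metric: str,
    tree: TreeNode,
    n_reps: int = 100,
    subsample_depth: int | None = None,
    seed=None,
) -> TreeNode:
    """Attach jackknife support to a reference UPGMA tree.

    Each replicate rarefies every sample (without replacement) to
    ``subsample_depth`` reads, recomputes the distance matrix and rebuilds the
    UPGMA tree; the support of an internal node is the fraction of replicate
    trees containing the same leaf bipartition.  ``subsample_depth`` defaults
    to 75% of the smallest sample total.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    min_total = int(table.sample_totals().min())
    if subsample_depth is None:
        subsample_depth = int(round(0.75 * min_total))
    if subsample_depth > min_total:
        raise ValueError(
            f"subsample depth {subsample_depth} exceeds smallest sample total {min_total}"
        )
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    children = ss.spawn(n_reps)
    universe = frozenset(tree.leaves())
    counts = {node: 0 for node in tree.internal_nodes()}
    for child in children:
        sub = rarefy(table, subsample_depth, np.random.default_rng(child))
        rep_tree = upgma(pairwise_distances(sub, metric))
        rep_parts = rep_tree.bipartitions()
        for node in counts:
            part = _normalize_bipartition(frozenset(node.leaves()), universe)
            if part in rep_parts:
                counts[node] += 1
    for node, c in counts.items():
        node.support = c / n_reps
    return tree
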