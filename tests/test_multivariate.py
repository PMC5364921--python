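"""PERMANOVA, PCoA, UPGMA and jackknife support."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mockrep import (
    DistanceMatrix,
    MockModel,
    OTUTable,
    jackknife_support,
    otu_scores,
    pairwise_distances,
    pcoa,
    permanova,
    simulate_table,
    upgma,
)


# ---------------------------------------------------------------------------
# independent PERMANOVA oracle: group sums of squared distances, enumerated
# ---------------------------------------------------------------------------

def brute_force_permanova(d: np.ndarray, labels: list) -> tuple[float, float]:
    """One-factor pseudo-F and exact permutation p from first principles.

    SS_total = (1/n) sum_{i<j} d_ij^2; SS_within = sum over groups of
    (1/n_g) sum_{i<j in g} d_ij^2; F from the between/within mean squares.
    The exact p enumerates every relabelling of the samples.
    """
    labels = np.asarray(labels)
    n = len(labels)
    groups = pd.unique(labels)

    def f_stat(lab):
        ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
        ss_within = 0.0
        for g in groups:
            idx = np.flatnonzero(lab == g)
            sub = d[np.ix_(idx, idx)]
            ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
        ss_between = ss_total - ss_within
        df_b, df_w = len(groups) - 1, n - len(groups)
        return (ss_between / df_b) / (ss_within / df_w)

    f_obs = f_stat(labels)
    count = 0
    perms = list(itertools.permutations(range(n)))
    for p in perms[1:]:
        if f_stat(labels[list(p)]) >= f_obs - 1e-12:
            count += 1
    return f_obs, (count + 1) / len(perms)


def _random_distance_matrix(n, seed):
    rng = np.random.default_rng(seed)
    pts = rng.random((n, 3))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    d /= d.max() * 1.01
    return DistanceMatrix(tuple(f"s{i}" for i in range(n)), d, "bray_curtis")


def test_permanova_matches_brute_force_enumeration():
    dm = _random_distance_matrix(6, seed=3)
    labels = ["a", "a", "a", "b", "b", "b"]
    f_oracle, p_oracle = brute_force_permanova(dm.values, labels)
    res = permanova(dm, {"grp": labels}, n_perm="exact")
    assert res.pseudo_f["grp"] == pytest.approx(f_oracle, rel=1e-9)
    assert res.p["grp"] == pytest.approx(p_oracle, rel=1e-9)


def test_permanova_agrees_with_skbio_pseudo_f():
    skbio_distance = pytest.importorskip("skbio.stats.distance")
    dm = _random_distance_matrix(9, seed=11)
    labels = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
    res = permanova(dm, {"grp": labels}, n_perm=99, seed=0)
    ref = skbio_distance.permanova(
        skbio_distance.DistanceMatrix(dm.values, list(dm.ids)),
        grouping=labels,
        permutations=99,
    )
    assert res.pseudo_f["grp"] == pytest.approx(float(ref["test statistic"]), rel=1e-9)


def test_permanova_perfect_separation():
    ids = ("a1", "a2", "b1", "b2")
    d = np.array(
        [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float
    )
    dm = DistanceMatrix(ids, d, "jaccard")
    res = permanova(dm, {"grp": ["a", "a", "b", "b"]}, n_perm="exact")
    assert res.r2["grp"] == pytest.approx(1.0)
    assert res.residual_ss == pytest.approx(0.0, abs=1e-12)
    assert np.isinf(res.pseudo_f["grp"])
    # minimum achievable p: the 8 relabellings preserving the partition
    assert res.p["grp"] == pytest.approx(8 / 24)


def test_permanova_df_pattern_and_ss_partition(design_table):
    dm = pairwise_distances(design_table, "bray_curtis")
    factors = pd.DataFrame(
        {
            "run": design_table.sample_meta["run"].astype(str),
            "primer": design_table.sample_meta["primer_index"].astype(str),
        },
        index=design_table.sample_meta.index,
    )
    res = permanova(dm, factors, n_perm=99, seed=1)
    assert (res.df["run"], res.df["primer"], res.residual_df) == (1, 6, 6)
    total = res.ss["run"] + res.ss["primer"] + res.residual_ss
    assert total == pytest.approx(res.total_ss, rel=1e-9)
    r2_sum = res.r2["run"] + res.r2["primer"] + res.residual_ss / res.total_ss
    assert r2_sum == pytest.approx(1.0, rel=1e-9)
    assert 0 < res.p["run"] <= 1 and 0 < res.p["primer"] <= 1


def test_permanova_balanced_order_independence(design_table):
    dm = pairwise_distances(design_table, "jaccard")
    fx = pd.DataFrame(
        {
            "run": design_table.sample_meta["run"].astype(str),
            "primer": design_table.sample_meta["primer_index"].astype(str),
        },
        index=design_table.sample_meta.index,
    )
    a = permanova(dm, fx[["run", "primer"]], n_perm=9, seed=0)
    b = permanova(dm, fx[["primer", "run"]], n_perm=9, seed=0)
    assert a.ss["primer"] == pytest.approx(b.ss["primer"], rel=1e-9)
    assert a.ss["run"] == pytest.approx(b.ss["run"], rel=1e-9)


def test_permanova_rank_deficient_design_errors():
    dm = _random_distance_matrix(4, seed=0)
    with pytest.raises(ValueError):
        permanova(dm, {"grp": ["a", "b", "c", "d"]}, n_perm=9)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def test_pcoa_equilateral_triangle_closed_form():
    ids = ("a", "b", "c")
    d = np.ones((3, 3)) - np.eye(3)
    res = pcoa(DistanceMatrix(ids, d, "jaccard"))
    pos = res.eigenvalues[res.eigenvalues > 1e-10]
    assert len(pos) == 2
    assert pos[0] == pytest.approx(pos[1], rel=1e-9)
    coords = res.coordinates.to_numpy()
    for i, j in itertools.combinations(range(3), 2):
        assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(1.0, abs=1e-9)


def test_pcoa_euclidean_recovery():
    rng = np.random.default_rng(5)
    pts = rng.random((8, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    d /= d.max() * 1.01
    res = pcoa(DistanceMatrix(tuple(f"s{i}" for i in range(8)), d, "bray_curtis"))
    coords = res.coordinates.to_numpy()
    rec = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    assert np.allclose(rec, d, atol=1e-8)


def test_pcoa_duplicate_sample_coincident_coordinates():
    d = np.array(
        [[0, 0, 0.5], [0, 0, 0.5], [0.5, 0.5, 0]], dtype=float
    )
    res = pcoa(DistanceMatrix(("a", "a2", "b"), d, "jaccard"))
    assert np.allclose(res.coordinates.loc["a"], res.coordinates.loc["a2"], atol=1e-9)


def test_pcoa_agrees_with_skbio(design_table):
    skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
    import skbio

    dm = pairwise_distances(design_table, "bray_curtis")
    mine = pcoa(dm)
    ref = skbio_pcoa(skbio.DistanceMatrix(dm.values, list(dm.ids)))
    n = mine.n_axes
    ref_eig = np.sort(ref.eigvals.to_numpy())[::-1][:n]
    assert np.allclose(np.sort(mine.eigenvalues)[::-1][:n], ref_eig, atol=1e-8)
    # coordinates agree up to per-axis sign
    ref_coords = ref.samples.to_numpy()[:, :n]
    for k in range(n):
        col, refc = mine.coordinates.to_numpy()[:, k], ref_coords[:, k]
        assert np.allclose(col, refc, atol=1e-6) or np.allclose(col, -refc, atol=1e-6)


def test_pcoa_requires_three_samples():
    d = np.array([[0, 0.2], [0.2, 0]])
    with pytest.raises(ValueError):
        pcoa(DistanceMatrix(("a", "b"), d, "jaccard"))


def test_otu_scores_single_sample_and_uniform(design_table):
    dm = pairwise_distances(design_table, "bray_curtis")
    res = pcoa(dm)
    counts = design_table.counts.copy()
    counts["solo"] = 0
    counts.loc[design_table.sample_ids[2], "solo"] = 11
    counts["uniform"] = 5
    t2 = OTUTable(counts, design_table.sample_meta)
    scores = otu_scores(t2, res, n_axes=2)
    np.testing.assert_allclose(
        scores.loc["solo"],
        res.coordinates.iloc[2, :2],
        atol=1e-9,
    )
    np.testing.assert_allclose(
        scores.loc["uniform"],
        res.coordinates.iloc[:, :2].mean(axis=0),
        atol=1e-9,
    )


def test_otu_scores_zero_total_omitted_with_warning(design_table):
    dm = pairwise_distances(design_table, "bray_curtis")
    res = pcoa(dm)
    counts = design_table.counts.copy()
    counts["ghost"] = 0
    t2 = OTUTable(counts, design_table.sample_meta)
    with pytest.warns(UserWarning, match="zero total"):
        scores = otu_scores(t2, res)
    assert "ghost" not in scores.index


# ---------------------------------------------------------------------------
# UPGMA + jackknife
# ---------------------------------------------------------------------------

def _dm(ids, rows):
    return DistanceMatrix(tuple(ids), np.asarray(rows, dtype=float), "bray_curtis")


def test_upgma_three_leaf_hand_trace():
    dm = _dm("ABC", [[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
    tree = upgma(dm)
    assert tree.newick(include_support=False) == "((A:0.1,B:0.1):0.2,C:0.3);"


def test_upgma_two_samples_root_at_half_distance():
    tree = upgma(_dm("AB", [[0, 0.4], [0.4, 0]]))
    assert tree.height == pytest.approx(0.2)
    assert sorted(tree.leaves()) == ["A", "B"]


def test_upgma_equal_distances_deterministic_ties():
    d = np.full((4, 4), 0.5) - 0.5 * np.eye(4)
    t1 = upgma(_dm("ABCD", d))
    # permuted input order gives the identical tree under the tie rule
    perm = [2, 0, 3, 1]
    ids = [list("ABCD")[i] for i in perm]
    t2 = upgma(_dm(ids, d[np.ix_(perm, perm)]))
    assert t1.newick(include_support=False) == t2.newick(include_support=False)
    heights = {n.height for n in t1.internal_nodes()}
    assert heights == {0.25}


def test_upgma_order_invariance_general(design_table):
    dm = pairwise_distances(design_table, "bray_curtis")
    rng = np.random.default_rng(0)
    perm = rng.permutation(dm.n)
    dm2 = DistanceMatrix(
        tuple(dm.ids[i] for i in perm), dm.values[np.ix_(perm, perm)], dm.metric
    )
    assert upgma(dm).newick(False) == upgma(dm2).newick(False)


def test_upgma_heights_match_scipy_average_linkage(design_table):
    hierarchy = pytest.importorskip("scipy.cluster.hierarchy")
    from scipy.spatial.distance import squareform

    dm = pairwise_distances(design_table, "bray_curtis")
    link = hierarchy.linkage(squareform(dm.values), method="average")
    mine = sorted(n.height * 2 for n in upgma(dm).internal_nodes())
    assert np.allclose(mine, sorted(link[:, 2]), atol=1e-12)


def test_jackknife_single_rep_and_full_depth(design_table):
    dm = pairwise_distances(design_table, "jaccard")
    tree = jackknife_support(
        design_table, "jaccard", upgma(dm), n_reps=1, subsample_depth=50, seed=0
    )
    assert all(n.support in (0.0, 1.0) for n in tree.internal_nodes())
    # rarefying to the (equal) full depth reproduces the table: all supports 1
    fixed = design_table.with_counts(design_table.counts * 0 + 10)
    dmf = pairwise_distances(fixed, "bray_curtis")
    depth = int(fixed.sample_totals().min())
    t = jackknife_support(fixed, "bray_curtis", upgma(dmf),
                          n_reps=5, subsample_depth=depth, seed=1)
    assert all(n.support == 1.0 for n in t.internal_nodes())


def test_jackknife_supports_well_separated_groups():
    # two primer groups with very different libraries -> the top split is stable
    model = MockModel(
        n_target=20, n_rare=0, n_primers=2, n_runs=4,
        primer_bias_sigma=1.0, depth_range=(2000, 2000), seed=9,
    )
    table, _ = simulate_table(model)
    dm = pairwise_distances(table, "bray_curtis")
    tree = jackknife_support(table, "bray_curtis", upgma(dm),
                             n_reps=30, subsample_depth=1500, seed=2)
    top_children = tree.children
    group_leaves = [frozenset(c.leaves()) for c in top_children]
    expected = [
        frozenset(s for s in table.sample_ids if s.startswith("P1")),
        frozenset(s for s in table.sample_ids if s.startswith("P2")),
    ]
    assert set(group_leaves) == set(expected)
    assert all(c.support is None or c.support > 0.95
               for c in top_children if not c.is_leaf)


def test_jackknife_depth_too_large_errors(design_table):
    dm = pairwise_distances(design_table, "jaccard")
    with pytest.raises(ValueError):
        jackknife_support(design_table, "jaccard", upgma(dm),
                          n_reps=2, subsample_depth=10**9)
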