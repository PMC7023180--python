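"""Ward.D agglomeration, tree utilities, and unknown-sample classification."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet as scipy_cophenet, linkage as scipy_linkage
from scipy.spatial.distance import squareform, pdist

from phagesensor import (
    hierarchical_cluster, cut_tree, cophenetic_matrix, classify_unknown,
    dendrogram_to_newick, distance_matrix,
)
from phagesensor.clustering import Dendrogram, ClusteringError
from phagesensor.distance import DistanceMatrix
from phagesensor.features import ResponsePattern
from phagesensor.simulate import scenario_delta_patterns, simulate_measured_patterns
from phagesensor.features import assemble_feature_table
from oracles import (
    ward_ess_agglomeration, single_linkage_agglomeration, lca_cophenetic,
    is_ultrametric,
)


def _dmat_from_points(pts, squared=True):
    d = squareform(pdist(np.atleast_2d(pts)))
    if squared:
        d = d ** 2
    labels = tuple(f"p{i}" for i in range(len(pts)))
    return DistanceMatrix(labels=labels, values=d)


def _random_points(rng, n=None, dim=None):
    n = n if n is not None else int(rng.integers(3, 9))
    dim = dim if dim is not None else int(rng.integers(1, 4))
    return rng.normal(size=(n, dim))


def test_two_leaves_single_merge():
    d = DistanceMatrix(labels=("A", "B"),
                       values=np.array([[0.0, 3.5], [3.5, 0.0]]))
    for linkage in ("ward_d", "single", "complete", "average"):
        tree = hierarchical_cluster(d, linkage=linkage)
        assert tree.merges == ((0, 1, 3.5, 2),)


def test_ward_on_three_point_line():
    """Points {0, 1, 10} with squared-Euclidean input: first merge {0,1} at
    height 1, second at 361/3 — exactly the from-scratch ESS increments."""
    pts = np.array([[0.0], [1.0], [10.0]])
    tree = hierarchical_cluster(_dmat_from_points(pts), linkage="ward_d")
    assert tree.merges[0][:2] == (0, 1)
    assert tree.merges[0][2] == pytest.approx(1.0)
    assert tree.merges[1][2] == pytest.approx(361.0 / 3.0)
    oracle = ward_ess_agglomeration(pts)
    for got, want in zip(tree.merges, oracle):
        assert got[:2] == want[:2]
        assert got[2] == pytest.approx(want[2], rel=1e-12)


def test_ward_matches_ess_oracle_on_random_point_sets():
    """On random point sets (n <= 8, 1-3 dims), the Lance-Williams Ward.D
    merges reproduce the from-scratch ESS-increment agglomeration, with
    monotone heights."""
    rng = np.random.default_rng(4711)
    for _ in range(60):
        pts = _random_points(rng)
        tree = hierarchical_cluster(_dmat_from_points(pts), linkage="ward_d")
        oracle = ward_ess_agglomeration(pts)
        for got, want in zip(tree.merges, oracle):
            assert got[:2] == want[:2]
            assert got[3] == want[3]
            assert got[2] == pytest.approx(want[2], rel=1e-9)
        h = tree.heights()
        assert np.all(np.diff(h) >= -1e-9 * max(1.0, h.max()))


def test_single_linkage_matches_exhaustive_oracle():
    rng = np.random.default_rng(99)
    for _ in range(40):
        pts = _random_points(rng)
        dm = _dmat_from_points(pts, squared=False)
        tree = hierarchical_cluster(dm, linkage="single")
        oracle = single_linkage_agglomeration(dm.values)
        for got, want in zip(tree.merges, oracle):
            assert got[:2] == want[:2]
            assert got[2] == pytest.approx(want[2], rel=1e-9)


@pytest.mark.parametrize("linkage,scipy_method", [
    ("single", "single"), ("complete", "complete"), ("average", "average"),
])
def test_classical_linkages_agree_with_scipy(linkage, scipy_method):
    """Cophenetic matrices match scipy's for the classical linkages."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        pts = _random_points(rng)
        dm = _dmat_from_points(pts, squared=False)
        tree = hierarchical_cluster(dm, linkage=linkage)
        ours = cophenetic_matrix(tree).values
        Z = scipy_linkage(squareform(dm.values), method=scipy_method)
        theirs = squareform(scipy_cophenet(Z))
        assert np.allclose(ours, theirs, rtol=1e-9)


def test_ward_d_agrees_with_scipy_ward_squared():
    """scipy implements the Ward.D2 convention on Euclidean distances; our
    Ward.D on *squared* distances must reproduce its cophenetic heights
    squared."""
    rng = np.random.default_rng(6)
    for _ in range(20):
        pts = _random_points(rng)
        tree = hierarchical_cluster(_dmat_from_points(pts, squared=True),
                                    linkage="ward_d")
        ours = cophenetic_matrix(tree).values
        Z = scipy_linkage(pdist(np.atleast_2d(pts)), method="ward")
        theirs = squareform(scipy_cophenet(Z)) ** 2
        assert np.allclose(ours, theirs, rtol=1e-8)


def test_ward_d2_dialect_matches_scipy_directly():
    rng = np.random.default_rng(8)
    pts = _random_points(rng, n=7, dim=2)
    tree = hierarchical_cluster(_dmat_from_points(pts, squared=False),
                                linkage="ward_d2")
    ours = cophenetic_matrix(tree).values
    Z = scipy_linkage(pdist(pts), method="ward")
    theirs = squareform(scipy_cophenet(Z))
    assert np.allclose(ours, theirs, rtol=1e-8)


def test_permutation_invariance():
    """Relabelling leaves permutes the tree but not its height multiset or
    cophenetic structure."""
    rng = np.random.default_rng(11)
    pts = _random_points(rng, n=7, dim=2)
    dm = _dmat_from_points(pts)
    perm = rng.permutation(7)
    dm_p = DistanceMatrix(
        labels=tuple(dm.labels[i] for i in perm),
        values=dm.values[np.ix_(perm, perm)])
    t1 = hierarchical_cluster(dm, "ward_d")
    t2 = hierarchical_cluster(dm_p, "ward_d")
    assert np.allclose(np.sort(t1.heights()), np.sort(t2.heights()))
    c1 = cophenetic_matrix(t1)
    c2 = cophenetic_matrix(t2)
    # compare by label, not by position
    idx2 = {lab: i for i, lab in enumerate(c2.labels)}
    for i, a in enumerate(c1.labels):
        for j, b in enumerate(c1.labels):
            assert c1.values[i, j] == pytest.approx(
                c2.values[idx2[a], idx2[b]], rel=1e-9)


def test_invalid_inputs_rejected():
    single = DistanceMatrix(labels=("a",), values=np.zeros((1, 1)))
    with pytest.raises(ClusteringError):
        hierarchical_cluster(single)
    d = DistanceMatrix(labels=("a", "b"),
                       values=np.array([[0.0, 1.0], [1.0, 0.0]]))
    with pytest.raises(ClusteringError):
        hierarchical_cluster(d, linkage="centroid")


def test_cut_tree_extremes_and_recovery(scenario):
    patterns = scenario_delta_patterns(scenario)
    concat = assemble_feature_table(patterns, mode="concatenated")
    tree = hierarchical_cluster(distance_matrix(concat), "ward_d")
    n = tree.n_leaves
    assert list(cut_tree(tree, 1)) == [0] * n
    assert list(cut_tree(tree, n)) == list(range(n))
    labels = cut_tree(tree, 2)
    truth = [scenario.class_of(a) for a in tree.leaf_labels]
    from sklearn.metrics import adjusted_rand_score
    assert adjusted_rand_score(truth, labels) == 1.0
    with pytest.raises(ValueError):
        cut_tree(tree, 0)
    with pytest.raises(ValueError):
        cut_tree(tree, n + 1)


def test_cophenetic_matches_lca_oracle_and_is_ultrametric():
    rng = np.random.default_rng(21)
    for _ in range(15):
        pts = _random_points(rng, n=6)
        tree = hierarchical_cluster(_dmat_from_points(pts), "ward_d")
        coph = cophenetic_matrix(tree)
        oracle = lca_cophenetic(tree.merges, tree.n_leaves)
        assert np.allclose(coph.values, oracle, rtol=1e-12)
        assert is_ultrametric(coph.values)


def test_cophenetic_two_leaves():
    d = DistanceMatrix(labels=("A", "B"),
                       values=np.array([[0.0, 2.0], [2.0, 0.0]]))
    coph = cophenetic_matrix(hierarchical_cluster(d))
    assert coph.values[0, 1] == 2.0


def test_classify_unknown_exact_and_single_reference(scenario):
    refs = assemble_feature_table(scenario_delta_patterns(scenario),
                                  mode="concatenated")
    classes = [scenario.class_of(p.analyte_id) for p in refs]
    cls, nearest, dist = classify_unknown(refs[0], refs, classes)
    assert (cls, nearest, dist) == ("estrogen", refs[0].analyte_id, 0.0)
    cls, nearest, _ = classify_unknown(refs[5], refs[:1], classes[:1])
    assert cls == "estrogen" and nearest == refs[0].analyte_id


def test_classify_unknown_recovers_noisy_replicates(scenario, small_layout):
    """>= 90% class recovery for 104 held-out noisy replicate patterns."""
    refs = assemble_feature_table(scenario_delta_patterns(scenario),
                                  mode="concatenated")
    classes = [scenario.class_of(p.analyte_id) for p in refs]
    hits = total = 0
    for rep in range(1, 14):  # 13 replicates x 8 analytes = 104 queries
        noisy = simulate_measured_patterns(scenario, layout=small_layout,
                                           replicate=rep)
        for q in assemble_feature_table(noisy, mode="concatenated"):
            cls, _, _ = classify_unknown(q, refs, classes)
            hits += int(cls == scenario.class_of(q.analyte_id))
            total += 1
    assert total == 104
    assert hits / total >= 0.90


def test_newick_two_leaves():
    d = DistanceMatrix(labels=("A", "B"),
                       values=np.array([[0.0, 1.5], [1.5, 0.0]]))
    nwk = dendrogram_to_newick(hierarchical_cluster(d))
    assert nwk == "(A:1.5,B:1.5);"


def test_newick_quotes_reserved_labels():
    d = DistanceMatrix(labels=("a b", "c:d"),
                       values=np.array([[0.0, 1.0], [1.0, 0.0]]))
    nwk = dendrogram_to_newick(hierarchical_cluster(d))
    assert "'a b'" in nwk and "'c:d'" in nwk


def test_newick_round_trips_through_dendropy(scenario):
    """An independent Newick parser recovers the exact topology and heights
    (leaf-pair path length = 2 x cophenetic height)."""
    import dendropy

    refs = assemble_feature_table(scenario_delta_patterns(scenario),
                                  mode="concatenated")
    tree = hierarchical_cluster(distance_matrix(refs), "ward_d")
    nwk = dendrogram_to_newick(tree)
    dtree = dendropy.Tree.get(data=nwk, schema="newick")
    assert len(dtree.leaf_nodes()) == 8
    pdm = dtree.phylogenetic_distance_matrix()
    coph = cophenetic_matrix(tree)
    taxa = {t.label: t for t in dtree.taxon_namespace}
    for i, a in enumerate(coph.labels):
        for j in range(i + 1, coph.n):
            b = coph.labels[j]
            got = pdm.patristic_distance(taxa[a], taxa[b])
            assert got == pytest.approx(2.0 * coph.values[i, j], rel=1e-6)


def test_dendrogram_validation():
    with pytest.raises(ClusteringError):
        Dendrogram(leaf_labels=("a", "b", "c"),
                   merges=((0, 1, 1.0, 2),))  # missing a merge
    with pytest.raises(ClusteringError):
        Dendrogram(leaf_labels=("a", "b"), merges=((0, 1, -1.0, 2),))
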