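import numpy as np
import pytest

import dendropy

import phyrn
from helpers import (
    minimum_evolution_topology,
    patristic_matrix,
    random_additive_instance,
    tree_cherry_pairs,
)
from phyrn.score_matrix import DistanceMatrix
from phyrn.treebuild import (
    bipartition_set,
    from_newick,
    nj_tree,
    rf_distance,
    to_newick,
)


def _dm(ids, values):
    return DistanceMatrix(ids=ids, values=np.asarray(values, dtype=float))


def test_nj_four_taxon_additive_exact():
    """Additive matrix from ((A,B),(C,D)) with distinct internal paths:
    NJ returns the AB|CD split and reproduces every pairwise distance."""
    # pendant lengths A=1, B=2, C=4, D=5, internal = 3
    values = [
        [0, 3, 8, 9],
        [3, 0, 9, 10],
        [8, 9, 0, 9],
        [9, 10, 9, 0],
    ]
    dm = _dm(list("ABCD"), values)
    tree = nj_tree(dm)
    assert bipartition_set(tree) == {frozenset({"C", "D"})} or bipartition_set(
        tree
    ) == {frozenset({"A", "B"})}
    labels = list("ABCD")
    recovered = patristic_matrix(tree, labels)
    assert np.allclose(recovered, np.array(values, dtype=float), atol=1e-9)


def test_nj_identical_rows_form_cherry():
    values = [
        [0, 0, 5, 6],
        [0, 0, 5, 6],
        [5, 5, 0, 3],
        [6, 6, 3, 0],
    ]
    tree = nj_tree(_dm(list("ABCD"), values))
    sides = bipartition_set(tree)
    assert frozenset({"A", "B"}) in sides or frozenset({"C", "D"}) in sides


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError):
        nj_tree(_dm(["a", "b"], [[0, 1], [1, 0]]))


def test_nj_three_taxa():
    tree = nj_tree(_dm(list("ABC"), [[0, 2, 3], [2, 0, 5], [3, 5, 0]]))
    assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set("ABC")
    recovered = patristic_matrix(tree, list("ABC"))
    assert np.allclose(recovered, [[0, 2, 3], [2, 0, 5], [3, 5, 0]])


def test_nj_consistent_on_random_additive_matrices():
    """NJ recovers topology and path lengths exactly on additive input."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        n = int(rng.integers(6, 13))
        true_tree, dm = random_additive_instance(n, rng)
        inferred = nj_tree(dm)
        assert rf_distance(inferred, true_tree) == 0
        labels = list(dm.ids)
        assert np.allclose(
            patristic_matrix(inferred, labels), dm.values, atol=1e-6
        )


def test_nj_five_taxon_matches_minimum_evolution():
    rng = np.random.default_rng(3)
    for _ in range(10):
        _, dm = random_additive_instance(5, rng)
        nj = nj_tree(dm)
        assert tree_cherry_pairs(nj) == frozenset(minimum_evolution_topology(dm))


def test_nj_branch_lengths_never_negative(rng):
    """Even on noisy, non-additive matrices the clamping rule holds."""
    for _ in range(10):
        n = int(rng.integers(4, 10))
        noise = rng.uniform(0, 1, size=(n, n))
        values = noise + noise.T
        np.fill_diagonal(values, 0.0)
        tree = nj_tree(_dm([f"t{i}" for i in range(n)], values))
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                assert node.edge.length >= 0


def test_nj_leaf_relabeling_equivariance(rng):
    _, dm = random_additive_instance(8, rng)
    tree = nj_tree(dm)
    mapping = dict(zip(dm.ids, [f"x{i}" for i in range(len(dm.ids))]))
    relabeled_dm = DistanceMatrix(
        ids=[mapping[i] for i in dm.ids], values=dm.values
    )
    relabeled_tree = nj_tree(relabeled_dm)
    expected = {
        frozenset(mapping[x] for x in side) for side in bipartition_set(tree)
    }
    # normalize to the min-label convention of the relabeled leaf set
    labels = set(mapping.values())
    ref = min(labels)
    expected = {s if ref not in s else frozenset(labels - s) for s in expected}
    assert bipartition_set(relabeled_tree) == expected


def test_newick_roundtrip_small():
    text = "(A:1,B:2,(C:3,D:4):5);"
    tree = from_newick(text)
    again = from_newick(to_newick(tree))
    assert rf_distance(tree, again) == 0
    assert np.allclose(
        patristic_matrix(again, list("ABCD")),
        patristic_matrix(tree, list("ABCD")),
    )


def test_newick_accepts_unlabeled_internals():
    tree = from_newick("((A,B),(C,D),E);")
    assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set("ABCDE")


def test_newick_rejects_malformed():
    with pytest.raises(ValueError):
        from_newick("((A,B)")


def test_newick_roundtrip_large(rng):
    tree = phyrn.sample_tree(545, branch_length_mean=0.1, rng=rng)
    again = from_newick(to_newick(tree))
    assert rf_distance(tree, again) == 0
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    sub = rng.choice(labels, size=12, replace=False).tolist()
    # spot-check path lengths on a subset (full 545x545 is unnecessary)
    assert np.allclose(
        patristic_matrix(tree, sub), patristic_matrix(again, sub), rtol=1e-9
    )


def test_rf_examples():
    t1 = from_newick("((A,B),(C,D));")
    t2 = from_newick("((A,C),(B,D));")
    assert rf_distance(t1, t1) == 0
    assert rf_distance(t1, t2) == 2
    with pytest.raises(ValueError):
        rf_distance(t1, from_newick("((A,B),(C,E));"))


def test_rf_matches_dendropy(rng):
    """Cross-check the native bipartition comparison against dendropy's
    implementation on random tree pairs."""
    for trial in range(10):
        n = int(rng.integers(5, 12))
        t1 = phyrn.sample_tree(n, 1.0, rng)
        t2 = phyrn.sample_tree(n, 1.0, rng)
        mine = rf_distance(t1, t2)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(
            data=to_newick(t1), schema="newick", taxon_namespace=tns
        )
        d2 = dendropy.Tree.get(
            data=to_newick(t2), schema="newick", taxon_namespace=tns
        )
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        theirs = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert mine == theirs


def test_reroot_at_outgroup():
    tree = from_newick("((A:1,B:1):1,(C:1,D:1):1,E:2);")
    rooted = phyrn.treebuild.reroot_at_outgroup(tree, "E")
    assert rooted.is_rooted
    # topology is unchanged in the unrooted sense
    assert rf_distance(tree, rooted) == 0
    with pytest.raises(ValueError):
        phyrn.treebuild.reroot_at_outgroup(tree, "Z")
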