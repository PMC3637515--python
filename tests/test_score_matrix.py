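import math

import numpy as np
import pytest

import phyrn
from phyrn.score_matrix import (
    CompositeMatrix,
    DistanceMatrix,
    apply_retention,
    euclidean_distances,
    scale_unit,
)
from phyrn.treebuild import bipartition_set, nj_tree


def _matrix_from_values(values, retained=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if retained is None:
        retained = np.ones((n, m), dtype=bool)
    return CompositeMatrix(
        query_ids=[f"q{i}" for i in range(n)],
        pssm_ids=[f"p{j}" for j in range(m)],
        values=values,
        retained=retained,
    )


def test_retention_keeps_exact_count(rng):
    values = rng.uniform(0, 10000, size=(6, 100))
    out, retained = apply_retention(values, 0.75)
    assert np.all(retained.sum(axis=1) == 75)
    assert np.all(out[~retained] == 0)
    # retained cells are the per-row top 75
    for i in range(6):
        kept = np.sort(values[i][retained[i]])
        dropped = values[i][~retained[i]]
        assert kept.min() >= dropped.max()


def test_retention_identity_at_full_fraction(rng):
    values = rng.uniform(0, 10000, size=(4, 10))
    out, retained = apply_retention(values, 1.0)
    assert np.array_equal(out, values)
    assert retained.all()


def test_retention_tie_rule_prefers_small_index():
    values = np.full((1, 8), 500.0)
    out, retained = apply_retention(values, 0.75)
    assert list(np.nonzero(retained[0])[0]) == list(range(math.ceil(0.75 * 8)))


def test_retention_rejects_bad_fraction(rng):
    with pytest.raises(ValueError):
        apply_retention(rng.uniform(size=(2, 4)), 0.0)
    with pytest.raises(ValueError):
        apply_retention(rng.uniform(size=(2, 4)), 1.2)


def test_euclidean_examples():
    cm = _matrix_from_values(
        [[0, 0, 0], [10000, 0, 0], [10000, 0, 0], [3, 4, 0]]
    )
    dm = euclidean_distances(cm)
    assert dm.values[1, 2] == 0.0
    assert dm.values[0, 1] == 10000.0
    assert dm.values[0, 3] == pytest.approx(5.0)


def test_euclidean_matches_direct_summation(rng):
    values = rng.uniform(0, 10000, size=(5, 3))
    dm = euclidean_distances(_matrix_from_values(values))
    for i in range(5):
        for j in range(5):
            direct = math.sqrt(sum((values[i, k] - values[j, k]) ** 2 for k in range(3)))
            assert dm.values[i, j] == pytest.approx(direct, rel=1e-12)


def test_euclidean_masked_drop_ignores_unshared_columns():
    values = np.array([[100.0, 0.0], [100.0, 50.0]])
    retained = np.array([[True, False], [True, True]])
    cm = _matrix_from_values(np.where(retained, values, 0.0), retained)
    dm_zero = euclidean_distances(cm, masked="zero")
    dm_drop = euclidean_distances(cm, masked="drop")
    assert dm_zero.values[0, 1] == pytest.approx(50.0)
    assert dm_drop.values[0, 1] == pytest.approx(0.0)


def test_permutation_equivariance(rng):
    values = rng.uniform(0, 10000, size=(6, 5))
    dm = euclidean_distances(_matrix_from_values(values))
    perm = rng.permutation(6)
    dm_perm = euclidean_distances(_matrix_from_values(values[perm]))
    assert np.allclose(dm_perm.values, dm.values[np.ix_(perm, perm)])


def test_triangle_inequality(rng):
    values = rng.uniform(0, 10000, size=(7, 4))
    d = euclidean_distances(_matrix_from_values(values)).values
    n = len(d)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-6


def test_scale_unit(rng):
    values = rng.uniform(0, 500, size=(5, 3))
    dm = euclidean_distances(_matrix_from_values(values))
    scaled = scale_unit(dm)
    assert scaled.values.max() == pytest.approx(1.0)
    # idempotent and order-preserving
    again = scale_unit(scaled)
    assert np.allclose(again.values, scaled.values)
    iu = np.triu_indices(5, 1)
    assert np.array_equal(np.argsort(dm.values[iu]), np.argsort(scaled.values[iu]))


def test_scale_unit_rejects_all_zero():
    dm = DistanceMatrix(ids=["a", "b"], values=np.zeros((2, 2)))
    with pytest.raises(ValueError):
        scale_unit(dm)


def test_duplicate_queries_form_cherry(rng):
    """Identical matrix rows sit at distance zero and NJ pairs them."""
    base = rng.uniform(0, 10000, size=(5, 6))
    base[1] = base[0]
    dm = euclidean_distances(_matrix_from_values(base))
    assert dm.values[0, 1] == 0.0
    tree = nj_tree(dm)
    # the cherry side contains the reference leaf q0, so it is stored as
    # its complement
    assert frozenset({"q2", "q3", "q4"}) in bipartition_set(tree)


def test_tsv_roundtrip(tmp_path, rng):
    values = rng.uniform(0, 10000, size=(4, 5))
    out, retained = apply_retention(values, 0.6)
    cm = _matrix_from_values(out, retained)
    cm.to_tsv(tmp_path / "m.tsv")
    back = CompositeMatrix.from_tsv(tmp_path / "m.tsv")
    assert back.query_ids == cm.query_ids
    assert back.pssm_ids == cm.pssm_ids
    assert np.allclose(back.values, cm.values, atol=1e-5)
    assert np.array_equal(back.retained, cm.retained)


def test_phylip_roundtrip(tmp_path, rng):
    values = rng.uniform(0, 10000, size=(5, 3))
    dm = euclidean_distances(_matrix_from_values(values))
    dm.to_phylip(tmp_path / "d.phy")
    back = DistanceMatrix.from_phylip(tmp_path / "d.phy")
    assert back.ids == dm.ids
    assert np.allclose(back.values, dm.values, rtol=1e-9)


def test_composite_matrix_on_library(small_family, small_library):
    cm = phyrn.build_composite_matrix(
        small_family.leaf_records, small_library, b_fraction=0.75
    )
    n, m = cm.shape
    assert n == len(small_family.leaf_records)
    assert m == len(small_library)
    assert np.all(cm.retained.sum(axis=1) == math.ceil(0.75 * m))
    assert cm.values.min() >= 0 and cm.values.max() <= 10000
    # self coordinates score highest per row
    for i, qid in enumerate(cm.query_ids):
        j = cm.pssm_ids.index(qid)
        assert cm.values[i, j] == cm.values[i].max()
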