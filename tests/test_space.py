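import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synkin.space import (
    Dendrogram,
    FlaggedObjectError,
    InvalidInputError,
    ObjectSet,
    RatingMatrix,
    SimilarityMatrix,
    aggregate_ratings,
    build_dendrogram,
    compute_rdm,
    entanglement,
    entanglement_permutation_test,
    select_high_centrality,
    untangle_trees,
)


def _ladder_tree(n, reverse=False):
    """Caterpillar tree: leaves join one at a time; leaf order 0..n-1."""
    merges = []
    cluster = 0
    height = 1.0
    for leaf in range(1, n):
        merges.append([cluster, leaf, height, leaf + 1])
        cluster = n + leaf - 1
        height += 1.0
    order = np.arange(n)[::-1] if reverse else np.arange(n)
    return Dendrogram(np.array(merges), [f"o{i}" for i in range(n)], order)


class TestAggregateRatings:
    def test_all_ones_87_raters(self):
        votes = np.ones((2, 3, 87), dtype=int)
        rm = aggregate_ratings(votes, ["s0", "s1"], ["a", "b", "c"])
        assert np.all(rm.loadings == 1.0)

    def test_mixed_half(self):
        votes = np.array([1, 0, 1, 0]).reshape(1, 1, 4)
        rm = aggregate_ratings(votes, ["s0"], ["a"])
        assert rm.loadings[0, 0] == 0.5

    def test_single_rater_identity(self, rng):
        votes = rng.integers(0, 2, size=(4, 5, 1))
        rm = aggregate_ratings(votes, [f"s{i}" for i in range(4)], [f"o{i}" for i in range(5)])
        assert np.array_equal(rm.loadings, votes[:, :, 0].astype(float))

    def test_non_binary_rejected(self):
        votes = np.full((1, 1, 3), 0.5)
        with pytest.raises(InvalidInputError):
            aggregate_ratings(votes, ["s0"], ["a"])

    def test_drop_catch_trial_columns(self):
        votes = np.ones((1, 3, 2), dtype=int)
        rm = aggregate_ratings(votes, ["s0"], ["a", "catch", "b"], drop_objects=["catch"])
        assert rm.object_ids == ["a", "b"]


class TestMedianSplit:
    def test_66_distinct_values_top_33(self, rng):
        vals = rng.permutation(np.linspace(1, 5, 66))
        objs = ObjectSet([f"o{i}" for i in range(66)], vals, np.ones(66))
        high = select_high_centrality(objs)
        assert len(high.object_ids) == 33
        assert set(high.centrality) == set(np.sort(vals)[33:])

    def test_symmetric_split(self):
        objs = ObjectSet(["a", "b", "c", "d"], [1, 1, 5, 5], np.ones(4))
        high = select_high_centrality(objs)
        assert high.object_ids == ["c", "d"]

    def test_all_ties_empty_with_warning(self):
        objs = ObjectSet(["a", "b", "c"], [3, 3, 3], np.ones(3))
        with pytest.warns(UserWarning):
            high = select_high_centrality(objs)
        assert high.object_ids == []


class TestComputeRdm:
    def test_identical_columns_zero(self):
        m = np.array([[1.0, 1.0], [0.0, 0.0], [2.0, 2.0]])
        rdm = compute_rdm(m, ["a", "b"])
        assert rdm.values[0, 1] == pytest.approx(0.0)

    def test_anticorrelated_columns_two(self):
        m = np.array([[1.0, -1.0], [0.0, 0.0], [-1.0, 1.0]])
        rdm = compute_rdm(m, ["a", "b"])
        assert rdm.values[0, 1] == pytest.approx(2.0)

    def test_hand_computed_example(self):
        # columns (1,0,0) and (0,1,0): r = -0.5, distance 1.5
        m = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        rdm = compute_rdm(m, ["a", "b"])
        assert rdm.values[0, 1] == pytest.approx(1.5)

    def test_zero_variance_column_flagged(self):
        m = np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        with pytest.raises(FlaggedObjectError) as err:
            compute_rdm(m, ["flat", "ok"])
        assert "flat" in str(err.value)

    def test_rsm_rdm_duality(self, ratings_small):
        rdm = compute_rdm(ratings_small)
        rsm = rdm.to_rsm()
        off = ~np.eye(rdm.n_objects, dtype=bool)
        assert np.allclose(rsm.values[off], 1.0 - rdm.values[off])
        assert np.allclose(np.diag(rsm.values), 1.0)
        assert np.allclose(np.diag(rdm.values), 0.0)


class TestSimilarityMatrix:
    def test_asymmetric_rejected(self):
        v = np.array([[0.0, 0.5], [0.9, 0.0]])
        with pytest.raises(InvalidInputError):
            SimilarityMatrix(v, "dissimilarity", ["a", "b"])

    def test_wrong_diagonal_rejected(self):
        v = np.array([[0.5, 0.2], [0.2, 0.5]])
        with pytest.raises(InvalidInputError):
            SimilarityMatrix(v, "similarity", ["a", "b"])


class TestDendrogram:
    def test_two_cluster_structure_first_merges_within(self):
        """Brute-force check on a 6-object two-cluster instance: the first
        n-2 merges happen within a planted cluster."""
        rng = np.random.default_rng(7)
        base = np.zeros((10, 6))
        base[:5, :3] = 1.0
        base[5:, 3:] = 1.0
        base += 0.01 * rng.standard_normal(base.shape)
        rdm = compute_rdm(base, [f"o{i}" for i in range(6)])
        tree = build_dendrogram(rdm)
        cluster = {f"o{i}": (0 if i < 3 else 1) for i in range(6)}
        n = 6
        members: dict[int, set] = {i: {tree.object_ids[i]} for i in range(n)}
        for k, row in enumerate(tree.merges[:-1]):  # all but the final merge
            a, b = int(row[0]), int(row[1])
            ca = {cluster[m] for m in members[a]}
            cb = {cluster[m] for m in members[b]}
            assert len(ca | cb) == 1, f"merge {k} crosses planted clusters"
            members[n + k] = members.pop(a) | members.pop(b)

    def test_two_objects_single_merge(self):
        rdm = SimilarityMatrix(np.array([[0.0, 0.8], [0.8, 0.0]]), "dissimilarity", ["a", "b"])
        tree = build_dendrogram(rdm)
        assert tree.merges.shape[0] == 1
        assert sorted(tree.leaf_labels()) == ["a", "b"]

    def test_order_invariance_up_to_relabel(self, ratings_small, rng):
        rdm = compute_rdm(ratings_small)
        perm = rng.permutation(rdm.n_objects)
        rdm2 = SimilarityMatrix(
            rdm.values[np.ix_(perm, perm)], "dissimilarity",
            [rdm.object_ids[i] for i in perm],
        )
        t1 = build_dendrogram(rdm)
        t2 = build_dendrogram(rdm2)
        assert np.allclose(np.sort(t1.merges[:, 2]), np.sort(t2.merges[:, 2]))
        # same partition at every merge height
        from scipy.cluster.hierarchy import fcluster
        for k in (2, 3, 4):
            c1 = fcluster(t1.merges, k, criterion="maxclust")
            c2 = fcluster(t2.merges, k, criterion="maxclust")
            p1 = {frozenset(np.array(t1.object_ids)[c1 == g]) for g in set(c1)}
            p2 = {frozenset(np.array(t2.object_ids)[c2 == g]) for g in set(c2)}
            assert p1 == p2

    def test_newick_roundtrip_parses(self, ratings_small):
        import io
        from Bio import Phylo

        tree = build_dendrogram(compute_rdm(ratings_small))
        parsed = Phylo.read(io.StringIO(tree.to_newick()), "newick")
        leaves = sorted(term.name for term in parsed.get_terminals())
        assert leaves == sorted(tree.object_ids)


class TestEntanglement:
    def test_identical_trees_zero(self, ratings_small):
        tree = build_dendrogram(compute_rdm(ratings_small))
        assert entanglement(tree, tree) == 0.0

    def test_reversed_ladder_is_one(self):
        d1 = _ladder_tree(8)
        d2 = _ladder_tree(8, reverse=True)
        assert entanglement(d1, d2) == pytest.approx(1.0)

    def test_symmetry(self, ratings_small):
        t1 = build_dendrogram(compute_rdm(ratings_small))
        t2 = t1.with_leaf_order(np.roll(t1.leaf_order, 3))
        assert entanglement(t1, t2) == pytest.approx(entanglement(t2, t1))

    def test_range_under_random_orders(self, rng):
        d1 = _ladder_tree(10)
        for _ in range(50):
            d2 = d1.with_leaf_order(rng.permutation(10))
            e = entanglement(d1, d2)
            assert 0.0 <= e <= 1.0

    def test_reversal_is_worst_case_brute_force(self):
        """Exhaustive check at n=6: no leaf permutation exceeds the
        reversed order under the default norm."""
        from itertools import permutations

        d1 = _ladder_tree(6)
        target = entanglement(d1, _ladder_tree(6, reverse=True))
        for perm in permutations(range(6)):
            e = entanglement(d1, d1.with_leaf_order(np.array(perm)))
            assert e <= target + 1e-12

    def test_mismatched_leaves_rejected(self):
        d1 = _ladder_tree(5)
        d2 = _ladder_tree(6)
        with pytest.raises(InvalidInputError):
            entanglement(d1, d2)

    def test_untangle_reduces_or_preserves(self, ratings_small, rng):
        t1 = build_dendrogram(compute_rdm(ratings_small))
        t2 = t1.with_leaf_order(rng.permutation(t1.n_leaves))
        raw = entanglement(t1, t2)
        u1, u2 = untangle_trees(t1, t2)
        assert entanglement(u1, u2) <= raw + 1e-12


class TestEntanglementPermutation:
    def test_identical_trees_minimal_p(self, ratings_small):
        tree = build_dendrogram(compute_rdm(ratings_small))
        res = entanglement_permutation_test(tree, tree, n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1.0 / 100.0)

    def test_determinism(self, ratings_small):
        t1 = build_dendrogram(compute_rdm(ratings_small))
        t2 = t1.with_leaf_order(np.roll(t1.leaf_order, 5))
        r1 = entanglement_permutation_test(t1, t2, n_perm=200, seed=11)
        r2 = entanglement_permutation_test(t1, t2, n_perm=200, seed=11)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.null, r2.null)

    def test_super_uniform_under_shuffled_labels(self, rng):
        """p-values on unstructured rating pairs should not be anticonservative."""
        from conftest import small_config
        from synkin.synthetic import generate_ratings

        n_rep, hits = 60, 0
        for rep in range(n_rep):
            cfg = small_config(seed=1000 + rep, n_objects=10, n_synergies=8)
            _, ratings = generate_ratings(cfg)
            t1 = build_dendrogram(compute_rdm(ratings))
            perm = rng.permutation(10)
            shuffled = t1.relabel([t1.object_ids[i] for i in perm])
            res = entanglement_permutation_test(t1, shuffled, n_perm=99, seed=rep)
            hits += res.p_value <= 0.05
        # binomial 95% upper bound at p=0.05, n=60 is ~7
        assert hits <= 7


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=4, max_value=12), st.integers(min_value=0, max_value=10**6))
def test_entanglement_always_in_unit_interval(n, seed):
    rng = np.random.default_rng(seed)
    d1 = _ladder_tree(n)
    d2 = d1.with_leaf_order(rng.permutation(n))
    e = entanglement(d1, d2, norm_power=1.5)
    assert 0.0 <= e <= 1.0


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=2, max_value=40))
def test_rating_matrix_rejects_out_of_range(n):
    load = np.full((3, n), 1.1)
    with pytest.raises(InvalidInputError):
        RatingMatrix(load, ["a", "b", "c"], [f"o{i}" for i in range(n)])
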