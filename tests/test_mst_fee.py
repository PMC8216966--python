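import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from feediv import (
    Community,
    SpeciesPool,
    adjust_distances,
    compute_mst,
    evenness_component,
    fee0,
    fee0_for_community,
    euclidean_distances,
)
from feediv.mst_fee import adjustment_factors
from feediv.traitspace import DistanceMatrix

from conftest import brute_force_mst

branch_vectors = st.lists(
    st.floats(0.0, 10.0, allow_nan=False), min_size=1, max_size=12
).map(np.array)


class TestComputeMST:
    def test_two_points(self):
        d = euclidean_distances(np.array([[0.0], [0.5]]))
        mst = compute_mst(d)
        np.testing.assert_allclose(mst.branch_lengths, [0.5])
        assert mst.total_length == pytest.approx(0.5)

    def test_one_dimensional_points_give_sorted_adjacency_path(self):
        d = euclidean_distances(np.array([[0.1], [0.4], [0.9]]))
        mst = compute_mst(d)
        np.testing.assert_allclose(mst.branch_lengths, [0.3, 0.5])

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="two species"):
            compute_mst(DistanceMatrix(("a",), np.zeros((1, 1))))

    def test_matches_brute_force_on_small_random_communities(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 7))
            pts = rng.random((n, 2))
            d = euclidean_distances(pts)
            mst = compute_mst(d)
            total, lengths = brute_force_mst(d.values)
            assert mst.total_length == pytest.approx(total)
            np.testing.assert_allclose(mst.branch_lengths, lengths)

    def test_edge_count_and_connectivity(self, rng):
        pts = rng.random((15, 3))
        mst = compute_mst(euclidean_distances(pts))
        assert len(mst.edges) == 14
        # n-1 edges touching all n labels means the tree is connected
        touched = {s for e in mst.edges for s in e[:2]}
        assert len(touched) == 15

    def test_zero_length_branches_participate(self):
        pts = np.array([[0.2, 0.2], [0.2, 0.2], [0.8, 0.2]])
        mst = compute_mst(euclidean_distances(pts))
        np.testing.assert_allclose(mst.branch_lengths, [0.0, 0.6])


class TestFee0:
    @pytest.mark.parametrize(
        "l, expected",
        [
            ([0.7], 0.7),  # n = 2: single branch
            ([0.2, 0.2, 0.2], 0.6),  # equal branches attain the sum
            ([0.1, 0.3], 0.3),  # mean 0.2 -> 0.1 + 0.2
        ],
    )
    def test_hand_cases(self, l, expected):
        assert fee0(np.array(l)) == pytest.approx(expected)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError, match="single-species"):
            fee0(np.array([]))

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            fee0(np.array([0.1, -0.2]))

    @settings(derandomize=True, max_examples=200)
    @given(branch_vectors)
    def test_bounded_by_total_length(self, l):
        assert fee0(l) <= l.sum() + 1e-12

    def test_equality_with_total_iff_equal_branches(self, rng):
        for _ in range(300):
            l = rng.random(int(rng.integers(2, 10)))
            if np.ptp(l) > 1e-9:
                assert fee0(l) < l.sum() - 1e-15
        l = np.full(5, 0.37)
        assert fee0(l) == pytest.approx(l.sum())


class TestEvennessComponent:
    @pytest.mark.parametrize(
        "l, expected",
        [
            ([0.2, 0.2, 0.2], 1.0),
            ([0.1, 0.3], 0.75),  # min(.25,.5) + min(.75,.5)
            ([0.42], 1.0),  # n = 2 is always perfectly even
        ],
    )
    def test_hand_cases(self, l, expected):
        assert evenness_component(np.array(l)) == pytest.approx(expected)

    def test_all_coincident_convention(self):
        assert evenness_component(np.zeros(4)) == 1.0

    @settings(derandomize=True, max_examples=200)
    @given(branch_vectors)
    def test_factorization_identity(self, l):
        assert abs(fee0(l) - l.sum() * evenness_component(l)) < 1e-12

    @settings(derandomize=True, max_examples=200)
    @given(branch_vectors)
    def test_range(self, l):
        assert 0.0 < evenness_component(l) <= 1.0 + 1e-12


class TestAdjustDistances:
    def _factor(self, wi, wj, n):
        w = np.array([wi, wj] + [(1 - wi - wj) / (n - 2)] * (n - 2))
        return adjustment_factors(w, n)[0, 1]

    def test_abundant_even_pair_shrinks(self):
        # n=4, w_i = w_j = 0.4: K1 = 0.625, K2 = 1
        assert self._factor(0.4, 0.4, 4) == pytest.approx(0.625)

    def test_rare_pair_left_unadjusted(self):
        # n=4, w_i = w_j = 0.05: K1 = 5, capped at 1
        assert self._factor(0.05, 0.05, 4) == pytest.approx(1.0)

    def test_mixed_common_rare_pair(self):
        # n=4, 0.6 vs 0.05: K1*K2 = 0.7692 * 1.8462 > 1, capped
        assert self._factor(0.6, 0.05, 4) == pytest.approx(1.0)

    def test_equal_abundances_leave_distances_unchanged(self, rng):
        pts = rng.random((6, 2))
        d = euclidean_distances(pts)
        adj = adjust_distances(d, np.full(6, 1 / 6))
        np.testing.assert_allclose(adj.values, d.values)
        assert adj.metric_tag == "adjusted"

    def test_never_exceeds_raw_distance(self, rng):
        for _ in range(500):
            n = int(rng.integers(2, 10))
            d = euclidean_distances(rng.random((n, 3)))
            w = rng.random(n) + 1e-6
            w /= w.sum()
            adj = adjust_distances(d, w)
            assert (adj.values <= d.values + 1e-12).all()

    def test_weight_sum_validated(self, rng):
        d = euclidean_distances(rng.random((3, 2)))
        with pytest.raises(ValueError, match="sum"):
            adjust_distances(d, np.array([0.5, 0.5, 0.5]))


class TestFee0ForCommunity:
    def test_two_species_equals_pair_distance(self, line_pool):
        c = Community(line_pool, ("a", "d"), abundances=np.array([9.0, 1.0]))
        x, mst = fee0_for_community(c, abundance_weighted=True)
        # single pair: adjusted distance of the pair itself
        w = np.array([0.9, 0.1])
        K1 = (2 / 2) / 1.0
        K2 = 2 * 9 / 10
        expected = min(K1 * K2, 1.0) * 0.9
        assert x == pytest.approx(expected)

    def test_equal_abundance_mode_identity(self, line_pool):
        c_eq = Community(
            line_pool, ("a", "b", "c", "d"),
            abundances=np.array([2.0, 2.0, 2.0, 2.0]),
        )
        x_on, _ = fee0_for_community(c_eq, abundance_weighted=True)
        x_off, _ = fee0_for_community(c_eq, abundance_weighted=False)
        assert x_on == pytest.approx(x_off)

    def test_equally_spaced_line(self, line_community):
        x, mst = fee0_for_community(line_community)
        assert x == pytest.approx(0.9)
        np.testing.assert_allclose(mst.branch_lengths, [0.3, 0.3, 0.3])

    def test_zero_abundance_member_dropped_with_warning(self, line_pool):
        c = Community(
            line_pool, ("a", "b", "d"),
            abundances=np.array([1.0, 1.0, 0.0]),
        )
        with pytest.warns(UserWarning, match="zero-abundance"):
            x, mst = fee0_for_community(c, abundance_weighted=True)
        assert mst.n_branches == 1  # only a and b remain
        assert x == pytest.approx(0.3)

    def test_permutation_invariance(self, rng):
        ids = [f"s{i}" for i in range(8)]
        pts = rng.random((8, 2))
        pool = SpeciesPool.from_normalized(ids, pts)
        A = rng.random(8) + 0.1
        base = None
        for _ in range(5):
            perm = rng.permutation(8)
            c = Community(
                pool, tuple(ids[i] for i in perm), abundances=A[perm]
            )
            for mode in (False, True):
                x, _ = fee0_for_community(c, abundance_weighted=mode)
                key = ("val", mode)
                if base is None:
                    base = {}
                if key not in base:
                    base[key] = x
                assert x == pytest.approx(base[key], abs=1e-12)
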