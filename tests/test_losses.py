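import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from datbio import (contrastive_loss, pair_distance, triplet_distances,
                    triplet_loss)

vec = arrays(np.float64, 8, elements=st.floats(-10, 10, allow_nan=False))


class TestPairDistance:
    def test_identical_vectors_at_zero(self):
        assert pair_distance(np.ones(4), np.ones(4)) == 0.0

    def test_three_four_five(self):
        assert pair_distance([0.0, 0.0], [3.0, 4.0]) == pytest.approx(5.0)

    def test_orthonormal_unit_vectors(self):
        assert pair_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(np.sqrt(2))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pair_distance(np.zeros(3), np.zeros(4))

    @given(vec, vec)
    def test_symmetry(self, a, b):
        assert pair_distance(a, b) == pytest.approx(pair_distance(b, a))

    @given(vec, vec)
    def test_identity_of_indiscernibles(self, a, b):
        d = pair_distance(a, b)
        assert d >= 0
        if np.array_equal(a, b):
            assert d == 0
        else:
            assert d > 0

    @given(vec, vec, vec)
    def test_triangle_inequality(self, a, b, c):
        assert pair_distance(a, c) <= (pair_distance(a, b)
                                       + pair_distance(b, c) + 1e-9)


class TestContrastiveLoss:
    def test_coincident_same_class_pair_costs_nothing(self):
        assert contrastive_loss(0.0, Y=1, m=1.0) == 0.0

    def test_different_class_pair_beyond_margin_costs_nothing(self):
        assert contrastive_loss(1.0, Y=0, m=1.0) == 0.0
        assert contrastive_loss(2.5, Y=0, m=1.0) == 0.0

    def test_coincident_different_class_pair_costs_half_margin_squared(self):
        assert contrastive_loss(0.0, Y=0, m=1.0) == pytest.approx(0.5)

    def test_as_printed_variant_swaps_the_roles(self):
        # literal published form: hinge acts on same-class pairs
        assert contrastive_loss(0.0, Y=0, m=1.0, as_printed=True) == 0.0
        assert contrastive_loss(0.0, Y=1, m=1.0, as_printed=True) == pytest.approx(0.5)

    @given(st.floats(0, 10), st.integers(0, 1), st.floats(0.01, 5))
    def test_nonnegative_everywhere(self, d, y, m):
        assert contrastive_loss(d, y, m) >= 0.0

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            contrastive_loss(1.0, Y=2, m=1.0)

    def test_nonpositive_margin_rejected(self):
        with pytest.raises(ValueError):
            contrastive_loss(1.0, Y=1, m=0.0)


class TestTripletLoss:
    def test_distances_match_pair_distance(self, rng):
        a, p, n = (rng.standard_normal(8) for _ in range(3))
        d_ap, d_an = triplet_distances(a, p, n)
        assert d_ap == pytest.approx(pair_distance(a, p))
        assert d_an == pytest.approx(pair_distance(a, n))

    def test_distances_swap_with_positive_negative(self, rng):
        a, p, n = (rng.standard_normal(8) for _ in range(3))
        assert triplet_distances(a, p, n) == tuple(reversed(triplet_distances(a, n, p)))

    def test_coincident_triplet_gives_zero_distances(self):
        e = np.ones(4)
        assert triplet_distances(e, e, e) == (0.0, 0.0)

    def test_satisfied_margins_cost_nothing(self):
        a = np.zeros((1, 2))
        p = np.zeros((1, 2))
        n = np.array([[2.0, 0.0]])  # d_an^2 = 4 >= alpha
        assert triplet_loss(a, p, n, alpha=0.5) == 0.0

    def test_single_triplet_hand_computation(self):
        # d_ap^2 = 2, d_an^2 = 1, alpha = 0.5 -> 1.5
        a = np.array([[0.0, 0.0]])
        p = np.array([[1.0, 1.0]])
        n = np.array([[1.0, 0.0]])
        assert triplet_loss(a, p, n, alpha=0.5) == pytest.approx(1.5)

    def test_degenerate_coincident_triplet_costs_alpha(self):
        e = np.ones((1, 4))
        assert triplet_loss(e, e, e, alpha=0.5) == pytest.approx(0.5)

    def test_empty_batch_warns_and_returns_zero(self):
        empty = np.empty((0, 4))
        with pytest.warns(UserWarning, match="empty"):
            assert triplet_loss(empty, empty, empty, alpha=0.5) == 0.0

    @given(arrays(np.float64, (3, 4), elements=st.floats(-5, 5, allow_nan=False)),
           arrays(np.float64, (3, 4), elements=st.floats(-5, 5, allow_nan=False)),
           arrays(np.float64, (3, 4), elements=st.floats(-5, 5, allow_nan=False)))
    def test_nonnegative_for_random_embeddings(self, a, p, n):
        assert triplet_loss(a, p, n, alpha=0.3) >= 0.0

    def test_hinge_inactive_when_all_margins_satisfied(self, rng):
        a = rng.standard_normal((5, 4))
        p = a + 1e-3 * rng.standard_normal((5, 4))
        n = a + 10.0 + rng.standard_normal((5, 4))
        assert triplet_loss(a, p, n, alpha=0.1) == 0.0

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            triplet_loss(np.ones((1, 2)), np.ones((1, 2)), np.ones((1, 2)),
                         alpha=0.0)
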