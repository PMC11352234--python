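import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from datbio import (Epoch, SAACurve, crossover_summary, detect_crossover,
                    erp_average, saa_curve, similarity_before_after,
                    similarity_during)

# worked-example crossover triples (before, during, after) -> (S_BA, S_DR)
EXAMPLE_TRIPLES = [
    ((210, 193, 203), 7.0, 13.5),
    ((173, 135, 167), 6.0, 35.0),
    ((116, 170, 149), 33.0, 37.5),
    ((146, 187, 132), 14.0, 48.0),
    ((181, 103, 167), 14.0, 71.0),
    ((156, 151, 159), 3.0, 6.5),
]


class TestErpAverage:
    def test_mean_of_identical_epochs_is_that_epoch(self, rng):
        x = rng.standard_normal(128)
        assert np.allclose(erp_average([x, x, x]), x)

    def test_opposite_epochs_cancel(self, rng):
        x = rng.standard_normal(64)
        assert np.allclose(erp_average([x, -x]), 0.0)

    def test_matches_explicit_loop_mean(self, rng):
        epochs = [rng.standard_normal(32) for _ in range(7)]
        expected = np.zeros(32)
        for e in epochs:  # independent brute-force accumulation
            expected += e
        expected /= len(epochs)
        assert np.allclose(erp_average(epochs), expected)

    def test_accepts_epoch_objects(self, rng):
        eps = [Epoch(samples=rng.standard_normal(16), subject_id="S01",
                     phase="before", start=0) for _ in range(3)]
        assert erp_average(eps).shape == (16,)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            erp_average([np.zeros(8), np.zeros(9)])

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            erp_average([])


class TestSaaCurve:
    def test_white_noise_slope_near_half(self, rng):
        """The fluctuation curve of uncorrelated noise has Hurst slope 1/2."""
        curve = saa_curve(rng.standard_normal(8192))
        assert curve.slope == pytest.approx(0.5, abs=0.1)

    def test_constant_signal_flags_degenerate(self):
        curve = saa_curve(np.full(1024, 3.7))
        assert curve.degenerate

    def test_amplitude_scaling_shifts_curve_by_log_factor(self, rng):
        x = rng.standard_normal(4096)
        c1, c2 = saa_curve(x), saa_curve(2.0 * x)
        assert c2.slope == pytest.approx(c1.slope, abs=1e-9)
        assert np.allclose(c2.log_fluct - c1.log_fluct, np.log10(2.0))

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            saa_curve(np.zeros(8))


def curve_from_residuals(resid):
    """Build a curve whose residuals against its reference equal *resid*."""
    resid = np.asarray(resid, dtype=float)
    n = resid.size
    log_s = np.arange(n, dtype=float)
    return SAACurve(log_scales=log_s, log_fluct=resid, slope=0.0, intercept=0.0)


class TestDetectCrossover:
    def test_first_sign_change_index(self):
        idx, found = detect_crossover(curve_from_residuals([1.0, 0.5, -0.2, -1.0]))
        assert (idx, found) == (2, True)

    def test_no_crossing_flagged(self):
        idx, found = detect_crossover(curve_from_residuals([0.5, 1.0, 2.0]))
        assert (idx, found) == (0, False)

    def test_crossing_count_matches_direct_count(self):
        resid = [1, -1, 1, -1, 1, -1, 1]  # alternates sign six times
        count, found = detect_crossover(curve_from_residuals(resid),
                                        mode="crossing_count")
        assert (count, found) == (6, True)

    def test_degenerate_curve_rejected(self):
        curve = saa_curve(np.zeros(1024))
        with pytest.raises(ValueError, match="degenerate"):
            detect_crossover(curve)

    def test_zero_reference_uses_raw_ordinates(self):
        curve = curve_from_residuals([0.5, -0.5])
        idx, found = detect_crossover(curve, reference="zero")
        assert (idx, found) == (1, True)


class TestCrossoverSimilarity:
    @pytest.mark.parametrize("triple,s_ba,s_dr", EXAMPLE_TRIPLES)
    def test_worked_example_triples(self, triple, s_ba, s_dr):
        cb, cd, ca = triple
        assert similarity_before_after(cb, ca) == s_ba
        assert similarity_during(cb, cd, ca) == s_dr

    def test_exploratory_example(self):
        assert similarity_before_after(11, 17) == 6.0
        assert similarity_during(11, 107, 17) == 93.0

    def test_identity_when_all_crossovers_equal(self):
        assert similarity_before_after(42, 42) == 0.0
        assert similarity_during(42, 42, 42) == 0.0

    def test_summary_bundles_both_statistics(self):
        cs = crossover_summary(210, 193, 203)
        assert (cs.S_BA, cs.S_DR) == (7.0, 13.5)

    def test_negative_crossovers_rejected(self):
        with pytest.raises(ValueError):
            similarity_before_after(-1, 5)

    @given(st.integers(0, 300), st.integers(0, 300))
    def test_before_after_symmetry(self, a, b):
        assert similarity_before_after(a, b) == similarity_before_after(b, a)

    def test_s_dr_zero_iff_all_equal_small_grid(self):
        for cb, cd, ca in itertools.product(range(6), repeat=3):
            s_dr = similarity_during(cb, cd, ca)
            assert (s_dr == 0) == (cb == cd == ca)

    def test_triangle_bound_s_dr_at_least_half_s_ba(self):
        """|CA-CD| + |CD-CB| >= |CA-CB| for every integer triple."""
        for cb, cd, ca in itertools.product(range(12), repeat=3):
            assert similarity_during(cb, cd, ca) >= similarity_before_after(cb, ca) / 2
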