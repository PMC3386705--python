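"""Estimator correctness: closed-form oracles, reductions, edge cases."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from flimkit import (AcquisitionConfig, DecayModel, GateCounts, Histogram,
                     PhotonList, expected_bin_counts, expected_gate_counts)
from flimkit.estimators import (biexp_fit, build_omega_lut, cmm, grld,
                                grld_ratio_root, iem, mle_fit, rld2, rld_m,
                                simpson_weights, _truncated_centroid)

from conftest import gated_cfg


def expected_hist(tau, T, M, A=1000.0, b=0.0):
    return expected_bin_counts(DecayModel([A], [tau], background=b),
                               AcquisitionConfig(T=T, M=M))


class TestRld2:
    def test_unit_log_ratio(self):
        est = rld2(GateCounts(n1=2718.281828, n2=1000.0, S=1, R=2, h=1.0))
        assert est.valid and est.tau == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("tau,h", [(0.3, 0.5), (1.0, 2.4), (7.0, 3.0)])
    def test_noiseless_recovery_exact(self, tau, h):
        gc = expected_gate_counts(DecayModel([100.0], [tau]),
                                  gated_cfg(h=h, S=1.0, R=2.0))
        assert rld2(gc).tau == pytest.approx(tau, rel=1e-12)

    def test_equal_counts_invalid(self):
        est = rld2(GateCounts(n1=100, n2=100, S=1, R=2, h=1.0))
        assert not est.valid and np.isnan(est.tau)

    def test_zero_second_gate_invalid(self):
        assert not rld2(GateCounts(n1=100, n2=0, S=1, R=2, h=1.0)).valid


class TestGrld:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(n1=st.floats(1.0, 1e6), ratio=st.floats(0.01, 0.99))
    def test_reduces_to_rld2_on_arbitrary_counts(self, n1, ratio):
        n2 = n1 * ratio
        a = grld(GateCounts(n1=n1, n2=n2, S=1.0, R=2.0, h=0.8))
        b = rld2(GateCounts(n1=n1, n2=n2, S=1.0, R=2.0, h=0.8))
        assert a.valid and b.valid
        assert a.tau == pytest.approx(b.tau, rel=1e-10)

    def test_noiseless_recovery_overlapping_gates(self, single_exp):
        gc = expected_gate_counts(single_exp, gated_cfg(h=1.0, S=0.2, R=3.2))
        assert grld(gc).tau == pytest.approx(1.0, abs=1e-9)

    def test_root_matches_brentq_oracle(self, rng):
        S, R = 0.25, 4.25
        d = round(R - S)
        ratios = rng.uniform(0.02, d - 0.05, size=50)

        def P(x):
            return x**S * (1 - x ** (R - S)) / (1 - x)

        ours = grld_ratio_root(ratios, S, R)
        for r, x in zip(ratios, ours):
            ref = brentq(lambda y: P(y) - r, 1e-14, 1 - 1e-14, xtol=1e-15)
            assert x == pytest.approx(ref, abs=1e-11)

    def test_chan_setting_accepted(self):
        # the historically suggested overlap setting S=0.25, R=12.25
        gc = expected_gate_counts(DecayModel([10.0], [1.0]),
                                  gated_cfg(h=0.3, S=0.25, R=12.25))
        assert grld(gc).tau == pytest.approx(1.0, abs=1e-9)

    def test_ratio_beyond_range_invalid(self):
        est = grld(GateCounts(n1=100, n2=320, S=0.2, R=3.2, h=1.0))
        assert not est.valid  # N2/N1 >= R-S has no root

    def test_non_integer_geometry_rejected(self):
        with pytest.raises(ValueError):
            grld(GateCounts(n1=10, n2=5, S=0.3, R=3.3, h=1.0))


class TestRldM:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(n0=st.floats(10.0, 1e5), ratio=st.floats(0.01, 0.99))
    def test_two_bins_identical_to_rld2(self, n0, ratio):
        h = 0.4
        est = rld_m(Histogram([n0, n0 * ratio], h=h))
        assert est.tau == pytest.approx(h / np.log(1 / ratio), rel=1e-12)

    @pytest.mark.parametrize("M", [2, 5, 32])
    def test_noiseless_recovery_exact(self, M):
        est = rld_m(Histogram(expected_hist(1.7, 6.0, M).counts, h=6.0 / M))
        assert est.tau == pytest.approx(1.7, rel=1e-12)

    def test_zero_bin_invalid(self):
        counts = expected_hist(1.0, 8.0, 8).counts.copy()
        counts[3] = 0.0
        assert not rld_m(Histogram(counts, h=1.0)).valid


class TestIem:
    def test_simpson_weight_pattern_m7(self):
        w = simpson_weights(7)
        assert np.allclose(w, [1, 4, 2, 4, 2, 4, 1] / np.array(3.0))
        assert w.sum() == pytest.approx(6.0)  # M - 1 intervals

    def test_three_bin_closed_form(self):
        # N = (1, x, x^2) with x = 0.9: tau = h (1 + 4x + x^2)/(3 (1 - x^2))
        x, h = 0.9, 0.25
        est = iem(Histogram(np.array([1.0, x, x * x]) * 500, h=h))
        ref = h * (1 + 4 * x + x * x) / (3 * (1 - x * x))
        assert ref / h == pytest.approx(9.4912281, abs=1e-6)
        assert est.tau == pytest.approx(ref, rel=1e-12)

    def test_constant_offset_cancels_in_denominator(self):
        base = expected_hist(1.0, 5.0, 5).counts
        h = 1.0
        t0 = iem(Histogram(base, h=h)).tau
        t1 = iem(Histogram(base + 200.0, h=h)).tau
        # denominator unchanged; shift comes only from the weighted sum
        w = simpson_weights(5)
        expected_shift = h * 200.0 * w.sum() / (base[0] - base[-1])
        assert t1 - t0 == pytest.approx(expected_shift, rel=1e-9)

    def test_even_bin_count_is_configuration_error(self):
        with pytest.raises(ValueError):
            iem(Histogram(np.ones(8), h=1.0))

    def test_non_decaying_invalid(self):
        assert not iem(Histogram(np.ones(7), h=1.0)).valid

    def test_small_relative_bias_fine_binning(self):
        est = iem(Histogram(expected_hist(1.0, 5.1, 51).counts, h=0.1))
        assert est.tau == pytest.approx(1.0, rel=1e-3)


class TestOmegaLut:
    def test_identity_limit_small_tau(self, omega_lut):
        u = np.array([1e-3, 5e-3, 1e-2])
        assert np.allclose(_truncated_centroid(u), u, rtol=1e-6)

    def test_unit_ratio_closed_form(self, omega_lut):
        g1 = 1 - np.exp(-1) / (1 - np.exp(-1))
        assert g1 == pytest.approx(0.41802, abs=1e-5)
        assert omega_lut(g1) == pytest.approx(1.0, abs=1e-3)

    def test_round_trip_inversion(self, omega_lut):
        u = np.logspace(np.log10(0.01), np.log10(10.0), 400)
        back = omega_lut(_truncated_centroid(u))
        assert np.max(np.abs(back / u - 1)) < 1e-3

    def test_saturation_sentinel(self, omega_lut):
        assert np.isnan(omega_lut(0.5))
        assert np.isnan(omega_lut(0.499999))

    def test_grid_strictly_increasing(self, omega_lut):
        assert np.all(np.diff(omega_lut.grid_g) > 0)

    def test_grid_size_floor(self):
        with pytest.raises(ValueError):
            build_omega_lut(grid_size=100)


class TestCmm:
    def test_all_photons_first_bin_half_bin_centroid(self, omega_lut):
        pl = PhotonList(np.zeros(100, dtype=int), M=64, h=0.1)
        est = cmm(pl, omega_lut)
        # raw centroid h/2 -> ratio 1/(2M), far below saturation
        assert est.valid
        assert est.tau == pytest.approx(omega_lut(0.5 / 64) * 6.4, rel=1e-12)

    def test_noiseless_tau_equals_window(self, omega_lut):
        # tau = T: raw centroid ratio -> 0.418, calibrated back to ~T
        M, T = 256, 4.0
        hist = expected_hist(4.0, T, M)
        est = cmm(hist, omega_lut)
        assert est.valid
        assert est.tau == pytest.approx(T, rel=5e-3)  # LUT + half-bin quantization

    def test_uniform_counts_saturated(self, omega_lut):
        est = cmm(Histogram(np.ones(32), h=1.0), omega_lut)
        assert not est.valid and "satur" in est.diagnostic

    def test_histogram_and_photon_list_agree_exactly(self, omega_lut, rng):
        codes = rng.integers(0, 40, size=5000)
        pl = PhotonList(codes, M=64, h=0.05)
        a = cmm(pl, omega_lut)
        b = cmm(pl.to_histogram(), omega_lut)
        assert a.tau == b.tau

    def test_empty_invalid(self, omega_lut):
        assert not cmm(PhotonList(np.array([], dtype=int), M=8, h=1.0),
                       omega_lut).valid


class TestMleFit:
    def test_noiseless_recovery(self):
        hist = expected_hist(1.0, 8.0, 256)
        assert mle_fit(hist).tau == pytest.approx(1.0, rel=1e-8)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n0=st.floats(50.0, 1e4), ratio=st.floats(0.05, 0.9))
    def test_two_bin_mle_equals_rld2(self, n0, ratio):
        h = 0.6
        hist = Histogram([n0, n0 * ratio], h=h)
        assert mle_fit(hist).tau == pytest.approx(h / np.log(1 / ratio),
                                                  rel=1e-6)

    def test_all_counts_last_bin_invalid(self):
        counts = np.zeros(16)
        counts[-1] = 100
        assert not mle_fit(Histogram(counts, h=1.0)).valid


class TestBiexpFit:
    def test_noiseless_parameter_recovery(self):
        model = DecayModel([1000.0, 1000.0], [0.3, 3.4])
        hist = expected_bin_counts(model, AcquisitionConfig(T=17.0, M=128))
        fit = biexp_fit(hist)
        assert fit.valid and not fit.degenerate
        assert fit.tau1 == pytest.approx(0.3, rel=1e-4)
        assert fit.tau2 == pytest.approx(3.4, rel=1e-4)
        assert fit.a1 == pytest.approx(1000.0, rel=1e-3)
        assert fit.a2 == pytest.approx(1000.0, rel=1e-3)

    def test_single_exponential_flagged_degenerate(self):
        hist = expected_hist(2.0, 10.0, 64)
        fit = biexp_fit(hist)
        assert fit.valid and fit.degenerate
        assert fit.tau_ave == pytest.approx(2.0, rel=1e-2)

    def test_too_few_counts_invalid(self):
        fit = biexp_fit(Histogram(np.full(16, 1.0), h=0.1))
        assert not fit.valid


class TestNoiselessRecoveryAcrossEstimators:
    """Every estimator recovers the generating lifetime on expected counts."""

    TAU, T = 1.3, 6.5

    def test_gated_and_binned_estimators(self, omega_lut):
        tau, T = self.TAU, self.T
        model = DecayModel([800.0], [tau])
        gc2 = expected_gate_counts(model, gated_cfg(h=T / 2, S=1.0, R=2.0))
        assert rld2(gc2).tau == pytest.approx(tau, rel=1e-10)
        gcg = expected_gate_counts(model, gated_cfg(h=T / 3.2, S=0.2, R=3.2))
        assert grld(gcg).tau == pytest.approx(tau, rel=1e-9)
        h51 = expected_bin_counts(model, AcquisitionConfig(T=T, M=51))
        assert rld_m(h51).tau == pytest.approx(tau, rel=1e-10)
        assert mle_fit(h51).tau == pytest.approx(tau, rel=1e-8)
        assert iem(h51).tau == pytest.approx(tau, rel=1e-3)
        h256 = expected_bin_counts(model, AcquisitionConfig(T=T, M=256))
        assert cmm(h256, omega_lut).tau == pytest.approx(tau, rel=5e-3)
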