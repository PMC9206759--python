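"""CF, GCF and the CMSF / CMSAW covariance-weighting chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from _oracles import msr_loops, rotary_average_terms, smooth_covariance_loops
from stabeam.beamform import BeamformerConfig
from stabeam.weights import (
    adaptive_delta,
    aperture_asd,
    apply_pixel_weight,
    cmsaw_weight,
    cmsf_weight,
    coherence_factor,
    diagonal_reduce,
    dynamic_subarray_length,
    generalized_cf,
    matrix_msr,
    normalize_asd,
    rotary_average,
    smooth_covariance,
)

complex_vectors = hnp.arrays(
    np.complex128,
    st.integers(4, 16),
    elements=st.complex_numbers(max_magnitude=10, allow_nan=False, allow_infinity=False),
)


class TestCoherenceFactor:
    @pytest.mark.parametrize(
        "x,expected",
        [
            ([1, 1, 1, 1], 1.0),
            ([1, -1, 1, -1], 0.0),
            ([1, 1, 0, 0], 0.5),
            ([0, 0, 0, 0], 0.0),
        ],
    )
    def test_closed_forms(self, x, expected):
        assert coherence_factor(np.array(x, dtype=float)) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=200)
    @given(complex_vectors)
    def test_bounded_unit_interval(self, x):
        assert 0.0 <= coherence_factor(x) <= 1.0 + 1e-12

    def test_unity_iff_identical_entries(self, rng):
        c = rng.standard_normal() + 1j * rng.standard_normal()
        assert coherence_factor(np.full(8, c)) == pytest.approx(1.0)


class TestGeneralizedCf:
    def test_constant_vector_is_all_low_frequency(self):
        assert generalized_cf(np.ones(8), M0=0) == pytest.approx(1.0)

    def test_full_band_always_unity(self, rng):
        x = rng.standard_normal(8) + 1j * rng.standard_normal(8)
        assert generalized_cf(x, M0=4) == pytest.approx(1.0)

    def test_nyquist_energy_excluded(self):
        x = np.array([1.0, -1.0] * 4)
        assert generalized_cf(x, M0=1) == pytest.approx(0.0, abs=1e-14)

    def test_monotone_in_cutoff(self, rng):
        x = rng.standard_normal(16) + 1j * rng.standard_normal(16)
        vals = [generalized_cf(x, M0) for M0 in range(0, 9)]
        assert np.all(np.diff(vals) >= -1e-12)
        assert vals[-1] == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=200)
    @given(complex_vectors)
    def test_bounded_unit_interval(self, x):
        assert 0.0 <= generalized_cf(x, M0=1) <= 1.0 + 1e-12


class TestApertureAsd:
    def test_constant_vector_zero(self):
        assert aperture_asd(np.full(6, 3.7)) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_case(self):
        assert aperture_asd(np.array([1.0, -1.0])) == pytest.approx(1.0)

    def test_matches_moment_oracle(self, rng):
        x = rng.standard_normal(16) + 1j * rng.standard_normal(16)
        oracle = np.sqrt(np.mean(np.abs(x) ** 2) - np.abs(np.mean(x)) ** 2)
        assert aperture_asd(x) == pytest.approx(oracle, rel=1e-12)


class TestNormalizeAsd:
    def test_uniform_map_all_ones(self):
        np.testing.assert_allclose(normalize_asd(np.full((3, 3), 2.0)), 1.0)

    def test_cube_root_reciprocal(self):
        np.testing.assert_allclose(normalize_asd(np.array([1.0, 8.0])), [1.0, 0.5])

    def test_max_is_one_and_order_reversed(self, rng):
        sigma = rng.uniform(0.1, 5.0, size=50)
        sp = normalize_asd(sigma)
        assert sp.max() == pytest.approx(1.0)
        assert np.array_equal(np.argsort(sp), np.argsort(-sigma))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_asd(np.zeros(4))


class TestDynamicSubarrayLength:
    @pytest.mark.parametrize(
        "sp,lmax,expected", [(1.0, 32, 32), (0.51, 32, 16), (0.05, 32, 2)]
    )
    def test_floor_and_clamp(self, sp, lmax, expected):
        assert dynamic_subarray_length(sp, lmax) == expected


class TestSmoothCovariance:
    def test_uniform_vector(self):
        np.testing.assert_allclose(smooth_covariance(np.ones(4), 2), np.ones((2, 2)))

    def test_shape_and_hermitian(self, rng):
        x = rng.standard_normal(8) + 1j * rng.standard_normal(8)
        R = smooth_covariance(x, 3)
        assert R.shape == (3, 3)
        np.testing.assert_allclose(R, R.conj().T, atol=1e-14)

    def test_matches_loop_oracle(self, rng):
        x = rng.standard_normal(10) + 1j * rng.standard_normal(10)
        np.testing.assert_allclose(
            smooth_covariance(x, 4), smooth_covariance_loops(x, 4), rtol=1e-12
        )

    def test_oversized_subarray_rejected(self):
        with pytest.raises(ValueError):
            smooth_covariance(np.ones(4), 5)


class TestRotaryAverage:
    def test_identity_two_by_two(self):
        np.testing.assert_allclose(rotary_average(np.eye(2)), np.full((2, 2), 0.5))

    def test_all_ones_fixed_point(self):
        np.testing.assert_allclose(rotary_average(np.ones((3, 3))), np.ones((3, 3)))

    def test_matches_term_by_term_oracle(self, rng):
        R = rng.standard_normal((3, 3)) + 1j * rng.standard_normal((3, 3))
        np.testing.assert_allclose(rotary_average(R), rotary_average_terms(R), atol=1e-14)

    def test_idempotent_on_symmetric_persymmetric(self, rng):
        R = rng.standard_normal((4, 4))
        Rh = rotary_average(R + R.T)
        J = np.eye(4)[::-1]
        assert np.allclose(Rh, Rh.T) and np.allclose(Rh, J @ Rh.T @ J)
        np.testing.assert_allclose(rotary_average(Rh), Rh, atol=1e-13)

    def test_classic_fb_mode(self, rng):
        R = rng.standard_normal((3, 3)) + 1j * rng.standard_normal((3, 3))
        J = np.eye(3)[::-1]
        np.testing.assert_allclose(
            rotary_average(R, mode="classic_fb"), (R + J @ R.T @ J) / 2, atol=1e-14
        )

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            rotary_average(np.ones((2, 3)))


class TestDiagonalReduce:
    def test_zero_delta_is_identity(self, rng):
        R = rng.standard_normal((3, 3))
        np.testing.assert_array_equal(diagonal_reduce(R, 0.0), R)

    def test_unit_delta_zeroes_diagonal(self, rng):
        R = rng.standard_normal((4, 4))
        out = diagonal_reduce(R, 1.0)
        np.testing.assert_array_equal(np.diag(out), 0.0)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_array_equal(out[off], R[off])

    def test_half_delta_on_diagonal_matrix(self):
        np.testing.assert_allclose(
            diagonal_reduce(np.diag([2.0, 4.0]), 0.5), np.diag([1.0, 2.0])
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diagonal_reduce(np.eye(2), 1.5)


class TestMatrixMsr:
    def test_antidiagonal_case(self):
        assert matrix_msr(np.array([[0.0, 1.0], [1.0, 0.0]])) == pytest.approx(1.0)

    def test_arithmetic_case(self):
        assert matrix_msr(np.array([[1.0, 2.0], [3.0, 4.0]])) == pytest.approx(
            2.5 / np.sqrt(1.25), rel=1e-12
        )

    def test_constant_matrix_capped(self):
        assert matrix_msr(np.full((3, 3), 2.0), cap=1e6) == 1e6

    def test_zero_matrix_returns_zero(self):
        assert matrix_msr(np.zeros((3, 3))) == 0.0

    def test_matches_loop_oracle(self, rng):
        M = rng.standard_normal((5, 5)) + 1j * rng.standard_normal((5, 5))
        mean, std = msr_loops(M)
        assert matrix_msr(M) == pytest.approx(mean / std, rel=1e-12)


class TestAdaptiveDelta:
    @pytest.mark.parametrize(
        "wcf,sp,dmax,expected",
        [(1.0, 0.7, 0.8, 0.8), (0.25, 0.5, 1.0, 0.5), (0.0, 0.5, 1.0, 0.0)],
    )
    def test_power_law(self, wcf, sp, dmax, expected):
        assert adaptive_delta(wcf, sp, dmax) == pytest.approx(expected)

    def test_bounded_by_delta_max(self, rng):
        for _ in range(100):
            d = adaptive_delta(rng.uniform(), rng.uniform(1e-3, 1), 0.7)
            assert 0.0 <= d <= 0.7


class TestCmsfChain:
    def cfg(self, n=16, **kw):
        return BeamformerConfig(**kw).resolved(n)

    def test_coherent_closed_form(self):
        # ones(N), delta=1: the reduced matrix has two values (0 on the
        # diagonal, 1 off it) whose MSR is sqrt(L' - 1)
        n = 16
        cfg = self.cfg(n, delta=1.0, L_max=8)
        sigma_prime = 0.9  # L' = floor(0.9 * 8) = 7
        expected = np.sqrt(7 - 1)
        assert cmsf_weight(np.ones(n), sigma_prime, cfg) == pytest.approx(expected)

    def test_off_axis_below_coherent_at_equal_length(self):
        n = 16
        cfg = self.cfg(n)
        alt = ((-1.0) ** np.arange(n)).astype(complex)
        w_coh = cmsf_weight(np.ones(n), 0.8, cfg)
        w_alt = cmsf_weight(alt, 0.8, cfg)
        assert w_alt < w_coh

    def test_noise_below_coherent(self, rng):
        n = 16
        cfg = self.cfg(n)
        noise = 0.1 * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
        assert cmsf_weight(noise, 0.8, cfg) < cmsf_weight(np.ones(n), 0.8, cfg)

    def test_composition_equals_step_chaining(self, rng):
        n = 12
        cfg = self.cfg(n, delta=0.6, L_max=6)
        x = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        sp = 0.77
        lp = int(dynamic_subarray_length(sp, cfg.L_max))
        manual = matrix_msr(
            diagonal_reduce(rotary_average(smooth_covariance(x, lp)), cfg.delta),
            cfg.msr_cap,
        )
        assert cmsf_weight(x, sp, cfg) == pytest.approx(manual, rel=1e-14)


class TestCmsawChain:
    def cfg(self, n=16, **kw):
        return BeamformerConfig(**kw).resolved(n)

    def test_fully_coherent_equals_cmsf_at_delta_max(self, rng):
        n = 16
        cfg = self.cfg(n, delta=0.8, delta_max=0.8)
        x = np.full(n, 2.0 + 0j)  # CF = 1 exactly
        assert cmsaw_weight(x, 0.9, cfg) == pytest.approx(
            cmsf_weight(x, 0.9, cfg), rel=1e-12
        )

    def test_delta_max_zero_is_plain_msr_of_rotary_average(self, rng):
        n = 16
        cfg = self.cfg(n, delta_max=0.0)
        x = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        sp = 0.66
        lp = int(dynamic_subarray_length(sp, cfg.L_max))
        expected = matrix_msr(rotary_average(smooth_covariance(x, lp)), cfg.msr_cap)
        assert cmsaw_weight(x, sp, cfg) == pytest.approx(expected, rel=1e-14)

    def test_composition_equals_step_chaining(self, rng):
        n = 16
        cfg = self.cfg(n, delta_max=0.9)
        x = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        sp = 0.5
        lp = int(dynamic_subarray_length(sp, cfg.L_max))
        d_ac = adaptive_delta(coherence_factor(x), sp, cfg.delta_max)
        manual = matrix_msr(
            diagonal_reduce(rotary_average(smooth_covariance(x, lp)), d_ac),
            cfg.msr_cap,
        )
        assert cmsaw_weight(x, sp, cfg) == pytest.approx(manual, rel=1e-14)


class TestApplyPixelWeight:
    def test_unit_weight_is_identity(self, rng):
        img = rng.standard_normal((3, 4)) + 1j * rng.standard_normal((3, 4))
        np.testing.assert_array_equal(apply_pixel_weight(np.ones((3, 4)), img), img)

    def test_zero_weight_zeroes_image(self, rng):
        img = rng.standard_normal((3, 4))
        np.testing.assert_array_equal(apply_pixel_weight(np.zeros((3, 4)), img), 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_pixel_weight(np.ones((2, 2)), np.ones((3, 3)))

    def test_gcf_weighting_reproduces_gcf_mv_image(self, toy_run):
        imgs = toy_run["images"]["point"]
        wm = toy_run["weight_maps"]["point"]
        np.testing.assert_array_equal(
            apply_pixel_weight(wm["w_gcf"], imgs["mv"].values),
            imgs["gcf_mv"].values,
        )
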