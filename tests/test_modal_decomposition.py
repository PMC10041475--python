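import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from numpy.polynomial.legendre import leggauss
from scipy.special import eval_legendre

from miop import (
    ModalCoefficients,
    ModalProfileMatrix,
    SimConfig,
    decompose_profile,
    decompose_sequence,
    legendre_P,
    reconstruct,
    select_order_aic,
    simulate_modal_profiles,
    synthesize_sequence,
)
from miop.contour_core import AngularProfile
from miop.errors import DomainError, InsufficientData


def profile_from(u, s=None, theta_R=0.6):
    if s is None:
        s = np.linspace(-1, 1, 241)
    return AngularProfile(s=s, theta=s * theta_R, theta_R=theta_R,
                          u=np.asarray(u, float), frame_index=1)


class TestLegendreBasis:
    def test_closed_forms(self):
        assert legendre_P(0, 0.37) == 1.0
        assert legendre_P(1, -0.25) == -0.25
        assert legendre_P(2, 0.5) == pytest.approx(-0.125, abs=1e-15)
        assert legendre_P(4, 1.0) == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize("n", range(9))
    def test_matches_scipy_reference(self, n):
        x = np.linspace(-1, 1, 257)
        np.testing.assert_allclose(legendre_P(n, x), eval_legendre(n, x),
                                   atol=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            legendre_P(-1, 0.0)
        with pytest.raises(DomainError):
            legendre_P(2, 1.5)


class TestProjection:
    @pytest.mark.parametrize("n", range(6))
    def test_basis_function_projects_to_unit_vector(self, n):
        s = np.linspace(-1, 1, 241)
        coeffs = decompose_profile(profile_from(legendre_P(n, s), s))
        expected = np.zeros(6)
        expected[n] = 1.0
        np.testing.assert_allclose(coeffs.a, expected, atol=1e-4)

    def test_constant_profile_loads_mode_zero(self):
        coeffs = decompose_profile(profile_from(np.full(241, 0.2)))
        assert coeffs.a[0] == pytest.approx(0.2, abs=1e-9)
        np.testing.assert_allclose(coeffs.a[1:], 0.0, atol=1e-9)

    def test_quadratic_splits_between_modes_0_and_2(self):
        s = np.linspace(-1, 1, 241)
        coeffs = decompose_profile(profile_from(s**2, s))
        assert coeffs.a[0] == pytest.approx(1 / 3, abs=1e-6)
        assert coeffs.a[2] == pytest.approx(2 / 3, abs=1e-6)
        np.testing.assert_allclose(coeffs.a[[1, 3, 4, 5]], 0.0, atol=1e-6)

    def test_fine_grid_projection_matches_gauss_quadrature(self):
        rng = np.random.default_rng(17)
        c = rng.normal(0, 0.05, 9)  # band-limited: degree <= 8
        s = np.linspace(-1, 1, 100_001)
        u = sum(ci * legendre_P(i, s) for i, ci in enumerate(c))
        ours = decompose_profile(profile_from(u, s)).a
        xg, wg = leggauss(64)
        ug = sum(ci * legendre_P(i, xg) for i, ci in enumerate(c))
        oracle = np.array([
            (2 * n + 1) / 2 * np.sum(wg * ug * legendre_P(n, xg))
            for n in range(6)
        ])
        np.testing.assert_allclose(ours, oracle, atol=1e-6)

    def test_uncorrected_projection_converges_at_second_order(self):
        s_c = np.linspace(-1, 1, 121)
        s_f = np.linspace(-1, 1, 481)
        err = []
        for s in (s_c, s_f):
            a = decompose_profile(profile_from(legendre_P(3, s), s),
                                  grid_corrected=False).a
            err.append(abs(a[3] - 1.0))
        assert err[1] < err[0] / 8  # h halves twice: expect ~16x

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientData):
            decompose_profile(profile_from(np.zeros(8), np.linspace(-1, 1, 8)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(-3, 3), st.floats(-3, 3))
    def test_projection_is_linear(self, seed, alpha, beta):
        rng = np.random.default_rng(seed)
        s = np.linspace(-1, 1, 241)
        u = rng.normal(0, 0.1, s.size)
        v = rng.normal(0, 0.1, s.size)
        a_u = decompose_profile(profile_from(u, s)).a
        a_v = decompose_profile(profile_from(v, s)).a
        a_mix = decompose_profile(profile_from(alpha * u + beta * v, s)).a
        np.testing.assert_allclose(a_mix, alpha * a_u + beta * a_v,
                                   atol=1e-9, rtol=1e-9)

    def test_parity_even_input_kills_odd_modes(self):
        s = np.linspace(-1, 1, 241)
        even = decompose_profile(profile_from(np.cos(2 * s), s)).a
        np.testing.assert_allclose(even[[1, 3, 5]], 0.0, atol=1e-12)
        odd = decompose_profile(profile_from(np.sin(2 * s), s)).a
        np.testing.assert_allclose(odd[[0, 2, 4]], 0.0, atol=1e-12)

    def test_literal_integrand_convention_evaluates(self):
        # The as-printed form integrates u(theta) P_n(cos theta) sin theta
        # over a symmetric range; its odd weight suppresses symmetric input.
        s = np.linspace(-1, 1, 2001)
        a = decompose_profile(profile_from(np.full_like(s, 1.0), s),
                              convention="literal_eq2").a
        np.testing.assert_allclose(a, 0.0, atol=1e-6)


class TestReconstruction:
    def test_round_trip_on_arbitrary_degree5_vector(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 0.3, 6)
        s = np.linspace(-1, 1, 241)
        u = reconstruct(ModalCoefficients(a=a, frame_index=1), s)
        back = decompose_profile(profile_from(u, s)).a
        np.testing.assert_allclose(back, a, atol=1e-9)

    def test_zero_coefficients_give_zero_curve(self):
        u = reconstruct(ModalCoefficients(a=np.zeros(6), frame_index=1),
                        np.linspace(-1, 1, 11))
        np.testing.assert_allclose(u, 0.0)

    def test_single_mode_four_at_endpoint(self):
        a = np.array([0.0, 0, 0, 0, 1.0, 0])
        u = reconstruct(ModalCoefficients(a=a, frame_index=1),
                        np.array([1.0]))
        assert u[0] == pytest.approx(1.0, abs=1e-12)


class TestSequenceDecomposition:
    def test_zero_noise_recovery(self, sim16):
        mp = decompose_sequence(sim16.sequence)
        np.testing.assert_allclose(mp.a, sim16.modal_truth.a, atol=1e-6)

    def test_symmetric_sequence_has_no_odd_modes(self, sim16):
        mp = decompose_sequence(sim16.sequence)
        np.testing.assert_allclose(mp.a[[1, 3, 5]], 0.0, atol=1e-9)

    def test_pure_translation_loads_mode_zero_only(self):
        cfg = SimConfig(wem_amp=0.25, c2=0.0, c4=0.0)
        truth = simulate_modal_profiles(cfg)
        seq = synthesize_sequence(truth, cfg)
        mp = decompose_sequence(seq)
        np.testing.assert_allclose(mp.a[1:], 0.0, atol=1e-9)
        assert mp.a[0].max() == pytest.approx(0.25, abs=1e-6)

    def test_modal_profile_csv_round_trip(self, sim16, tmp_path):
        mp = decompose_sequence(sim16.sequence)
        path = tmp_path / "profile.csv"
        mp.write_csv(path)
        back = ModalProfileMatrix.read_csv(path)
        assert back.basis_convention == mp.basis_convention
        np.testing.assert_allclose(back.a, mp.a, atol=1e-7)


class TestOrderSelection:
    @staticmethod
    def _sequence_with(a_rows, noise_sd, seed=0):
        cfg = SimConfig(noise_sd=noise_sd, seed=seed)
        t = np.arange(1, 141, dtype=float)
        a = np.zeros((6, 140))
        for n, amp in a_rows.items():
            # trapezoid pulse, exactly zero at frame 1 so the reference
            # frame is a perfect circle
            a[n] = amp * np.interp(t, [1, 25, 60, 85, 115, 140],
                                   [0, 0, 1, 1, 0, 0])
        truth = ModalProfileMatrix(a=a, dt_ms=cfg.dt_ms)
        return synthesize_sequence(truth, cfg)

    def test_degree4_signal_with_noise_selects_four(self):
        seq = self._sequence_with({2: 0.4, 4: 0.2}, noise_sd=1e-4, seed=2)
        assert select_order_aic(seq) == 4

    def test_pure_noise_selects_zero(self):
        seq = self._sequence_with({}, noise_sd=1e-3, seed=3)
        assert select_order_aic(seq) == 0

    def test_noise_free_degree2_selects_two(self):
        seq = self._sequence_with({2: 0.4}, noise_sd=0.0)
        assert select_order_aic(seq) == 2
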