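"""Analytic properties of the Butterworth bandpass and DHBB filter bank."""

import numpy as np
import pytest

from fdbseg import (
    ButterworthSpec,
    FDBParams,
    FrequencyGrid,
    ParameterError,
    butterworth_1d,
    butterworth_2d_spectrum,
    butterworth_bilinear_1d,
    butterworth_roots,
    dhbb_filterbank,
    directional_hilbert_spectrum,
)


class TestButterworth1D:
    def test_unit_peak_at_geometric_mean(self):
        spec = ButterworthSpec(gamma=2, omega_L=0.3, omega_H=1.0)
        assert butterworth_1d(np.array([spec.p]), spec)[0] == pytest.approx(1.0, abs=1e-12)

    def test_vanishes_at_dc(self):
        spec = ButterworthSpec(gamma=2)
        assert butterworth_1d(np.array([0.0]), spec)[0] == 0.0

    def test_matches_printed_formula_at_high_precision(self):
        # independent 50-digit evaluation of the closed-form transfer function
        import sympy as sp

        w, g = sp.Rational(1, 2), 2
        wl, wh = sp.Rational(3, 10), sp.Integer(1)
        delta, p2 = wh - wl, wh * wl
        expr = (w * delta) ** (2 * g) / ((w * delta) ** (2 * g) + (w**2 - p2) ** (2 * g))
        expected = float(sp.N(expr, 50))
        spec = ButterworthSpec(gamma=2, omega_L=0.3, omega_H=1.0)
        assert butterworth_1d(np.array([0.5]), spec)[0] == pytest.approx(expected, rel=1e-12)

    def test_bounded_single_interior_maximum(self):
        spec = ButterworthSpec(gamma=3)
        omega = np.linspace(0.0, np.pi, 4001)
        b = butterworth_1d(omega, spec)
        assert np.all((b >= 0.0) & (b <= 1.0))
        signs = np.sign(np.diff(b))
        changes = np.count_nonzero(np.diff(signs[signs != 0]) != 0)
        assert changes == 1  # rises then falls: one interior maximum

    def test_large_gamma_approaches_ideal_filter(self):
        spec = ButterworthSpec(gamma=50)
        omega = np.linspace(1e-3, np.pi, 3000)
        away = (np.abs(omega - spec.omega_L) > 0.05) & (np.abs(omega - spec.omega_H) > 0.05)
        ideal = ((omega >= spec.omega_L) & (omega <= spec.omega_H)).astype(float)
        b = butterworth_1d(omega, spec)
        assert np.max(np.abs(b - ideal)[away]) < 0.01

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ParameterError):
            ButterworthSpec(gamma=2, omega_L=1.0, omega_H=0.3)
        with pytest.raises(ParameterError):
            ButterworthSpec(gamma=0)


class TestButterworthRoots:
    def test_gamma_one_and_two_closed_forms(self):
        np.testing.assert_allclose(butterworth_roots(1), [np.exp(1j * np.pi)], atol=1e-15)
        np.testing.assert_allclose(
            butterworth_roots(2), [np.exp(3j * np.pi / 4), np.exp(5j * np.pi / 4)], atol=1e-15
        )

    @pytest.mark.parametrize("gamma", [1, 2, 3, 5, 8])
    def test_negative_squares_are_roots_of_minus_one(self, gamma, rng):
        # -t_k^2 enumerate the gamma roots of z^gamma = -1, hence
        # prod_k (z + t_k^2) = z^gamma + 1 and, substituting z = -t^2,
        # prod_k (t^2 - t_k^2) = t^{2 gamma} + (-1)^gamma
        tk = butterworth_roots(gamma)
        assert np.allclose(np.abs(tk), 1.0)
        np.testing.assert_allclose(
            np.sort((-(tk**2)) ** gamma), np.full(gamma, -1.0 + 0.0j), atol=1e-12
        )
        t = rng.standard_normal(32) + 1j * rng.standard_normal(32)
        lhs = np.prod([t**2 - r**2 for r in tk], axis=0)
        rhs = t ** (2 * gamma) + (-1.0) ** gamma
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9)


class TestButterworthBilinear:
    def test_zero_at_dc(self):
        spec = ButterworthSpec(gamma=2)
        assert butterworth_bilinear_1d(np.array([0.0]), spec)[0] == 0.0

    def test_single_interior_magnitude_maximum(self):
        spec = ButterworthSpec(gamma=2, omega_L=0.3, omega_H=1.0)
        omega = np.linspace(0.0, np.pi, 4001)
        mag = np.abs(butterworth_bilinear_1d(omega, spec))
        signs = np.sign(np.diff(mag))
        changes = np.count_nonzero(np.diff(signs[signs != 0]) != 0)
        assert changes == 1
        peak = omega[np.argmax(mag)]
        assert 0.3 < peak < 1.0  # peak inside the passband, near p

    @pytest.mark.parametrize("gamma", [1, 2, 3, 4])
    def test_agrees_with_analog_factorization_through_bilinear_map(self, gamma, rng):
        # H(t) = prod_k 1/(t - t_k) evaluated at t = (w^2 + p^2)/(w*Delta)
        # with w the bilinear image of j*omega must reproduce B^gamma, and
        # H(t)H(-t) its squared magnitude
        spec = ButterworthSpec(gamma=gamma, omega_L=0.3, omega_H=1.0)
        omega = rng.uniform(0.05, np.pi - 0.05, 64)
        z = np.exp(1j * omega)
        w = 2.0 * (z - 1.0) / (z + 1.0)
        t = (w**2 + spec.p**2) / (w * spec.delta)
        tk = butterworth_roots(gamma)
        H = lambda tt: np.prod([1.0 / (tt - r) for r in tk], axis=0)
        B = butterworth_bilinear_1d(omega, spec)
        np.testing.assert_allclose(B, H(t), rtol=1e-9)
        np.testing.assert_allclose(np.abs(B) ** 2, (H(t) * H(-t)).real, rtol=1e-9)

    def test_narrower_passband_than_original(self):
        # |B|^2 is the power response comparable to b_hat; the bilinear
        # frequency warp compresses the passband
        spec_b = ButterworthSpec(gamma=2)
        spec_o = ButterworthSpec(gamma=2, variant="original")
        omega = np.linspace(1e-3, np.pi, 2000)
        width = lambda resp: np.count_nonzero(resp >= 0.5)
        assert width(np.abs(butterworth_bilinear_1d(omega, spec_b)) ** 2) < width(
            butterworth_1d(omega, spec_o)
        )


class TestButterworth2D:
    def test_cartesian_split_partitions_plane(self):
        grid = FrequencyGrid.for_shape((64, 64))
        chi_h = grid.b * np.abs(grid.omega1) >= grid.a * np.abs(grid.omega2)
        chi_v = ~chi_h
        assert np.all(chi_h.astype(int) + chi_v.astype(int) == 1)

    def test_axis_frequencies_take_pure_1d_response(self):
        grid = FrequencyGrid.for_shape((32, 32))
        spec = ButterworthSpec(gamma=2)
        g2 = butterworth_2d_spectrum(grid, spec)
        row = np.flatnonzero(grid.omega2[:, 0] == 0.0)[0]
        expected = butterworth_bilinear_1d(grid.omega1[row], spec)
        np.testing.assert_allclose(g2[row], expected, atol=1e-14)

    def test_horizontal_branch_dominates_below_diagonal(self):
        grid = FrequencyGrid.for_shape((48, 48))
        spec = ButterworthSpec(gamma=2, variant="original")
        g2 = butterworth_2d_spectrum(grid, spec)
        sel = grid.b * np.abs(grid.omega1) > grid.a * np.abs(grid.omega2)
        np.testing.assert_array_equal(g2[sel], butterworth_1d(np.abs(grid.omega1), spec)[sel])


class TestDirectionalHilbert:
    def test_unit_response_along_own_orientation(self):
        # a frequency parallel to u gives exactly (-j)^n
        L, n = 16, 20
        grid = FrequencyGrid.for_shape((64, 64))
        h0 = directional_hilbert_spectrum(grid, 0, L, n)
        row = np.flatnonzero(grid.omega2[:, 0] == 0.0)[0]
        col = np.flatnonzero(grid.omega1[row] > 0)[0]
        assert h0[row, col] == pytest.approx(1.0)  # (-j)^20 = 1

    def test_zero_perpendicular_to_orientation(self):
        grid = FrequencyGrid.for_shape((64, 64))
        h0 = directional_hilbert_spectrum(grid, 0, 16, 20)
        on_axis = (grid.omega1 == 0.0) & (grid.omega2 != 0.0)
        np.testing.assert_allclose(np.abs(h0[on_axis]), 0.0, atol=1e-200)

    def test_magnitude_bounded_by_one_and_zero_at_dc(self):
        grid = FrequencyGrid.for_shape((96, 96))
        for l in range(8):
            h = directional_hilbert_spectrum(grid, l, 8, 7)
            assert np.max(np.abs(h)) <= 1.0 + 1e-12
            assert h[0, 0] == 0.0

    def test_even_order_spectrum_is_real(self):
        grid = FrequencyGrid.for_shape((32, 32))
        h = directional_hilbert_spectrum(grid, 3, 16, 20)
        assert not np.iscomplexobj(h)

    def test_grid_max_reaches_one_for_order_twenty(self):
        grid = FrequencyGrid.for_shape((64, 64))
        h = directional_hilbert_spectrum(grid, 0, 16, 20)
        assert np.max(h) == pytest.approx(1.0)

    def test_quarter_turn_orientations_annihilate_on_axes(self):
        grid = FrequencyGrid.for_shape((64, 64))
        L = 16
        prod = directional_hilbert_spectrum(grid, 0, L, 20) * directional_hilbert_spectrum(
            grid, L // 2, L, 20
        )
        axes = (grid.omega1 == 0.0) | (grid.omega2 == 0.0)
        np.testing.assert_allclose(prod[axes], 0.0, atol=1e-250)

    def test_orientation_relabeling_matches_rotated_grid(self):
        # the subband at theta = pi/2 equals the base subband on the grid
        # rotated by -pi/2 (exact for axis-aligned rotations)
        grid = FrequencyGrid.for_shape((64, 64))
        L, n = 16, 20
        rotated = FrequencyGrid(omega1=grid.omega2, omega2=-grid.omega1, a=grid.a, b=grid.b)
        np.testing.assert_allclose(
            directional_hilbert_spectrum(grid, L // 2, L, n),
            directional_hilbert_spectrum(rotated, 0, L, n),
            atol=1e-12,
        )

    def test_out_of_range_orientation_rejected(self):
        grid = FrequencyGrid.for_shape((16, 16))
        with pytest.raises(ParameterError):
            directional_hilbert_spectrum(grid, 16, 16, 20)


class TestDHBBFilterBank:
    def test_spectra_count_finite_and_vanish_at_dc(self, default_params):
        bank = dhbb_filterbank((64, 64), default_params)
        assert len(bank.spectra) == default_params.L
        for s in bank.spectra:
            assert np.all(np.isfinite(s))
            assert s[0, 0] == 0.0

    def test_even_order_original_variant_bounded_by_bandpass(self):
        params = FDBParams(variant="original")
        bank = dhbb_filterbank((64, 64), params)
        grid = bank.grid
        g2 = butterworth_2d_spectrum(grid, bank.butterworth)
        for s in bank.spectra:
            assert not np.iscomplexobj(s)
            assert np.all(np.abs(s) <= g2 + 1e-12)

    def test_ring_coverage_at_worst_orientation(self):
        # the worst frequency direction sits midway between two subband
        # orientations, where the best subband still passes cos^n(pi/(2L))
        params = FDBParams(variant="original")
        bank = dhbb_filterbank((128, 128), params)
        grid = bank.grid
        g2 = butterworth_2d_spectrum(grid, bank.butterworth)
        ring = np.abs(np.hypot(grid.omega1, grid.omega2) - bank.butterworth.p) < 0.05
        best = np.max(np.abs(np.stack([np.asarray(s) for s in bank.spectra])), axis=0)
        floor = np.cos(np.pi / (2 * params.L)) ** params.n
        assert np.all(best[ring] >= floor * g2[ring] - 1e-12)
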