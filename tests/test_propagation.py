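"""Angular-spectrum propagation against analytic and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sonoretina import (
    ComplexField,
    Grid2D,
    MediumProps,
    angular_spectrum,
    backpropagate,
    band_limit_cutoff,
    focused_piston_source,
    make_source_grid,
    propagate,
    rs_oracle,
)
from sonoretina.propagation import on_axis_piston

from conftest import band_limited_field, small_random_field


class TestAngularSpectrum:
    def test_uniform_field_is_dc_only(self):
        g = Grid2D(32, 32, 0.1, 0.1)
        f = ComplexField(g, np.ones((32, 32), complex), 0.0, 4.5)
        spec = np.abs(angular_spectrum(f))
        dc = spec[16, 16]
        spec[16, 16] = 0.0
        assert dc > 0
        assert spec.max() < 1e-10 * dc

    def test_center_impulse_has_flat_magnitude(self):
        g = Grid2D(32, 32, 0.1, 0.1)
        vals = np.zeros((32, 32), complex)
        vals[16, 16] = 1.0
        spec = np.abs(angular_spectrum(ComplexField(g, vals, 0.0, 4.5)))
        assert np.allclose(spec, spec[0, 0])

    def test_parseval(self):
        f = small_random_field(0, n=48)
        g = f.grid
        spec = angular_spectrum(f)
        dk = (2 * np.pi) ** 2 / (g.nx * g.dx * g.ny * g.dy)
        lhs = np.sum(np.abs(f.values) ** 2) * g.dx * g.dy
        rhs = np.sum(np.abs(spec) ** 2) * dk / (2 * np.pi) ** 2
        assert np.isclose(lhs, rhs, rtol=1e-12)

    def test_nonfinite_input_rejected(self):
        g = Grid2D(8, 8, 0.1, 0.1)
        vals = np.ones((8, 8), complex)
        vals[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            ComplexField(g, vals, 0.0, 4.5)


class TestPropagate:
    def test_zero_distance_is_identity(self):
        f = small_random_field(1)
        out = propagate(f, 0.0)
        assert out is f

    def test_plane_wave_phase_advance(self, water):
        g = Grid2D(32, 32, 0.1, 0.1)
        f = ComplexField(g, np.ones((32, 32), complex), 0.0, 4.5)
        out = propagate(f, 1.0, water)
        km = water.wavenumber(4.5)
        assert np.allclose(out.values, np.exp(1j * km * 1.0), atol=1e-10)
        assert np.allclose(np.abs(out.values), 1.0)

    def test_undersampled_grid_rejected(self, water):
        # λ/2 at 20 MHz is 37.5 µm; 0.1 mm spacing is far too coarse
        f = small_random_field(2, dx=0.1, f=20.0)
        with pytest.raises(ValueError, match="undersampled"):
            propagate(f, 1.0, water)

    def test_negative_dz_directed_to_backpropagate(self):
        f = small_random_field(3)
        with pytest.raises(ValueError, match="backpropagate"):
            propagate(f, -1.0)

    def test_energy_conserved_for_propagating_components(self, water):
        f = band_limited_field(4)
        out = propagate(f, 7.0, water)
        assert np.isclose(out.energy(), f.energy(), rtol=1e-10)

    def test_linearity(self, water):
        f1 = band_limited_field(5)
        f2 = band_limited_field(6)
        a, b = 2.0 - 1.0j, 0.3 + 0.7j
        combo = ComplexField(f1.grid, a * f1.values + b * f2.values, 0.0, f1.f)
        lhs = propagate(combo, 3.0, water).values
        rhs = a * propagate(f1, 3.0, water).values + b * propagate(f2, 3.0, water).values
        assert np.allclose(lhs, rhs, atol=1e-12 * np.abs(lhs).max())

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(dz=st.floats(0.1, 20.0), seed=st.integers(0, 50))
    def test_roundtrip_identity_property(self, dz, seed):
        """propagate∘backpropagate is the identity on band-limited fields."""
        f = band_limited_field(seed)
        rt = backpropagate(propagate(f, dz), dz)
        err = np.max(np.abs(rt.values - f.values))
        assert err < 1e-8 * np.abs(f.values).max()

    def test_backpropagate_plane_wave_phase_retard(self, water):
        g = Grid2D(32, 32, 0.1, 0.1)
        f = ComplexField(g, np.ones((32, 32), complex), 10.0, 4.5)
        out = backpropagate(f, 2.0, water)
        km = water.wavenumber(4.5)
        assert np.allclose(out.values, np.exp(-1j * km * 2.0), atol=1e-10)
        assert out.z == 8.0


class TestBandLimitCutoff:
    def test_small_z_limit_tends_to_km(self):
        lam = 0.3
        cutoff = band_limit_cutoff(12.0, 6.0, lam, 1e-9)
        assert np.isclose(cutoff, 2 * np.pi / lam, rtol=1e-12)

    def test_hand_evaluation(self):
        # π(12+6) / (0.333·sqrt(10² + 18²/4)) evaluated by hand
        expected = np.pi * 18.0 / (0.333 * np.sqrt(100.0 + 81.0))
        assert np.isclose(band_limit_cutoff(12.0, 6.0, 0.333, 10.0), expected)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(z1=st.floats(0.1, 50.0), dz=st.floats(0.01, 50.0))
    def test_strictly_decreasing_in_z(self, z1, dz):
        assert band_limit_cutoff(12, 6, 0.3, z1) > band_limit_cutoff(12, 6, 0.3, z1 + dz)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            band_limit_cutoff(-1, 6, 0.3, 10)
        with pytest.raises(ValueError):
            band_limit_cutoff(12, 6, 0.3, 0.0)


class TestRayleighSommerfeld:
    def test_point_source_spherical_spreading(self, water):
        g = Grid2D(16, 16, 0.1, 0.1)
        vals = np.zeros((16, 16), complex)
        vals[8, 8] = 1.0
        src = ComplexField(g, vals, 0.0, 4.5)
        r1, r2 = 8.0, 16.0
        p = rs_oracle(src, [(0, 0, r1), (0, 0, r2)], water)
        # on-axis: |p| ∝ 1/r (obliquity z/r = 1)
        assert np.isclose(np.abs(p[0]) / np.abs(p[1]), r2 / r1, rtol=0.02)
        km = water.wavenumber(4.5)
        dphi = np.angle(p[1] / p[0]) - km * (r2 - r1)
        assert abs(np.angle(np.exp(1j * dphi))) < 0.02

    def test_uniform_piston_matches_closed_form_on_axis(self, water):
        a = 2.0  # piston radius, mm
        lam = water.wavelength(4.5)
        g = Grid2D(96, 96, lam / 4, lam / 4)
        X, Y = g.meshgrid()
        r = np.hypot(X, Y)
        # antialiased rim: fractional pixel coverage of the disk boundary
        vals = np.clip((a - r) / g.dx + 0.5, 0.0, 1.0).astype(complex)
        src = ComplexField(g, vals, 0.0, 4.5)
        zs = np.array([6.0, 9.0, 14.0])
        p = rs_oracle(src, [(0, 0, z) for z in zs], water)
        ref = on_axis_piston(a, zs, 4.5, water)
        assert np.all(np.abs(np.abs(p) - np.abs(ref)) <= 0.01 * np.abs(ref).max())

    def test_singular_target_rejected(self, water):
        g = Grid2D(8, 8, 0.1, 0.1)
        src = ComplexField(g, np.ones((8, 8), complex), 0.0, 4.5)
        with pytest.raises(ValueError, match="singular"):
            rs_oracle(src, [(0.0, 0.0, 0.0)], water)

    @pytest.mark.parametrize("f_mhz,D", [(3.0, 10.0), (5.4, 8.0)])
    def test_angular_spectrum_matches_rs_at_focus(self, f_mhz, D, water):
        """Cross-method check: spectral propagator vs direct RS quadrature at
        focal-plane points of a focused piston, ≤ 2% relative error."""
        F = 10.0
        grid = make_source_grid(D, f_mhz, water, oversample=4.0, pad_factor=2.0)
        src = focused_piston_source(D, F, f_mhz, grid, water)
        fld = propagate(src, F, water)
        ix = grid.nx // 2 + np.array([0, 1, 2, 4, 8])
        pts = [(grid.x[i], 0.0, F) for i in ix]
        ref = rs_oracle(src, pts, water)
        got = fld.values[grid.ny // 2, ix]
        rel = np.abs(got - ref) / np.abs(ref[0])
        assert rel.max() <= 0.02


class TestFocusedPiston:
    def test_phase_zero_at_center_and_decreasing(self, water):
        g = make_source_grid(8.0, 5.4, water)
        src = focused_piston_source(8.0, 10.0, 5.4, g, water)
        row = src.values[g.ny // 2]
        x = g.x
        center = row[g.nx // 2]
        assert np.isclose(np.angle(center), 0.0, atol=1e-9)
        # unwrapped phase strictly decreasing with radius over the disk
        disk = (x > 0) & (x <= 3.9)
        phases = np.unwrap(np.angle(row[disk]))
        assert np.all(np.diff(phases) < 0)

    def test_axial_maximum_near_geometric_focus(self, water):
        g = make_source_grid(8.0, 5.4, water)
        src = focused_piston_source(8.0, 10.0, 5.4, g, water)
        zs = np.arange(6.0, 14.01, 0.25)
        amps = [propagate(src, z, water).magnitude.max() for z in zs]
        z_peak = zs[int(np.argmax(amps))]
        assert abs(z_peak - 10.0) <= 0.05 * 10.0 + 0.25

    def test_focal_fwhm_matches_airy_scaling(self, water):
        """Half-power lateral width ≈ 1.03·λ·F/D at the focal plane."""
        from sonoretina import measure_fwhm

        g = make_source_grid(8.0, 5.4, water)
        src = focused_piston_source(8.0, 10.0, 5.4, g, water)
        fld = propagate(src, 10.0, water)
        fwhm = measure_fwhm(fld)
        lam = water.wavelength(5.4)
        assert abs(fwhm - 1.03 * lam * 10.0 / 8.0 * 1000) <= 0.10 * fwhm

    def test_grid_too_small_rejected(self, water):
        g = Grid2D(32, 32, 0.05, 0.05)  # 1.6 mm extent for a 10 mm aperture
        with pytest.raises(ValueError, match="1.5"):
            focused_piston_source(10.0, 10.0, 4.5, g, water)
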