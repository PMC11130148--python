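"""Hologram decode / steering / forward-model checks."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.interpolate import RegularGridInterpolator

from sonoretina import (
    ArraySpec,
    ComplexField,
    DriveSolution,
    EyePose,
    TargetPattern,
    decode_pattern,
    locate_peak,
    measure_fwhm,
    pattern_similarity,
    rs_oracle,
    steer_focus,
    synthesize_field,
    tilt_phase,
)


def point_target(z: float = 10.0, li: float = 2.0) -> TargetPattern:
    img = np.zeros((65, 65))
    img[32, 32] = 1.0
    return TargetPattern(img, Li=li, z=z)


def geometric_delay_law(array: ArraySpec, z: float, km: float) -> np.ndarray:
    xe, ye = array.element_xy()
    return km * (np.sqrt(xe**2 + ye**2 + z**2) - z)


def weighted_circular_std(phase_diff, weights):
    m = np.angle(np.sum(weights * np.exp(1j * phase_diff)))
    resid = np.angle(np.exp(1j * (phase_diff - m)))
    return np.sqrt(np.sum(weights * resid**2) / np.sum(weights)), resid


class TestTiltPhase:
    def test_zero_tilt_is_zero(self, array_default, water):
        assert np.allclose(tilt_phase(array_default, 0.0, 0.0, water), 0.0)

    def test_hand_evaluation(self, array_default, water):
        # km·x·tan5° for the element at x = 1.125 mm (column 9), row-center y
        ramp = tilt_phase(array_default, 5.0, 0.0, water)
        km = water.wavenumber(array_default.f0)
        xe, _ = array_default.element_xy()
        expected = np.mod(km * 1.125 * np.tan(np.radians(5.0)), 2 * np.pi)
        col = int(np.argmin(np.abs(xe[0] - 1.125)))
        assert np.isclose(ramp[7, col], expected, atol=1e-10)

    def test_tilt_ramp_shifts_focus_by_z_tan_theta(
        self, array_default, water, array_grid
    ):
        z = 10.0
        base = steer_focus(0.0, 0.0, z, array_default, water)
        for theta in (5.0, 10.0):
            ramp = tilt_phase(array_default, theta, 0.0, water)
            tilted = DriveSolution(base.amplitude, base.phase + ramp)
            fld = synthesize_field(tilted, array_default, z, water, array_grid)
            px, py = locate_peak(fld)
            assert abs(abs(px) - z * np.tan(np.radians(theta))) <= 0.2
            assert abs(py) <= 0.2


class TestSteerFocus:
    def test_on_axis_phase_map_radially_symmetric(self, array_default, water):
        d = steer_focus(0.0, 0.0, 10.0, array_default, water)
        assert np.allclose(d.phase, d.phase[::-1, :])
        assert np.allclose(d.phase, d.phase[:, ::-1])
        assert np.allclose(d.phase, d.phase.T)

    def test_steered_peak_position(self, array_default, water, array_grid):
        d = steer_focus(-3.0, 0.0, 10.0, array_default, water)
        fld = synthesize_field(d, array_default, 10.0, water, array_grid)
        px, py = locate_peak(fld)
        assert abs(px - (-3.0)) <= 0.15
        assert abs(py) <= 0.15

    def test_matches_decoded_point_target(self, array_default, water):
        """Steering law vs single-point decode: constant phase offset across
        the elements that carry hologram amplitude."""
        ds = steer_focus(0.0, 0.0, 10.0, array_default, water)
        dd = decode_pattern(point_target(), array_default, water)
        sel = dd.amplitude >= 0.1
        diff = np.angle(np.exp(1j * (dd.phase - ds.phase)))[sel]
        std, _ = weighted_circular_std(diff, dd.amplitude[sel])
        assert std < 0.05

    def test_nonpositive_depth_rejected(self, array_default):
        with pytest.raises(ValueError):
            steer_focus(0.0, 0.0, 0.0, array_default)


class TestDecodePattern:
    def test_point_decode_matches_geometric_law(self, array_default, water):
        dd = decode_pattern(point_target(), array_default, water)
        km = water.wavenumber(array_default.f0)
        law = geometric_delay_law(array_default, 10.0, km)
        sel = dd.amplitude >= 0.1
        diff = np.angle(np.exp(1j * (dd.phase - law)))[sel]
        _, resid = weighted_circular_std(diff, dd.amplitude[sel])
        assert np.abs(resid).max() < 0.1

    def test_zero_tilt_pose_equals_no_pose(self, array_default, water):
        tgt = point_target()
        a = decode_pattern(tgt, array_default, water)
        b = decode_pattern(tgt, array_default, water, pose=EyePose(10.0, 0.0, 0.0))
        assert np.array_equal(a.amplitude, b.amplitude)
        assert np.array_equal(a.phase, b.phase)

    def test_all_zero_target_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            TargetPattern(np.zeros((16, 16)), Li=2.0, z=10.0)

    def test_letter_closure_ssim(self, array_default, water, letter_c):
        """decode → synthesize reproduces the letter pattern: SSIM against
        the target blurred to the system's measured point-spread width."""
        z, li = 10.0, 4.0
        # measured PSF width of the decode→synthesize chain for a point
        dpoint = decode_pattern(point_target(z), array_default, water)
        psf_field = synthesize_field(dpoint, array_default, z, water)
        psf_fwhm_mm = measure_fwhm(psf_field) / 1000.0

        tgt = TargetPattern(letter_c, Li=li, z=z)
        drive = decode_pattern(tgt, array_default, water)
        fld = synthesize_field(drive, array_default, z, water)
        g = fld.grid

        h, w = letter_c.shape
        rows = (np.arange(h) - (h - 1) / 2) * (li / h)
        cols = (np.arange(w) - (w - 1) / 2) * (li / w)
        ri = RegularGridInterpolator(
            (rows, cols), np.sqrt(letter_c), bounds_error=False, fill_value=0.0
        )
        X, Y = g.meshgrid()
        ref = ri(np.stack([Y.ravel(), X.ravel()], -1)).reshape(g.shape)
        ref = gaussian_filter(ref, (psf_fwhm_mm / 2.355) / g.dx)

        half = li / 2 + psf_fwhm_mm
        selx = np.abs(g.x) <= half
        sely = np.abs(g.y) <= half
        a = fld.magnitude[np.ix_(sely, selx)]
        b = ref[np.ix_(sely, selx)]
        ssim = pattern_similarity(a / a.max(), b / b.max())
        assert ssim > 0.6


class TestSynthesizeField:
    def test_zero_drive_gives_zero_field(self, array_default, water, array_grid):
        shape = (array_default.n_elem_y, array_default.n_elem_x)
        d = DriveSolution(np.zeros(shape), np.zeros(shape))
        fld = synthesize_field(d, array_default, 10.0, water, array_grid)
        assert np.all(fld.magnitude == 0.0)

    def test_linearity_in_drive(self, array_default, water, array_grid):
        """Rendering + propagation is linear in the complex drive: the field
        of the complex-summed drive equals the sum of the individual fields."""
        from sonoretina.holography import render_source
        from sonoretina import propagate

        rng = np.random.default_rng(0)
        shape = (array_default.n_elem_y, array_default.n_elem_x)
        a = DriveSolution(rng.uniform(0, 1, shape), rng.uniform(0, 2 * np.pi, shape))
        b = DriveSolution(rng.uniform(0, 1, shape), rng.uniform(0, 2 * np.pi, shape))
        fa = synthesize_field(a, array_default, 10.0, water, array_grid)
        fb = synthesize_field(b, array_default, 10.0, water, array_grid)
        src_a = render_source(a, array_default, array_grid, water)
        src_b = render_source(b, array_default, array_grid, water)
        summed = ComplexField(
            array_grid, src_a.values + src_b.values, 0.0, array_default.f0
        )
        f_sum = propagate(summed, 10.0, water)
        peak = np.abs(fa.values + fb.values).max()
        assert np.allclose(f_sum.values, fa.values + fb.values, atol=1e-12 * peak)

    def test_phase_wrap_is_noop(self, array_default, water, array_grid):
        rng = np.random.default_rng(1)
        shape = (array_default.n_elem_y, array_default.n_elem_x)
        amp = rng.uniform(0, 1, shape)
        phi = rng.uniform(0, 2 * np.pi, shape)
        f1 = synthesize_field(
            DriveSolution(amp, phi), array_default, 10.0, water, array_grid
        )
        f2 = synthesize_field(
            DriveSolution(amp, phi + 2 * np.pi), array_default, 10.0, water, array_grid
        )
        assert np.allclose(f1.values, f2.values, atol=1e-12)

    def test_single_element_matches_rs_oracle(self, array_default, water):
        """One driven element is a small piston; its field must match the
        direct Rayleigh–Sommerfeld quadrature within 2%."""
        from sonoretina.holography import render_source

        shape = (array_default.n_elem_y, array_default.n_elem_x)
        amp = np.zeros(shape)
        amp[7, 7] = 1.0  # element just off-center at (-0.375, -0.375) mm
        drive = DriveSolution(amp, np.zeros(shape))
        src = render_source(drive, array_default, medium=water)
        fld = synthesize_field(drive, array_default, 5.0, water, src.grid)
        g = src.grid
        ix = g.nx // 2 + np.array([-4, 0, 4, 12])
        pts = [(g.x[i], 0.0, 5.0) for i in ix]
        ref = rs_oracle(src, pts, water)
        got = fld.values[g.ny // 2, ix]
        rel = np.abs(got - ref) / np.abs(ref).max()
        assert rel.max() <= 0.02
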