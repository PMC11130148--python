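"""Hologram computation for the 16×16 stimulation array.

Turns a target stimulation pattern (plus the measured eye pose) into
per-element drive amplitudes and phases, and synthesizes the resulting field
for verification.  The decode is a single backpropagation of the desired
target-plane field to the array plane with the band-limited angular spectrum
method, followed by averaging the hologram over each element's active area.

Phase convention
----------------
``DriveSolution.phase`` is a *delay* in radians, wrapped to [0, 2π): the
forward model renders element e as ``amplitude_e · exp(−i·phase_e)`` and
propagates with the ``exp(+i·z·kz)`` propagator.  Under this convention the
focusing law is the familiar positive delay
``phase_e = km·sqrt((xe−xf)² + (ye−yf)² + zf²)``, and the tilt-compensation
ramp ``km(x·tanθx + y·tanθy)`` is simply added to the per-element delays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.interpolate import RegularGridInterpolator

from .propagation import (
    ComplexField,
    Grid2D,
    MediumProps,
    WATER,
    backpropagate,
    make_source_grid,
    propagate,
)

TWO_PI = 2.0 * np.pi


def wrap_phase(phi: NDArray[np.float64] | float) -> NDArray[np.float64]:
    """Wrap phase(s) to [0, 2π)."""
    return np.mod(phi, TWO_PI)


@dataclass(frozen=True)
class ArraySpec:
    """Geometry of the 2D stimulation/imaging array.

    Defaults describe the 256-channel (16×16) array: 4.5 MHz center
    frequency, 0.75 mm pitch, kerf filled so that 90% of the pitch is active.
    """

    n_elem_x: int = 16
    n_elem_y: int = 16
    pitch: float = 0.75
    f0: float = 4.5
    fill_factor: float = 0.9

    def __post_init__(self) -> None:
        if self.n_elem_x < 1 or self.n_elem_y < 1:
            raise ValueError("element counts must be positive")
        if self.pitch <= 0 or self.f0 <= 0:
            raise ValueError("pitch and center frequency must be positive")
        if not (0 < self.fill_factor <= 1):
            raise ValueError("fill_factor must be in (0, 1]")

    @property
    def n_channels(self) -> int:
        return self.n_elem_x * self.n_elem_y

    @property
    def La(self) -> float:
        """Aperture side length (mm) — the larger side for non-square arrays."""
        return max(self.n_elem_x, self.n_elem_y) * self.pitch

    @property
    def element_width(self) -> float:
        return self.fill_factor * self.pitch

    def element_xy(self) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
        """Element-center coordinates as (XE, YE) arrays of shape
        (n_elem_y, n_elem_x), centered on the array axis."""
        xe = (np.arange(self.n_elem_x) - (self.n_elem_x - 1) / 2.0) * self.pitch
        ye = (np.arange(self.n_elem_y) - (self.n_elem_y - 1) / 2.0) * self.pitch
        return np.meshgrid(xe, ye)


@dataclass(frozen=True)
class TargetPattern:
    """Desired stimulation pattern on the retina plane.

    ``image`` is a non-negative intensity map (normalized to max 1 on
    construction), ``Li`` its physical side length in mm, ``z`` the target
    depth in mm.
    """

    image: NDArray[np.float64]
    Li: float
    z: float
    meta: dict | None = None

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2:
            raise ValueError("pattern image must be 2D")
        if np.any(~np.isfinite(img)) or np.any(img < 0):
            raise ValueError("pattern image must be finite and non-negative")
        if self.Li <= 0 or self.z <= 0:
            raise ValueError("Li and z must be positive")
        peak = img.max()
        if peak == 0:
            raise ValueError("pattern image is all zero")
        object.__setattr__(self, "image", img / peak)


@dataclass(frozen=True)
class EyePose:
    """Eye pose relative to the array: retina depth and tilt angles (deg)."""

    z: float
    theta_x: float = 0.0
    theta_y: float = 0.0

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("depth must be positive")
        if abs(self.theta_x) >= 45 or abs(self.theta_y) >= 45:
            raise ValueError("tilt angles must satisfy |θ| < 45°")


@dataclass(frozen=True)
class DriveSolution:
    """Per-element drive: amplitude in [0, 1], phase delay in [0, 2π)."""

    amplitude: NDArray[np.float64]
    phase: NDArray[np.float64]

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitude, dtype=float)
        phi = np.asarray(self.phase, dtype=float)
        if amp.shape != phi.shape:
            raise ValueError("amplitude and phase shapes differ")
        if np.any(~np.isfinite(amp)) or np.any(~np.isfinite(phi)):
            raise ValueError("drive contains non-finite values")
        if np.any(amp < 0) or np.any(amp > 1 + 1e-12):
            raise ValueError("amplitudes must lie in [0, 1]")
        object.__setattr__(self, "amplitude", np.clip(amp, 0.0, 1.0))
        object.__setattr__(self, "phase", wrap_phase(phi))

    @property
    def complex_drive(self) -> NDArray[np.complex128]:
        """amplitude·exp(−i·phase): the source value rendered on each element."""
        return self.amplitude * np.exp(-1j * self.phase)


def tilt_phase(
    array: ArraySpec,
    theta_x: float,
    theta_y: float,
    medium: MediumProps = WATER,
) -> NDArray[np.float64]:
    """Tilt-compensation phase ramp, per element, wrapped to [0, 2π).

    ``φ(x, y) = km·(x·tanθx + y·tanθy)`` with angles in degrees: a linear
    delay ramp that rotates the emitted pattern onto a target plane tilted by
    (θx, θy) relative to the array.
    """
    if abs(theta_x) >= 45 or abs(theta_y) >= 45:
        raise ValueError("tilt angles must satisfy |θ| < 45°")
    km = medium.wavenumber(array.f0)
    XE, YE = array.element_xy()
    ramp = km * (
        XE * np.tan(np.radians(theta_x)) + YE * np.tan(np.radians(theta_y))
    )
    return wrap_phase(ramp)


def steer_focus(
    xf: float,
    yf: float,
    z: float,
    array: ArraySpec = ArraySpec(),
    medium: MediumProps = WATER,
) -> DriveSolution:
    """Geometric focal law steering a single focus to (xf, yf, z) mm.

    Uniform unit amplitudes; per-element delay ``km·sqrt((xe−xf)²+(ye−yf)²+z²)``
    wrapped to [0, 2π).  Equivalent (up to a constant phase) to decoding a
    single-point target.
    """
    if z <= 0:
        raise ValueError("focal depth must be positive")
    if abs(xf) > array.La / 2 or abs(yf) > array.La / 2:
        warnings.warn(
            "steering target lies beyond half the aperture; expect a degraded focus",
            stacklevel=2,
        )
    km = medium.wavenumber(array.f0)
    XE, YE = array.element_xy()
    delay = km * np.sqrt((XE - xf) ** 2 + (YE - yf) ** 2 + z**2)
    return DriveSolution(np.ones_like(delay), wrap_phase(delay))


def _element_coverage(
    centers: NDArray[np.float64], width: float, coords: NDArray[np.float64], d: float
) -> NDArray[np.float64]:
    """Fractional overlap of each grid cell with each element along one axis.

    Returns (n_elem, n_grid): antialiased rendering / averaging weights.
    """
    lo = np.maximum(centers[:, None] - width / 2, coords[None, :] - d / 2)
    hi = np.minimum(centers[:, None] + width / 2, coords[None, :] + d / 2)
    return np.clip(hi - lo, 0.0, None) / d


def render_source(
    drive: DriveSolution,
    array: ArraySpec = ArraySpec(),
    grid: Grid2D | None = None,
    medium: MediumProps = WATER,
) -> ComplexField:
    """Render a drive as the z = 0 source field: uniform pistons over each
    element's active area carrying the element's complex drive."""
    if drive.amplitude.shape != (array.n_elem_y, array.n_elem_x):
        raise ValueError("drive shape does not match array")
    if grid is None:
        grid = make_source_grid(array.La, array.f0, medium)
    if grid.extent_x < array.La or grid.extent_y < array.La:
        raise ValueError("grid smaller than the array aperture")
    xe = (np.arange(array.n_elem_x) - (array.n_elem_x - 1) / 2.0) * array.pitch
    ye = (np.arange(array.n_elem_y) - (array.n_elem_y - 1) / 2.0) * array.pitch
    wx = _element_coverage(xe, array.element_width, grid.x, grid.dx)
    wy = _element_coverage(ye, array.element_width, grid.y, grid.dy)
    vals = wy.T @ drive.complex_drive @ wx
    return ComplexField(grid, vals.astype(np.complex128), 0.0, array.f0)


def synthesize_field(
    drive: DriveSolution,
    array: ArraySpec = ArraySpec(),
    z: float = 10.0,
    medium: MediumProps = WATER,
    grid: Grid2D | None = None,
    band_limit: tuple[float, float] | None = None,
) -> ComplexField:
    """Forward model: render the drive as finite pistons and propagate to z."""
    src = render_source(drive, array, grid, medium)
    return propagate(src, z, medium, band_limit=band_limit)


def decode_pattern(
    target: TargetPattern,
    array: ArraySpec = ArraySpec(),
    medium: MediumProps = WATER,
    pose: EyePose | None = None,
    grid: Grid2D | None = None,
    iterations: int = 0,
) -> DriveSolution:
    """Decode a target pattern into a hologram (per-element drive).

    The target intensity is converted to pressure amplitude (square root),
    embedded at depth z on a propagation grid, and backpropagated to the
    array plane with the finite-aperture band limit (La, Li).  The resulting
    complex hologram is averaged over each element's active area; amplitudes
    are normalized to max 1 and phases stored as wrapped delays.  If a pose
    with nonzero tilt is given, the tilt-compensation ramp is added to the
    element delays (and the pose depth overrides the target depth).

    ``iterations > 0`` enables an optional alternate-projections refinement:
    the synthesized amplitude at the target plane is replaced by the desired
    amplitude (keeping phase) and re-backpropagated, which can sharpen
    complex patterns at the cost of extra FFTs.  Default off.
    """
    z = target.z if pose is None else pose.z
    if grid is None:
        grid = make_source_grid(max(array.La, target.Li), array.f0, medium)
    if target.Li > min(grid.extent_x, grid.extent_y):
        raise ValueError("target extent exceeds the propagation grid")
    lam = medium.wavelength(array.f0)
    if grid.dx > lam / 2 or grid.dy > lam / 2:
        raise ValueError("grid undersampled for the array frequency")

    # target intensity -> pressure amplitude, resampled onto the grid
    img = np.sqrt(target.image)
    h, w = img.shape
    rows = (np.arange(h) - (h - 1) / 2.0) * (target.Li / h)
    cols = (np.arange(w) - (w - 1) / 2.0) * (target.Li / w)
    interp = RegularGridInterpolator(
        (rows, cols), img, bounds_error=False, fill_value=0.0
    )
    X, Y = grid.meshgrid()
    amp = interp(np.stack([Y.ravel(), X.ravel()], axis=-1)).reshape(grid.shape)
    target_field = ComplexField(grid, amp.astype(np.complex128), z, array.f0)

    band = (array.La, target.Li)
    holo = backpropagate(target_field, z, medium, band_limit=band)
    for _ in range(max(0, int(iterations))):
        fwd = propagate(holo, z, medium, band_limit=band)
        phase = np.angle(fwd.values)
        constrained = ComplexField(grid, amp * np.exp(1j * phase), z, array.f0)
        holo = backpropagate(constrained, z, medium, band_limit=band)

    # least-squares projection of the hologram onto finite piston elements
    xe = (np.arange(array.n_elem_x) - (array.n_elem_x - 1) / 2.0) * array.pitch
    ye = (np.arange(array.n_elem_y) - (array.n_elem_y - 1) / 2.0) * array.pitch
    wx = _element_coverage(xe, array.element_width, grid.x, grid.dx)
    wy = _element_coverage(ye, array.element_width, grid.y, grid.dy)
    weights = wy.sum(axis=1)[:, None] * wx.sum(axis=1)[None, :]
    elem = (wy @ holo.values @ wx.T) / weights
    amplitude = np.abs(elem)
    peak = amplitude.max()
    if peak == 0:
        raise ValueError("decoded hologram is identically zero")
    amplitude = amplitude / peak
    delay = wrap_phase(-np.angle(elem))
    if pose is not None and (pose.theta_x != 0.0 or pose.theta_y != 0.0):
        delay = wrap_phase(delay + tilt_phase(array, pose.theta_x, pose.theta_y, medium))
    return DriveSolution(amplitude, delay)
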