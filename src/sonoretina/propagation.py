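"""Scalar wavefield containers and plane-to-plane acoustic propagation.

The workhorse is the band-limited angular spectrum method: a monochromatic
pressure field sampled on a uniform plane is decomposed into plane waves by a
2D FFT, each component is advanced by the exact free-space propagator
``exp(i·dz·sqrt(km² − kx² − ky²))``, and spatial frequencies above a
geometry-dependent cutoff are zeroed to suppress the sampling artifacts of
finite apertures.  A direct Rayleigh–Sommerfeld quadrature (`rs_oracle`)
serves as a brute-force cross-check.

Unit conventions, used consistently across the package:

* space in **mm**, spatial frequency in **rad/mm**;
* frequency in **MHz** (so time is implicitly in µs);
* medium sound speed in **m/s** (converted internally: ``c_mm_per_us =
  c / 1000``);
* pressure values are arbitrary-but-linear (Pa if the caller says so).

With these, the medium wavenumber is ``km = 2π·f/(c/1000)`` rad/mm and the
wavelength ``λ = c/(1000·f)`` mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray


@dataclass(frozen=True)
class Grid2D:
    """Uniform 2D sampling grid with a centered origin.

    ``x`` runs along array axis 1 (columns), ``y`` along axis 0 (rows).
    Sample ``(ny // 2, nx // 2)`` sits at the physical origin.
    """

    nx: int
    ny: int
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid needs at least 2 samples per axis")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def extent_x(self) -> float:
        return self.nx * self.dx

    @property
    def extent_y(self) -> float:
        return self.ny * self.dy

    @property
    def x(self) -> NDArray[np.float64]:
        return (np.arange(self.nx) - self.nx // 2) * self.dx

    @property
    def y(self) -> NDArray[np.float64]:
        return (np.arange(self.ny) - self.ny // 2) * self.dy

    @property
    def kx(self) -> NDArray[np.float64]:
        """Conjugate (angular) frequency samples along x, FFT-shifted order."""
        return 2.0 * np.pi * np.fft.fftshift(np.fft.fftfreq(self.nx, self.dx))

    @property
    def ky(self) -> NDArray[np.float64]:
        return 2.0 * np.pi * np.fft.fftshift(np.fft.fftfreq(self.ny, self.dy))

    def meshgrid(self) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
        return np.meshgrid(self.x, self.y)


@dataclass(frozen=True)
class MediumProps:
    """Homogeneous fluid medium.

    Parameters
    ----------
    c:
        Sound speed, m/s.
    rho:
        Density, kg/m³.
    alpha:
        Amplitude attenuation coefficient, Np·m⁻¹·MHz⁻¹ (linear-in-frequency
        model).  Defaults to 0 — free-field water maps are computed lossless.
    """

    c: float = 1500.0
    rho: float = 1000.0
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.c <= 0 or self.rho <= 0:
            raise ValueError("sound speed and density must be positive")
        if self.alpha < 0:
            raise ValueError("attenuation must be non-negative")

    def wavelength(self, f: float) -> float:
        """Wavelength in mm at frequency ``f`` (MHz)."""
        if f <= 0:
            raise ValueError("frequency must be positive")
        return self.c / (1000.0 * f)

    def wavenumber(self, f: float) -> float:
        """Angular wavenumber km = 2π/λ in rad/mm."""
        return 2.0 * np.pi / self.wavelength(f)


WATER = MediumProps()


@dataclass(frozen=True)
class ComplexField:
    """Complex pressure samples on one transverse plane.

    Attributes
    ----------
    grid:
        Sampling grid (mm).
    values:
        Complex array of shape ``grid.shape`` (ny, nx).
    z:
        Plane depth, mm (z = 0 is the array/transducer surface, z grows away
        from it).
    f:
        Acoustic frequency, MHz.
    """

    grid: Grid2D
    values: NDArray[np.complex128]
    z: float
    f: float

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.complex128)
        if vals.shape != self.grid.shape:
            raise ValueError(
                f"value shape {vals.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(vals.view(np.float64))):
            raise ValueError("field contains non-finite values")
        if self.f <= 0:
            raise ValueError("frequency must be positive")
        object.__setattr__(self, "values", vals)

    @property
    def magnitude(self) -> NDArray[np.float64]:
        return np.abs(self.values)

    def energy(self) -> float:
        """Discrete field energy ∑|p|²·dx·dy."""
        return float(np.sum(self.magnitude**2) * self.grid.dx * self.grid.dy)


def angular_spectrum(field: ComplexField) -> NDArray[np.complex128]:
    """Angular spectrum P(kx, ky) of a plane field.

    Uses the analysis kernel ``exp(-i(kx·x + ky·y))``; the returned array is
    FFT-shifted so that it is indexed by ``(grid.ky, grid.kx)`` with DC at the
    center, and scaled by dx·dy so that Parseval holds in the continuous
    normalization: ``∑|p|²·dx·dy = ∑|P|²·dkx·dky/(2π)²``.
    """
    p = np.fft.ifftshift(field.values)
    spec = np.fft.fft2(p) * (field.grid.dx * field.grid.dy)
    return np.fft.fftshift(spec)


def band_limit_cutoff(La: float, Li: float, wavelength: float, z: float) -> float:
    """Per-axis spatial-frequency cutoff (rad/mm) for a finite aperture.

    ``kc = π(La+Li) / (λ·sqrt(z² + (La+Li)²/4))`` where La and Li are the side
    lengths (mm) of the source aperture and of the target pattern plane, and z
    is the propagation distance.  As z → 0 the cutoff tends to the full
    propagating band 2π/λ; it decreases strictly with distance, discarding
    plane waves that geometrically cannot connect the two finite windows.
    """
    if La <= 0 or Li <= 0 or wavelength <= 0 or z <= 0:
        raise ValueError("La, Li, wavelength and z must all be positive")
    L = La + Li
    return np.pi * L / (wavelength * np.hypot(z, L / 2.0))


def _propagator(
    grid: Grid2D,
    dz: float,
    km: float,
    band_limit: tuple[float, float] | None,
    wavelength: float,
    conjugate: bool,
) -> NDArray[np.complex128]:
    """Unit-modulus spectral propagator on the unshifted FFT grid."""
    kx = 2.0 * np.pi * np.fft.fftfreq(grid.nx, grid.dx)
    ky = 2.0 * np.pi * np.fft.fftfreq(grid.ny, grid.dy)
    KX, KY = np.meshgrid(kx, ky)
    kz_sq = km**2 - KX**2 - KY**2
    propagating = kz_sq > 0.0
    kz = np.sqrt(np.where(propagating, kz_sq, 0.0))
    sign = -1.0 if conjugate else 1.0
    H = np.where(propagating, np.exp(sign * 1j * dz * kz), 0.0 + 0.0j)
    if band_limit is not None:
        La, Li = band_limit
        if dz > 0:
            kc = band_limit_cutoff(La, Li, wavelength, dz)
            H = np.where((np.abs(KX) <= kc) & (np.abs(KY) <= kc), H, 0.0 + 0.0j)
    return H


def _check_sampling(field: ComplexField, medium: MediumProps) -> float:
    lam = medium.wavelength(field.f)
    if field.grid.dx > lam / 2 or field.grid.dy > lam / 2:
        raise ValueError(
            f"grid undersampled: spacing ({field.grid.dx:g}, {field.grid.dy:g}) mm "
            f"exceeds λ/2 = {lam / 2:g} mm at {field.f:g} MHz"
        )
    return lam


def propagate(
    field: ComplexField,
    dz: float,
    medium: MediumProps = WATER,
    band_limit: tuple[float, float] | None = None,
) -> ComplexField:
    """Propagate a plane field forward by ``dz`` mm (angular spectrum method).

    Each plane-wave component is multiplied by ``exp(i·dz·sqrt(km²−kx²−ky²))``;
    evanescent components (kx²+ky² > km²) are zeroed outright, since at the
    propagation distances of interest (≫ λ) their decay is numerically total.
    ``band_limit=(La, Li)`` additionally zeroes |kx| or |ky| beyond the
    finite-aperture cutoff (see `band_limit_cutoff`), applied separably per
    axis.  If the medium is lossy the amplitude factor ``exp(−α·f·dz)`` is
    applied.

    The operator works on the field's own grid without internal padding and is
    therefore exactly unitary on the propagating band; build source grids with
    ≥ 2× the aperture extent (as the source constructors here do) to keep FFT
    wrap-around negligible.
    """
    if dz < 0:
        raise ValueError("negative dz: use backpropagate for upstream planes")
    lam = _check_sampling(field, medium)
    if dz == 0:
        return field
    km = medium.wavenumber(field.f)
    H = _propagator(field.grid, dz, km, band_limit, lam, conjugate=False)
    spec = np.fft.fft2(np.fft.ifftshift(field.values))
    out = np.fft.fftshift(np.fft.ifft2(spec * H))
    if medium.alpha > 0:
        out = out * np.exp(-medium.alpha * field.f * dz * 1e-3)  # α is per meter
    return ComplexField(field.grid, out, field.z + dz, field.f)


def backpropagate(
    field: ComplexField,
    dz: float,
    medium: MediumProps = WATER,
    band_limit: tuple[float, float] | None = None,
) -> ComplexField:
    """Propagate a plane field *backward* by ``dz`` mm (conjugate propagator).

    Exact inverse of `propagate` on the band-limited propagating subspace:
    the spectral factor is ``exp(−i·dz·sqrt(km²−kx²−ky²))``.  Used to turn a
    desired target-plane field into a source-plane hologram.
    """
    if dz < 0:
        raise ValueError("negative dz: use propagate for downstream planes")
    lam = _check_sampling(field, medium)
    if dz == 0:
        return field
    km = medium.wavenumber(field.f)
    H = _propagator(field.grid, dz, km, band_limit, lam, conjugate=True)
    spec = np.fft.fft2(np.fft.ifftshift(field.values))
    out = np.fft.fftshift(np.fft.ifft2(spec * H))
    return ComplexField(field.grid, out, field.z - dz, field.f)


def rs_oracle(
    source: ComplexField,
    target_points: NDArray[np.float64] | list[tuple[float, float, float]],
    medium: MediumProps = WATER,
) -> NDArray[np.complex128]:
    """Direct first Rayleigh–Sommerfeld integral at arbitrary points.

    Brute-force O(N·M) quadrature of

        p(r) = (1/2π) ∬ p(x',y',0) · (1/r − i·km) · (z/r) · e^{i·km·r}/r dx'dy'

    with r the source-sample-to-target distance.  No FFT, no band limit —
    this is the independent oracle the spectral propagator is validated
    against.  ``target_points`` is an (M, 3) array of (x, y, z) mm with z
    measured from the source plane.
    """
    _check_sampling(source, medium)
    pts = np.atleast_2d(np.asarray(target_points, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("target_points must be (M, 3) of (x, y, z) mm")
    if np.any(pts[:, 2] < 0):
        raise ValueError("target points must lie downstream (z ≥ 0)")
    km = medium.wavenumber(source.f)
    X, Y = source.grid.meshgrid()
    xs = X.ravel()
    ys = Y.ravel()
    ps = source.values.ravel()
    dA = source.grid.dx * source.grid.dy
    out = np.empty(len(pts), dtype=np.complex128)
    for i, (tx, ty, tz) in enumerate(pts):
        r = np.sqrt((tx - xs) ** 2 + (ty - ys) ** 2 + tz**2)
        if np.any(r == 0.0):
            raise ValueError(
                "target point coincides with a source sample (singular kernel)"
            )
        kernel = (1.0 / r - 1j * km) * (tz / r) * np.exp(1j * km * r) / r
        out[i] = np.sum(ps * kernel) * dA / (2.0 * np.pi)
    return out


def focused_piston_source(
    D: float,
    F: float,
    f: float,
    grid: Grid2D,
    medium: MediumProps = WATER,
) -> ComplexField:
    """Spherically focused circular piston at z = 0.

    Unit-amplitude disk of diameter ``D`` mm carrying the focusing phase
    ``−km·(sqrt(r²+F²) − F)`` (a delay that equalizes path lengths to the
    geometric focus at depth ``F`` mm); zero outside the disk.
    """
    if D <= 0 or F <= 0:
        raise ValueError("aperture and focal length must be positive")
    lam = medium.wavelength(f)
    if grid.dx > lam / 2 or grid.dy > lam / 2:
        raise ValueError("grid spacing must be ≤ λ/2 for a faithful source")
    if grid.extent_x < 1.5 * D or grid.extent_y < 1.5 * D:
        raise ValueError("grid extent must be ≥ 1.5 × aperture diameter")
    km = medium.wavenumber(f)
    X, Y = grid.meshgrid()
    r = np.hypot(X, Y)
    phase = -km * (np.sqrt(r**2 + F**2) - F)
    vals = np.where(r <= D / 2.0, np.exp(1j * phase), 0.0 + 0.0j)
    return ComplexField(grid, vals, 0.0, f)


def make_source_grid(
    D: float,
    f: float,
    medium: MediumProps = WATER,
    oversample: float = 4.0,
    pad_factor: float = 2.0,
) -> Grid2D:
    """Grid sized for a diameter-``D`` source: spacing λ/oversample, extent
    ≥ pad_factor·D, sample count rounded up to the next power of two."""
    lam = medium.wavelength(f)
    d = lam / oversample
    n = int(2 ** np.ceil(np.log2(pad_factor * D / d)))
    return Grid2D(n, n, d, d)


def on_axis_piston(
    a: float, z: NDArray[np.float64] | float, f: float, medium: MediumProps = WATER
) -> NDArray[np.complex128]:
    """Closed-form on-axis pressure of an unfocused plane piston of radius
    ``a`` mm (unit surface pressure), for validating `rs_oracle`:

        p(z) = e^{i·km·z} − (z/R)·e^{i·km·R},  R = sqrt(z² + a²).
    """
    km = medium.wavenumber(f)
    z = np.asarray(z, dtype=float)
    R = np.sqrt(z**2 + a**2)
    return np.exp(1j * km * z) - (z / R) * np.exp(1j * km * R)


@dataclass(frozen=True)
class Layer:
    """One planar tissue layer on the propagation path."""

    name: str
    thickness: float  # mm
    medium: MediumProps


@dataclass(frozen=True)
class LayeredPath:
    """Stack of planar layers tiling the path from z = 0 downstream.

    Beyond the last layer the final layer's medium continues indefinitely.
    Interfaces are treated at normal incidence: the pressure amplitude is
    multiplied by the transmission coefficient T = 2·Z₂/(Z₁+Z₂).
    """

    layers: tuple[Layer, ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("at least one layer required")
        if any(l.thickness <= 0 for l in self.layers):
            raise ValueError("layer thicknesses must be positive")

    def total_thickness(self) -> float:
        return sum(l.thickness for l in self.layers)


def propagate_layered(
    field: ComplexField, z_target: float, path: LayeredPath
) -> ComplexField:
    """Propagate a z = 0 field to ``z_target`` through planar layers.

    Within each layer the angular spectrum propagator uses that layer's
    wavenumber and attenuation; at each interface the normal-incidence
    amplitude transmission factor is applied.  ``z_target`` may lie beyond the
    stack, in which case the last medium extends to it.
    """
    if field.z != 0:
        raise ValueError("layered propagation starts from the z = 0 plane")
    if z_target <= 0:
        raise ValueError("target depth must be positive")
    cur = field
    z_done = 0.0
    prev_medium: MediumProps | None = None
    for layer in path.layers:
        if z_done >= z_target:
            break
        if prev_medium is not None:
            Z1 = prev_medium.rho * prev_medium.c
            Z2 = layer.medium.rho * layer.medium.c
            T = 2.0 * Z2 / (Z1 + Z2)
            cur = ComplexField(cur.grid, cur.values * T, cur.z, cur.f)
        step = min(layer.thickness, z_target - z_done)
        cur = propagate(cur, step, layer.medium)
        z_done += step
        prev_medium = layer.medium
    if z_done < z_target:
        cur = propagate(cur, z_target - z_done, path.layers[-1].medium)
    return cur
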