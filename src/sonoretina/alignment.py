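"""Synthetic B-mode eye imaging and automatic pose recovery.

The array images the eye it stimulates, so the stimulation pattern can be
auto-aligned: the retina depth and the array-to-eye tilt are extracted from
edges detected in cross-sectional B-mode slices and fed back into the
hologram computation as a depth override and a tilt-compensation phase ramp.

The phantom generator stands in for the imaging sequence of the physical
system.  It renders the eye as a sphere with an anechoic interior (vitreous),
echogenic surrounding tissue, and extra-bright anterior (cornea) and
posterior (retina) arcs, with multiplicative speckle at a configurable
signal-to-noise ratio and log compression to dB — enough structure for the
edge-detection and pose-fitting chain to be exercised against an analytically
known geometry.

Geometry and conventions
------------------------
Axial coordinate z (mm) increases away from the array; image row 0 is z = 0.
Tilt is parameterized by the angles (θx, θy) between the array axis and the
eye axis: the sphere center is displaced laterally by
``(R·tanθx, R·tanθy)/sqrt(1+tan²θx+tan²θy)`` so that the surface normal at
the point where the array axis pierces the anterior surface makes exactly
(θx, θy) with the axis.  A positive θx therefore tips the apex toward +x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy import ndimage
from skimage import feature


@dataclass(frozen=True)
class BModeImage:
    """One log-compressed B-mode slice (dB scale, values ≥ 0)."""

    intensity: NDArray[np.float64]
    dz: float  # axial pixel size, mm (rows)
    dx: float  # lateral pixel size, mm (columns)
    y: float = 0.0  # slice position along the elevational axis, mm

    def __post_init__(self) -> None:
        img = np.asarray(self.intensity, dtype=float)
        if img.ndim != 2:
            raise ValueError("B-mode intensity must be 2D")
        if np.any(~np.isfinite(img)) or np.any(img < 0):
            raise ValueError("B-mode intensities must be finite and ≥ 0")
        if self.dz <= 0 or self.dx <= 0:
            raise ValueError("pixel sizes must be positive")
        object.__setattr__(self, "intensity", img)

    @property
    def z_coords(self) -> NDArray[np.float64]:
        return np.arange(self.intensity.shape[0]) * self.dz

    @property
    def x_coords(self) -> NDArray[np.float64]:
        n = self.intensity.shape[1]
        return (np.arange(n) - n // 2) * self.dx


@dataclass(frozen=True)
class EyePhantomSpec:
    """Ground-truth geometry and noise level of the synthetic eye.

    ``radius`` and ``anterior_depth`` are in mm; tilt angles in degrees;
    ``speckle_snr_db`` sets the multiplicative speckle strength (mean/std of
    the linear-intensity speckle factor, in dB; ``inf`` disables speckle).
    """

    radius: float = 3.5
    anterior_depth: float = 3.0
    theta_x: float = 0.0
    theta_y: float = 0.0
    speckle_snr_db: float = 20.0
    seed: int = 0
    dz: float = 0.05
    dx: float = 0.05
    axial_extent: float = 14.0
    lateral_extent: float = 12.0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.anterior_depth <= 0:
            raise ValueError("radius and anterior depth must be positive")
        if abs(self.theta_x) >= 45 or abs(self.theta_y) >= 45:
            raise ValueError("tilt angles must satisfy |θ| < 45°")

    def center(self) -> tuple[float, float, float]:
        """Sphere center (xc, yc, zc) in mm implied by depth and tilt."""
        tx = np.tan(np.radians(self.theta_x))
        ty = np.tan(np.radians(self.theta_y))
        s = self.radius / np.sqrt(1.0 + tx**2 + ty**2)
        xc, yc = s * tx, s * ty
        zc = self.anterior_depth + s
        return xc, yc, zc

    @property
    def retina_depth(self) -> float:
        """Axial coordinate where the array axis meets the posterior surface."""
        xc, yc, zc = self.center()
        return zc + np.sqrt(self.radius**2 - xc**2 - yc**2)

    def anterior_z(self, x: NDArray[np.float64], y: float) -> NDArray[np.float64]:
        """Analytic anterior-surface depth z(x) in the slice at elevation y
        (NaN where the slice lies outside the sphere)."""
        xc, yc, zc = self.center()
        q = self.radius**2 - (x - xc) ** 2 - (y - yc) ** 2
        return np.where(q > 0, zc - np.sqrt(np.maximum(q, 0.0)), np.nan)

    def posterior_z(self, x: NDArray[np.float64], y: float) -> NDArray[np.float64]:
        xc, yc, zc = self.center()
        q = self.radius**2 - (x - xc) ** 2 - (y - yc) ** 2
        return np.where(q > 0, zc + np.sqrt(np.maximum(q, 0.0)), np.nan)


@dataclass(frozen=True)
class AlignmentResult:
    """Recovered eye pose plus the edge evidence it was fitted from."""

    depth: float
    theta_x: float
    theta_y: float
    top_points: NDArray[np.float64]  # (N, 3) of (x, y, z) mm
    bottom_points: NDArray[np.float64]

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if len(self.top_points) == 0 or len(self.bottom_points) == 0:
            raise ValueError("edge point sets must be non-empty")


class EdgeNotFoundError(RuntimeError):
    """Raised when a required arc (top/cornea or bottom/retina) is missing."""


_DB_RANGE = 40.0  # displayed dynamic range of the log-compressed image


def synthesize_bmode(spec: EyePhantomSpec, n_slices: int = 9) -> list[BModeImage]:
    """Render B-mode slices of the eye phantom at known geometry.

    Slices are spaced uniformly over the central ±2 mm of the elevational
    axis (a single slice sits at y = 0).  Each slice shows echogenic tissue
    outside the eye sphere, an anechoic interior, and boosted-brightness
    anterior/posterior arcs; multiplicative speckle with mean 1 and standard
    deviation ``10^(−snr_db/20)`` multiplies the tissue signal, and the result
    is log-compressed to a 40 dB display range.  Bit-reproducible for a given
    spec (seed included).
    """
    if n_slices < 1:
        raise ValueError("n_slices must be ≥ 1")
    rng = np.random.default_rng(spec.seed)
    xc, yc, zc = spec.center()
    nz = int(round(spec.axial_extent / spec.dz))
    nx = int(round(spec.lateral_extent / spec.dx)) | 1  # odd: symmetric x grid
    z = np.arange(nz) * spec.dz
    x = (np.arange(nx) - nx // 2) * spec.dx
    Z, X = np.meshgrid(z, x, indexing="ij")
    if spec.anterior_depth < 3 * spec.dz:
        raise ValueError("eye anterior surface lies too close to the array")
    if zc + spec.radius > spec.axial_extent - 3 * spec.dz:
        raise ValueError("eye extends beyond the axial image range")
    if abs(xc) + spec.radius > spec.lateral_extent / 2:
        raise ValueError("eye extends beyond the lateral image range")

    ys = np.linspace(-2.0, 2.0, n_slices) if n_slices > 1 else np.array([0.0])
    tissue, vitreous, arc_boost = 1.0, 0.1, 4.0
    snr_lin = 10.0 ** (spec.speckle_snr_db / 20.0)
    slices = []
    for y in ys:
        q = spec.radius**2 - (y - yc) ** 2
        d = np.sqrt((X - xc) ** 2 + (Z - zc) ** 2)  # distance to slice circle center
        if q > 0:
            rs = np.sqrt(q)
            # smooth analytic step in the signed distance so the inflection
            # (hence the detected edge) sits exactly on the sphere, free of
            # pixel-quantization bias; bright shell on the outward side
            t = (d - rs) / spec.dz
            outer = 1.0 / (1.0 + np.exp(-6.0 * t))
            shell = np.exp(-0.5 * ((d - rs - 4 * spec.dz) / (3 * spec.dz)) ** 2)
        else:
            outer = np.ones_like(d)
            shell = np.zeros_like(d)
        img = vitreous + (tissue - vitreous) * outer + arc_boost * shell * outer
        if np.isfinite(spec.speckle_snr_db):
            # multi-look speckle: mean-1 gamma = average of K unit-exponential
            # intensity draws, K chosen so mean/std matches the stated SNR
            looks = max(snr_lin**2, 1.0)
            img = img * rng.gamma(looks, 1.0 / looks, size=img.shape)
        db = 10.0 * np.log10(np.maximum(img, 1e-6) / (tissue + arc_boost))
        db = np.clip(db + _DB_RANGE, 0.0, _DB_RANGE)
        slices.append(BModeImage(db, spec.dz, spec.dx, y=float(y)))
    return slices


def detect_edges(
    image: BModeImage,
    sigma: float = 2.0,
    low: float = 0.4,
    high: float = 0.8,
) -> NDArray[np.bool_]:
    """Canny edge map of a B-mode slice.

    ``low`` and ``high`` are hysteresis thresholds expressed as fractions of
    the 99th percentile of the Gaussian-smoothed gradient magnitude, so the
    detector adapts to the slice's own contrast.
    """
    if not (0 <= low < high):
        raise ValueError("thresholds must satisfy 0 ≤ low < high")
    img = image.intensity
    gx = ndimage.gaussian_filter(img, sigma, order=(0, 1))
    gz = ndimage.gaussian_filter(img, sigma, order=(1, 0))
    gmag = np.hypot(gx, gz)
    scale = np.percentile(gmag, 99.0)
    if scale == 0:
        return np.zeros_like(img, dtype=bool)
    return feature.canny(
        img, sigma=sigma, low_threshold=low * scale, high_threshold=high * scale
    )


def _subpixel_row(gmag_col: NDArray[np.float64], row: int) -> float:
    """Parabolic refinement of a gradient-magnitude peak along one column."""
    if 0 < row < len(gmag_col) - 1:
        a, b, c = gmag_col[row - 1], gmag_col[row], gmag_col[row + 1]
        denom = a - 2 * b + c
        if denom < 0:
            return row + 0.5 * (a - c) / denom
    return float(row)


def _arc_points(
    image: BModeImage, edges: NDArray[np.bool_], sigma: float = 2.0
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Split an edge map into top (anterior) and bottom (posterior) arc
    points, one point per image column, in (x, z) mm.

    The anechoic interior anchors the split: its central row (darkest band of
    the central columns) separates anterior from posterior candidates.  Per
    column, the edge pixel with the strongest smoothed gradient on each side
    wins — speckle edges are much weaker than the boundary step — and its
    axial position is refined to sub-pixel by a parabolic fit on the gradient
    magnitude.  Columns whose anterior–posterior chord is under 70% of the
    widest chord graze the silhouette (edges localize poorly there) and
    contribute nothing.
    """
    xs = image.x_coords
    nz, nx = edges.shape
    gx = ndimage.gaussian_filter(image.intensity, sigma, order=(0, 1))
    gz = ndimage.gaussian_filter(image.intensity, sigma, order=(1, 0))
    gmag = np.hypot(gx, gz)
    central = image.intensity[:, nx // 3 : 2 * nx // 3]
    profile = ndimage.gaussian_filter1d(central.mean(axis=1), 3.0)
    mid = int(np.argmin(profile))

    cand = []
    for j in range(nx):
        rows = np.flatnonzero(edges[:, j])
        up = rows[rows < mid]
        lo = rows[rows >= mid]
        if len(up) == 0 or len(lo) == 0:
            cand.append(None)
            continue
        g = gmag[:, j]
        rt = up[np.argmax(g[up])]
        rb = lo[np.argmax(g[lo])]
        cand.append((rt, rb, (rb - rt) * image.dz))
    spans = [c[2] for c in cand if c is not None]
    if not spans:
        return np.empty((0, 2)), np.empty((0, 2))
    min_span = max(1.0, 0.7 * max(spans))
    top, bottom = [], []
    for j, c in enumerate(cand):
        if c is None or c[2] < min_span:
            continue
        g = gmag[:, j]
        top.append((xs[j], _subpixel_row(g, c[0]) * image.dz))
        bottom.append((xs[j], _subpixel_row(g, c[1]) * image.dz))
    return np.asarray(top, dtype=float), np.asarray(bottom, dtype=float)


def stack_to_surface(
    slices: list[BModeImage],
    edges: list[NDArray[np.bool_]] | None = None,
    **canny_kwargs,
) -> dict[str, NDArray[np.float64]]:
    """Lift per-slice edge pixels to labeled 3D boundary point clouds.

    Returns ``{"top": (N, 3), "bottom": (M, 3)}`` arrays of (x, y, z) mm.
    Raises if the slices disagree on pixel geometry.  A stack whose slices
    all share one elevation (degenerate y extent) is reported but allowed.
    """
    if len(slices) < 1:
        raise ValueError("at least one slice required")
    d0 = (slices[0].dz, slices[0].dx)
    if any((s.dz, s.dx) != d0 for s in slices):
        raise ValueError("inconsistent pixel geometry across slices")
    if edges is None:
        edges = [detect_edges(s, **canny_kwargs) for s in slices]
    top_all, bottom_all = [], []
    for s, e in zip(slices, edges):
        top, bottom = _arc_points(s, e)
        for pts, acc in ((top, top_all), (bottom, bottom_all)):
            if len(pts):
                acc.append(
                    np.column_stack([pts[:, 0], np.full(len(pts), s.y), pts[:, 1]])
                )
    out = {
        "top": np.vstack(top_all) if top_all else np.empty((0, 3)),
        "bottom": np.vstack(bottom_all) if bottom_all else np.empty((0, 3)),
    }
    return out


def estimate_pose(
    slices: list[BModeImage],
    edges: list[NDArray[np.bool_]] | None = None,
    apex_window: float = 2.5,
    **canny_kwargs,
) -> AlignmentResult:
    """Recover retina depth and array-to-eye tilt from a B-mode stack.

    Depth: posterior (retina) edge points within ±1.5 mm of the lateral
    center of the most central slice are fitted with a quadratic in x and
    evaluated at x = 0 — the array-axis distance to the retina.

    Tilt: anterior (cornea) edge points from all slices within
    ``apex_window`` mm (lateral radius) of the array axis are fitted with a
    least-squares quadric — an algebraic sphere ``|P|² = 2·P·C + k`` — and
    the tilt angles are taken from the surface normal where the array axis
    pierces the fitted surface: ``tanθx = xc/s``, ``tanθy = yc/s`` with
    ``s = sqrt(R² − xc² − yc²)`` (degrees; a positive θ tips the apex toward
    the positive axis).  Fitting the quadric over the whole imaged cornea cap
    avoids the curvature bias of small-window tangent-plane fits.
    """
    cloud = stack_to_surface(slices, edges, **canny_kwargs)
    top, bottom = cloud["top"], cloud["bottom"]
    if len(top) == 0:
        raise EdgeNotFoundError("anterior (cornea) edge not found in any slice")
    if len(bottom) == 0:
        raise EdgeNotFoundError("posterior (retina) edge not found in any slice")

    y_central = min((s.y for s in slices), key=abs)
    sel = (bottom[:, 1] == y_central) & (np.abs(bottom[:, 0]) <= 1.5)
    pts = bottom[sel]
    if len(pts) < 3:
        raise EdgeNotFoundError("posterior edge too short near the lateral center")
    coef = np.polynomial.polynomial.polyfit(pts[:, 0], pts[:, 2], 2)
    depth = float(coef[0])

    r = np.hypot(top[:, 0], top[:, 1])
    apex = top[r <= apex_window]
    if len(apex) < 6:
        raise EdgeNotFoundError("anterior edge has too few apex-region points")
    # algebraic sphere fit: x²+y²+z² = 2(xc·x + yc·y + zc·z) + (R² − |C|²)
    A = np.column_stack([2 * apex, np.ones(len(apex))])
    b = np.sum(apex**2, axis=1)
    (xc, yc, zc, k), *_ = np.linalg.lstsq(A, b, rcond=None)
    R_sq = k + xc**2 + yc**2 + zc**2
    s_sq = R_sq - xc**2 - yc**2
    if R_sq <= 0 or s_sq <= 0:
        raise EdgeNotFoundError("anterior surface fit degenerate")
    s = np.sqrt(s_sq)
    theta_x = float(np.degrees(np.arctan2(xc, s)))
    theta_y = float(np.degrees(np.arctan2(yc, s)))
    return AlignmentResult(depth, theta_x, theta_y, top, bottom)
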