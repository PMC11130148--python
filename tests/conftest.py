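import numpy as np
import pytest

from sonoretina import (
    ArraySpec,
    ComplexField,
    Grid2D,
    MediumProps,
    focal_spot,
    make_source_grid,
)


@pytest.fixture(scope="session")
def water() -> MediumProps:
    return MediumProps(c=1500.0, rho=1000.0)


@pytest.fixture(scope="session")
def array_default() -> ArraySpec:
    return ArraySpec()


@pytest.fixture(scope="session")
def array_grid(array_default, water) -> Grid2D:
    """Propagation grid sized for the 16×16 array (λ/4 sampling, ≥2× extent)."""
    return make_source_grid(array_default.La, array_default.f0, water)


@pytest.fixture(scope="session")
def focus20(water):
    """Focal-plane field of the 20 MHz, D=10 mm, F=10 mm transducer at z=10 mm
    (shared by the resolution-related tests; ~2048² FFT, computed once)."""
    field, z = focal_spot(10.0, 10.0, 20.0, water, z=10.0)
    return field


@pytest.fixture(scope="session")
def letter_c():
    from sonoretina import letter_c_pattern

    return letter_c_pattern()


def small_random_field(seed: int, n: int = 32, dx: float = 0.1, f: float = 4.5):
    rng = np.random.default_rng(seed)
    g = Grid2D(n, n, dx, dx)
    vals = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    return ComplexField(g, vals, 0.0, f)


def band_limited_field(seed: int, n: int = 64, dx: float = 0.1, f: float = 4.5):
    """Random field whose spectrum occupies only low, propagating spatial
    frequencies (for exact round-trip checks)."""
    rng = np.random.default_rng(seed)
    spec = np.zeros((n, n), dtype=complex)
    w = n // 8
    block = rng.standard_normal((2 * w, 2 * w)) + 1j * rng.standard_normal((2 * w, 2 * w))
    spec[n // 2 - w : n // 2 + w, n // 2 - w : n // 2 + w] = block
    vals = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(spec)))
    g = Grid2D(n, n, dx, dx)
    return ComplexField(g, vals, 0.0, f)
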