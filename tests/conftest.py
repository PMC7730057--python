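import numpy as np
import pytest

from busfeat.synthetic_data import PhantomConfig, generate_phantoms


def disk_mask(radius: int, size: int | None = None, center=None) -> np.ndarray:
    size = size or (2 * radius + 21)
    center = center or (size / 2.0, size / 2.0)
    rr, cc = np.mgrid[0:size, 0:size]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def ellipse_mask(a: float, b: float, angle_deg: float, size: int) -> np.ndarray:
    """Rasterized ellipse, semi-axes a >= b, major axis at angle_deg from x-axis."""
    rr, cc = np.mgrid[0:size, 0:size]
    c0 = (size - 1) / 2.0
    dr, dc = rr - c0, cc - c0
    t = np.radians(angle_deg)
    u = dc * np.cos(t) - dr * np.sin(t)
    v = dc * np.sin(t) + dr * np.cos(t)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


@pytest.fixture(scope="session")
def phantom_small():
    """30 phantoms (15/15), shared across tests that only read them."""
    return generate_phantoms(PhantomConfig(n_benign=15, n_malignant=15, seed=7))


@pytest.fixture(scope="session")
def phantom_medium():
    """60 phantoms (30/30) for CV-based tests."""
    return generate_phantoms(PhantomConfig(n_benign=30, n_malignant=30, seed=11))
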