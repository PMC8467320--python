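import numpy as np
import pytest

from ppdxdeg import crackmorph as cm


def digitize_disk(radius_px: int, pad: int = 10) -> np.ndarray:
    n = 2 * (radius_px + pad) + 1
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    return ((xx - c) ** 2 + (yy - c) ** 2 <= radius_px**2).astype(np.uint8)


def digitize_ellipse(a_px: float, b_px: float, angle_deg: float = 0.0, pad: int = 8) -> np.ndarray:
    """Filled ellipse with semi-axes a, b rotated by angle (y-up convention)."""
    half = int(np.ceil(max(a_px, b_px))) + pad
    n = 2 * half + 1
    yy, xx = np.mgrid[0:n, 0:n]
    dx = xx - half
    dy = -(yy - half)  # y-up
    th = np.radians(angle_deg)
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    return ((u / a_px) ** 2 + (v / b_px) ** 2 <= 1).astype(np.uint8)


def measure_single(pixels: np.ndarray, pixel_size: float = 1.0) -> cm.CrackRecord:
    recs = cm.measure_all(cm.BinaryMask(pixels, pixel_size))
    assert len(recs) == 1
    return recs[0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
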