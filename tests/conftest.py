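import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stedring import (
    ImagePlane,
    SceneConfig,
    generate_scene,
    render_scene,
)

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def draw_thin_ring(
    shape=(101, 101), center=(50.0, 50.0), radius=10.0, value=100.0
) -> np.ndarray:
    """Deposit an (approximately) 1-px-wide uniform circle on a zero raster."""
    img = np.zeros(shape)
    n = int(math.ceil(2 * math.pi * radius * 8))
    th = np.linspace(0, 2 * math.pi, n, endpoint=False)
    r = np.clip(np.round(center[0] + radius * np.cos(th)).astype(int), 0, shape[0] - 1)
    c = np.clip(np.round(center[1] + radius * np.sin(th)).astype(int), 0, shape[1] - 1)
    img[r, c] = value
    return img


def blurred_ring_image(
    shape=(101, 101), center=(50.0, 50.0), radius=10.0, sigma=2.0, amp=100.0
) -> np.ndarray:
    """Analytic Gaussian-blurred thin ring: amp * exp(-(d^2+r^2)/2s^2) I0(dr/s^2)."""
    from scipy.special import i0e

    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    d = np.hypot(rr - center[0], cc - center[1])
    x = d * radius / sigma**2
    val = amp * np.exp(-((d - radius) ** 2) / (2 * sigma**2)) * i0e(x)
    return val


@pytest.fixture(scope="session")
def single_ring_scene():
    """One isolated noiseless rendered ring with its ground truth."""
    cfg = SceneConfig(
        image_size_px=(160, 160), n_cells=1, rings_per_cell_range=(1, 1),
        cluster_probability=0.0, radius_range_nm=(160.0, 240.0), rng_seed=11,
    )
    truth = generate_scene(cfg)
    sted, conf, centers = render_scene(truth, noise=False)
    return truth, sted, conf, centers


@pytest.fixture()
def uniform_ring_plane():
    img = draw_thin_ring()
    return ImagePlane(img, pixel_size_nm=20.0)
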