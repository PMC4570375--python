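import numpy as np
import pytest

import flytrack as ft


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def render_blob(
    shape=(80, 80),
    center=(40.0, 40.0),
    theta=0.0,
    sa=6.0,
    sb=2.5,
    contrast=120.0,
    cutoff=1.0,
):
    """Render one anisotropic Gaussian darkening profile and return
    (pixels_xy, weights) of the region where the depth exceeds ``cutoff``."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * (xx - center[0]) + st * (yy - center[1])
    v = -st * (xx - center[0]) + ct * (yy - center[1])
    depth = contrast * np.exp(-0.5 * ((u / sa) ** 2 + (v / sb) ** 2))
    rr, cc = np.nonzero(depth > cutoff)
    return np.column_stack([cc, rr]).astype(float), depth[rr, cc]


def flat_model(shape=(60, 60), level=220.0, sigma=0.0):
    """A trivially fitted background model (constant scene)."""
    return ft.BackgroundModel(
        mu=np.full(shape, level),
        sigma=np.full(shape, sigma),
        n_frames_fitted=5,
    )


@pytest.fixture
def small_scene():
    return ft.SceneConfig(
        width=300, height=300, plate_radius=130, n_flies=4, seed=3
    )
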