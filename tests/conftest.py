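import numpy as np
import pytest

from fazmorph.types import EyeGroundTruth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_blob_mask(rng, size=96, n_lobes=4):
    """Random star-convex blob mask for geometry oracle tests."""
    c = size / 2
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    ang = np.arctan2(yy - c, xx - c)
    base = rng.uniform(size * 0.15, size * 0.3)
    r = np.full_like(ang, base)
    for k in range(1, n_lobes + 1):
        amp = rng.uniform(0, base * 0.25)
        phase = rng.uniform(0, 2 * np.pi)
        r += amp * np.cos(k * ang + phase)
    rad = np.hypot(xx - c, yy - c)
    return rad <= np.maximum(r, 2.0)


@pytest.fixture
def make_blob(rng):
    return lambda **kw: random_blob_mask(rng, **kw)


def gapfree_eye(eye_id, a_um, b_um, theta_deg, seed, layer="superficial"):
    return EyeGroundTruth(
        eye_id=eye_id,
        group="control",
        layer=layer,
        faz_semi_major_um=a_um,
        faz_semi_minor_um=b_um,
        faz_orientation_deg=theta_deg,
        n_gaps=0,
        gap_arc_deg=0.0,
        dropout_fraction=0.0,
        bcva_letters=85.0,
        render_seed=seed,
    )
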