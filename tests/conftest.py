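import math

import numpy as np
import pytest

import mitomorph as mm


@pytest.fixture(scope="session")
def disk_mask():
    """Digital disk of radius 30 px (pixel centers within the circle)."""
    yy, xx = np.mgrid[0:80, 0:80]
    return (xx - 40) ** 2 + (yy - 40) ** 2 <= 30 * 30


@pytest.fixture(scope="session")
def disk_scene():
    """Noiseless scene with one dark disk of radius 30, gradient only."""
    return mm.SceneSpec(
        particles=(mm.ParticleSpec((128, 128), 30.0, 30.0),),
        noise_sd=0.0,
        stripe_amplitude=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def random_blobs():
    """A set of >= 50 random connected particles for oracle comparisons."""
    rng = np.random.default_rng(11)
    blobs = []
    for _ in range(55):
        m = np.zeros((48, 48), dtype=bool)
        a = rng.uniform(4, 15)
        b = rng.uniform(2, a)
        th = rng.uniform(0, math.pi)
        cy, cx = rng.uniform(18, 30, size=2)
        yy, xx = np.mgrid[0:48, 0:48]
        u = (xx - cx) * math.cos(th) + (yy - cy) * math.sin(th)
        v = -(xx - cx) * math.sin(th) + (yy - cy) * math.cos(th)
        m = (u / a) ** 2 + (v / b) ** 2 <= 1
        # roughen the boundary so blobs are not perfect ellipses
        noise = rng.random(m.shape) < 0.03
        m = m ^ (noise & m)
        from skimage.measure import label

        lab = label(m, connectivity=2)
        if lab.max() == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        m = lab == (np.argmax(sizes) + 1)
        if m.sum() >= 3:
            blobs.append(m)
    assert len(blobs) >= 50
    return blobs
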