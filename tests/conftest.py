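import numpy as np
import pytest

from cervimorph import generate_epithelium, generate_three_disc_scene, make_preset

# Small frame for fast smoke tests: still holds >= 30 nuclei for every preset.
SMALL = dict(width=304, height=236)


@pytest.fixture(scope="session")
def three_disc_scene():
    return generate_three_disc_scene()


@pytest.fixture(scope="session")
def three_disc_mask(three_disc_scene):
    return three_disc_scene.grey == 0


@pytest.fixture(scope="session")
def normal_small():
    """One small Normal-preset image plus its ground truth."""
    return generate_epithelium(make_preset("NORMAL"), seed=3, **SMALL)


@pytest.fixture(scope="session")
def cin3_small():
    return generate_epithelium(make_preset("CIN3"), seed=3, **SMALL)


def random_blob_mask(rng: np.random.Generator, shape=(60, 80), n_discs=6):
    """A random union of discs, for morphology property tests."""
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for _ in range(n_discs):
        cy = rng.integers(5, shape[0] - 5)
        cx = rng.integers(5, shape[1] - 5)
        r = rng.integers(2, 7)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return mask
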