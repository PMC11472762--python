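import numpy as np
import pytest

from keelmorph.radiograph_io import Radiograph
from keelmorph.synthetic_data import (FlockSimParams, PhantomSpec,
                                      make_phantom, simulate_flock)


@pytest.fixture(scope="session")
def phantom_clean():
    """Noise-free, haze-free phantom with exact analytic truth."""
    return make_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def phantom_noisy():
    """Phantom under realistic haze + noise."""
    return make_phantom(PhantomSpec(seed=1, noise_sd=1.0, haze=5.0))


@pytest.fixture(scope="session")
def flock_small():
    """Study-sized flock (155 birds) at the default conditions."""
    return simulate_flock(FlockSimParams(n_birds=155, seed=0))


@pytest.fixture(scope="session")
def flock_large():
    """Large flock for law-of-large-numbers checks."""
    return simulate_flock(FlockSimParams(n_birds=5000, seed=1))


def flat_image(value=0.0, shape=(128, 128), mm_per_px=None):
    return Radiograph(pixels=np.full(shape, float(value)),
                      mm_per_px=mm_per_px, photometric_normalized=True)


def rotate90(image: Radiograph):
    """Rotate a radiograph 90 degrees CCW plus the point map (x,y)->(y,N-1-x)."""
    ncol = image.shape[1]
    rot = Radiograph(pixels=np.rot90(image.pixels, k=1),
                     mm_per_px=image.mm_per_px,
                     bird_id=image.bird_id,
                     photometric_normalized=True)

    def map_point(p):
        x, y = p
        return (y, ncol - 1 - x)

    return rot, map_point
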