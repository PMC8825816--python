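import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose oracles.py

from octcyst import Shadow, dme_like, generate_phantom


@pytest.fixture(scope="session")
def cystic_scan():
    return generate_phantom(dme_like(cystic=True, seed=7))


@pytest.fixture(scope="session")
def clean_scan():
    return generate_phantom(dme_like(cystic=False, seed=7))


@pytest.fixture(scope="session")
def shadow_scan():
    """Shadow-only phantom: columns 60-70 (0-based), strong attenuation."""
    return generate_phantom(
        dme_like(cystic=False, shadows=(Shadow(60, 70, 0.2),), seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)


def random_images(count: int, shape: tuple[int, int], seed: int = 0):
    """Random smooth-ish test images in [0, 255]."""
    rng = np.random.default_rng(seed)
    for _ in range(count):
        yield rng.uniform(0.0, 255.0, size=shape)
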