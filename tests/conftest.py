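import numpy as np
import pytest

from subtomo.maps import DensityMap
from subtomo.phantoms import MicrotubulePhantomParams, make_microtubule_map


@pytest.fixture(scope="session")
def mt_params():
    """Short default-lattice microtubule for alignment-scale tests."""
    return MicrotubulePhantomParams(length=160.0)


@pytest.fixture(scope="session")
def mt_map(mt_params) -> DensityMap:
    """Canonical 48³ microtubule phantom at 8 Å voxels."""
    return make_microtubule_map(mt_params, 8.0, (48, 48, 48))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def correlate(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=np.float64) - np.mean(a)
    b = np.asarray(b, dtype=np.float64) - np.mean(b)
    return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))
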