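import numpy as np
import pytest

from vesselperm import ScanProtocol, population_aif
from vesselperm.synthetic import PhantomTruth, RegionTruth, generate_phantom


@pytest.fixture(scope="session")
def protocol():
    return ScanProtocol()


@pytest.fixture(scope="session")
def default_aif(protocol):
    return population_aif(protocol.times)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small noiseless phantom with lesion / mirror / background + sinus."""
    return generate_phantom(seed=1, grid_shape=(8, 8, 2), snr=None)


def lesion_phantom(ktrans: float, seed: int, snr: float | None = 50.0,
                   n_voxels: int = 200):
    """Uniform single-region phantom with ``n_voxels`` lesion voxels."""
    truth = PhantomTruth((RegionTruth(1, "lesion", 1000.0, ktrans, 0.2, 0.02),))
    assert n_voxels % 10 == 0
    return generate_phantom(
        seed=seed, truth=truth, grid_shape=(n_voxels // 10, 10, 1),
        snr=snr, include_sinus=False,
    )
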