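import warnings

import numpy as np
import pytest

from glioquant import default_protocol
from glioquant.aif import AIFModel
from glioquant.synthetic import CohortSpec, PhantomSpec, simulate_cohort, simulate_dwi

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def aif():
    return AIFModel()


@pytest.fixture(scope="session")
def noiseless_dwi(protocol):
    """500-voxel noiseless DWI phantom with its ground truth."""
    spec = PhantomSpec(shape=(10, 10, 5), noise_sigma=0.0, seed=1)
    series, truth = simulate_dwi(spec, protocol)
    return spec, series, truth


@pytest.fixture(scope="session")
def default_cohort():
    """81-patient synthetic cohort with the default case mix."""
    return simulate_cohort(CohortSpec(seed=5))
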