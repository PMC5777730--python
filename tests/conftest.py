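import numpy as np
import pytest

from kinomeflow import GroundTruth
from kinomeflow.synthetic_data import make_layout, simulate_intensities


@pytest.fixture
def small_layout():
    return make_layout(10, 3, kinase_annotation_density=0.5, seed=11)


@pytest.fixture
def noisy_chip_pair(small_layout):
    """One control + one experimental chip, CV 10%, one planted 2x effect."""
    truth = GroundTruth(
        substrate_effects={"pep0003": 2.0},
        unreliable_substrates=frozenset({"pep0007"}),
        noise_cv=0.10,
        seed=5,
    )
    controls, experimentals = simulate_intensities(small_layout, truth)
    return truth, controls, experimentals


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
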