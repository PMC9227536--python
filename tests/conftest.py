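import numpy as np
import pytest

from pbpkcat.studies import build_species_model


@pytest.fixture(scope="session")
def rat_model():
    return build_species_model("rat")


@pytest.fixture(scope="session")
def mouse_model():
    return build_species_model("mouse")


@pytest.fixture(scope="session")
def dog_model():
    return build_species_model("dog")


@pytest.fixture(scope="session")
def human_model():
    return build_species_model("human")


@pytest.fixture
def iv_grid():
    """Time grid resolving the initial venous mixing spike after a bolus."""
    def make(t_end: float, n: int = 1000) -> np.ndarray:
        return np.unique(np.concatenate([[0.0], np.geomspace(1e-4, t_end, n)]))
    return make
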