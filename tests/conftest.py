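import numpy as np
import pytest

from nanofork import workflows
from nanofork.pore_model import default_pore_model


@pytest.fixture(scope="session")
def pore_model():
    return default_pore_model()


@pytest.fixture(scope="session")
def trained_detect(pore_model):
    """Detection network trained on the standard 0%/80% cohort (fixed seed).

    Session-scoped because training takes minutes; every test that needs a
    trained detector shares this model.
    """
    model, _history = workflows.train_detection_model(seed=1, pore_model=pore_model)
    return model


@pytest.fixture(scope="session")
def trained_forks(pore_model):
    """Fork-direction network trained on both labelling protocols (fixed seed)."""
    model, _history = workflows.train_fork_model(seed=2, pore_model=pore_model)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
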