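import numpy as np
import pytest

from chromatone.matching import INTERVAL_CLASSES, build_pair_table
from chromatone.ratings import attribute_vectors
from chromatone.synthdata import GeneratorConfig, generate_all


@pytest.fixture(scope="session")
def study():
    """One synthetic study at the default configuration, seed-fixed."""
    return generate_all(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def F(study):
    return attribute_vectors(study["ratings"])


@pytest.fixture(scope="session")
def pair_tables(study, F):
    return {
        cls: build_pair_table(study["selections"], cls, F, study["stimuli"])
        for cls in INTERVAL_CLASSES
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
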