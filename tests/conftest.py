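import numpy as np
import pytest

from seednet import make_planted_truth, generate_mirna_reference
from seednet.simulate import PlantedTruth


@pytest.fixture(scope="session")
def truth():
    """Default planted study: 9 down / 3 up miRNAs, |log2 effect| = 2."""
    return make_planted_truth(seed=11)


@pytest.fixture(scope="session")
def null_truth():
    """No planted effects at all."""
    return PlantedTruth(de_mirnas=(), target_map={}, enriched_terms=(), seed=11)


@pytest.fixture(scope="session")
def reference(truth):
    """Mature reference carrying all planted miRNAs plus 20 per species."""
    named = [(m, sp) for m, sp, _ in truth.de_mirnas]
    return generate_mirna_reference(20, seed=11, named=named)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
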