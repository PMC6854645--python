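import numpy as np
import pytest

from droughtleaf.synthetic_data import SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_params():
    return SimulationParams(seed=7, n_base=30, n_transcripts=200, n_de=20)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
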