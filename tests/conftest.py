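import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

from dimorph import ModelParams, MutationModel, PopulationState  # noqa: E402


@pytest.fixture
def params():
    """Default study conditions: N=1000, VS=2N (delta = 1), symmetric
    selection on the sexes."""
    return ModelParams(N=1000, U=0.0134)


@pytest.fixture
def infinitesimal():
    return MutationModel(mean_sq_magnitude=1.0, shared_fraction=0.5)


@pytest.fixture
def multigenic():
    return MutationModel(mean_sq_magnitude=16.0, shared_fraction=0.95)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def one_allele_state():
    """A single shared allele at x = 0.25 with unit effect in both sexes."""
    return PopulationState(af=[1.0], am=[1.0], x=[0.25])


def make_state(af, am, x, F_f=0.0, F_m=0.0, generation=0):
    return PopulationState(af=np.asarray(af, float), am=np.asarray(am, float),
                           x=np.asarray(x, float), F_f=F_f, F_m=F_m,
                           generation=generation)


@pytest.fixture
def gamma_sym():
    return 1.0 / math.sqrt(2.0)
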