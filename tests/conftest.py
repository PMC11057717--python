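import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from rgcsurprise import (
    BeliefPrior,
    CellModel,
    EncoderParams,
    MarkovParams,
    generate_condition_blocks,
)


@pytest.fixture(scope="session")
def short_stimulus():
    """~1.5 minutes of the three-condition stimulus (750 bins)."""
    return generate_condition_blocks(minutes_per_block=0.5, seed=101)


@pytest.fixture(scope="session")
def random_history():
    return np.random.default_rng(7).integers(0, 2, size=400)


@pytest.fixture
def weak_prior():
    # low-confidence prior: strength ~ e^2.8 per context, mean 1/2
    return BeliefPrior(alpha0={0: 8.0, 1: 8.0}, beta0={0: 8.0, 1: 8.0}, eta=0.2)


@pytest.fixture
def weak_adaptive_cell(weak_prior):
    return CellModel(belief=weak_prior, encoder=EncoderParams(a=2.0, b=-1.0))


@pytest.fixture
def fixed_cell():
    return CellModel(
        belief=MarkovParams(order=1, theta={0: 0.3, 1: 0.8}),
        encoder=EncoderParams(a=2.0, b=-1.0),
    )


@pytest.fixture
def markov2_cell():
    theta = {(0, 0): 0.2, (0, 1): 0.7, (1, 0): 0.35, (1, 1): 0.85}
    return CellModel(
        belief=MarkovParams(order=2, theta=theta),
        encoder=EncoderParams(a=2.0, b=-1.0),
    )
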