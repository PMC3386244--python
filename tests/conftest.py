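import numpy as np
import pytest

from introsim import ExperimentDesign, SelectionParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture
def default_design():
    return ExperimentDesign()


@pytest.fixture
def small_design():
    return ExperimentDesign(
        n_males=30,
        n_females=30,
        n_generations=8,
        sample_generations=(4, 8),
        sample_males=5,
        sample_females=5,
        n_replicates=2,
    )


@pytest.fixture
def neutral_params():
    return SelectionParams(s=0.0, h=0.5, c=0.0)
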