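import numpy as np
import pytest

from effortalloc import Condition, ParameterSet, design_conditions


@pytest.fixture(scope="session")
def placebo_truth() -> ParameterSet:
    """Winning-model parameters at the placebo group means."""
    return ParameterSet(Sem=0.16, Srm=0.37, Ai=0.15, Sed=0.021, Sri=0.086)


@pytest.fixture(scope="session")
def conditions() -> list[Condition]:
    return design_conditions()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
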