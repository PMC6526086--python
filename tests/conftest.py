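import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from fdagof import Domain, FunctionalSample, SimulationDesign, SubjectRecord, simulate_dataset


@pytest.fixture
def tiny_sample() -> FunctionalSample:
    """Two subjects, irregular design, hand-written values."""
    return FunctionalSample(
        [
            SubjectRecord("a", [-0.5, 0.0, 0.75], [1.0, -0.2, 0.4]),
            SubjectRecord("b", [-1.0, 1.0], [0.3, 0.9]),
        ],
        Domain(-1.0, 1.0),
    )


@pytest.fixture
def null_sample() -> FunctionalSample:
    """Moderate dataset from the null design (Delta = 0)."""
    return simulate_dataset(SimulationDesign(n=100, m=20, seed=123))
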