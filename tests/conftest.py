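import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from coarsemi.coarse import AnalysisDataset, CoarseValue, SampleSpace
from coarsemi.simulate import SPACE

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def space():
    return SampleSpace(("a", "b", "c"))


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def cv(*labels):
    return CoarseValue(labels, SPACE)


@pytest.fixture
def small_dataset():
    """10-row continuous dataset with observed, coarsened and missing rows."""
    x = [cv("a"), cv("b"), cv("c"), cv("b", "c"), cv("b", "c"),
         cv("a", "b", "c"), cv("a"), cv("b"), cv("c"), cv("a", "b", "c")]
    rng = np.random.default_rng(7)
    z = pd.DataFrame({"z1": rng.normal(size=10), "z2": rng.normal(size=10)})
    y = rng.normal(size=10)
    return AnalysisDataset(x=x, z=z, outcome_kind="continuous", y=y)
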