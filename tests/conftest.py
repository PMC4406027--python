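import numpy as np
import pytest

from mcda_weights import CriteriaHierarchy
from mcda_weights.hierarchy import Criterion


@pytest.fixture(scope="session")
def evidem():
    """The bundled 14-criterion hierarchy."""
    return CriteriaHierarchy.default()


@pytest.fixture(scope="session")
def two_leaf():
    """Minimal hierarchy: one category of two criteria."""
    return CriteriaHierarchy(
        (
            Criterion("A1", "first", "Only"),
            Criterion("A2", "second", "Only"),
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
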