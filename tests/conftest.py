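import numpy as np
import pandas as pd
import pytest

from emfkit.design import StudyDesign
from emfkit.emf import FunctionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_design():
    """A reduced design for fast community-level tests."""
    return StudyDesign(
        n_taxa_pro=60, n_taxa_fun=50, n_indicator_planted=6, depth=5000, seed=7
    )


@pytest.fixture
def toy_functions():
    """3 plots × 2 functions used by the hand-computed EMF examples."""
    values = pd.DataFrame(
        [[10.0, 1.0], [5.0, 1.0], [0.0, 1.0]],
        index=["p1", "p2", "p3"],
        columns=["PP_1", "C_1"],
    )
    return FunctionMatrix(values=values, category={"PP_1": "PP", "C_1": "C"})
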