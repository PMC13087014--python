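import numpy as np
import pytest

from braintx import default_atlas, make_atlas, simulate_expression
from braintx.config import DEFAULT_GENE_PANEL


@pytest.fixture(scope="session")
def atlas58():
    """The default 58-region atlas (41 cortical, 6 subcortical, 9 cerebellar,
    2 brainstem)."""
    return default_atlas(seed=1)


@pytest.fixture(scope="session")
def small_atlas():
    return make_atlas(8, 2, 2, 1, seed=7)


@pytest.fixture(scope="session")
def expression12(atlas58):
    """Default 12-gene synthetic expression panel on the 58-region atlas."""
    return simulate_expression(atlas58, DEFAULT_GENE_PANEL, length_scale=40.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
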