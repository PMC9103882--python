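import numpy as np
import pytest
from hypothesis import settings

import mcdock as m

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted12():
    """The (12 atoms, 2 torsions) planted complex used across the suite."""
    return m.make_planted_complex(12, 2, seed=1, check=False)


@pytest.fixture(scope="session")
def prep12(planted12):
    """(receptor, flat_ligand, grid_cache) of the planted (12, 2) complex."""
    return m.prepare(planted12)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
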