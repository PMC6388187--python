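import numpy as np
import pytest

import aquagrade as aq


@pytest.fixture(scope="session")
def standards() -> aq.StandardsTable:
    return aq.builtin_graded_standard()


@pytest.fixture(scope="session")
def fixtures() -> aq.FixtureSet:
    return aq.load_fixtures()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture()
def six_well_panel():
    """A small deterministic synthetic panel with all 16 indicators."""
    return aq.generate_panel(aq.default_config(n_wells=6, seed=7))
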