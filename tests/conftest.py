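import numpy as np
import pytest

from micromediate import generate_study, preset


@pytest.fixture(scope="session")
def mixed_small():
    """A small mixed-scenario study (mediation + direct effect)."""
    cfg = preset("mixed", n_per_group=80, n_taxa=6, seed=11)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def mixed_medium():
    """A mid-sized mixed-scenario study for fit-quality checks."""
    cfg = preset("mixed", n_per_group=200, n_taxa=8, seed=5)
    return generate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
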