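import logging

import pytest

from winterq import SyntheticConfig

# keep expected-diagnostic log noise out of test output
logging.getLogger("winterq").setLevel(logging.ERROR)


@pytest.fixture
def default_cfg():
    """The study design: 12 fish, 14->2.5 degC, passive Q10 2.5."""
    return SyntheticConfig(seed=1)


@pytest.fixture
def small_cfg():
    """Scaled-down design for fast structural tests."""
    return SyntheticConfig(n_fish=3, intervals_per_phase=6, seed=7)
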