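import numpy as np
import pytest

from abatune import DEFAULT_MOTIF_TEXT, parse_motif


@pytest.fixture(scope="session")
def aba_pattern():
    """The four-anchor ABA-binding signature used as the default motif."""
    return parse_motif(DEFAULT_MOTIF_TEXT)


@pytest.fixture
def rng():
    return np.random.default_rng(20260420)
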