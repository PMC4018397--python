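import numpy as np
import pytest

from capmir.io import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20140512)


@pytest.fixture
def mir1():
    """The muscle-specific miR-1 mature sequence."""
    return SequenceRecord("chi-miR-1", "TGGAATGTAAAGAAGTATGTAT")
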