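import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make reference.py importable

from agcp import TwoSampleMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20180525)


@pytest.fixture
def small_data(rng):
    """A 6+6 sample, 8-variable continuous dataset."""
    return TwoSampleMatrix(rng.standard_normal((6, 8)),
                           rng.standard_normal((6, 8)))
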