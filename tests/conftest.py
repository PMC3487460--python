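import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles

from cyanoflux import synthetic


@pytest.fixture(scope="session")
def mini_phototroph():
    """The fixed 16-reaction phototroph fixture with its ground truth."""
    return synthetic.make_mini_phototroph(seed=0)


@pytest.fixture(scope="session")
def branched():
    return synthetic.make_branched_network(seed=7)
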