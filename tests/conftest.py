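import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose _oracles to test modules

from treelen.cost_model import preset

SCHEME_NAMES = ["simple1", "simple2", "affine", "mp"]


@pytest.fixture(params=SCHEME_NAMES)
def any_scheme(request):
    return preset(request.param)


@pytest.fixture
def simple1():
    return preset("simple1")


@pytest.fixture
def affine():
    return preset("affine")


@pytest.fixture
def mp():
    return preset("mp")


@pytest.fixture
def pyrng():
    return random.Random(0xC0FFEE)
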