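import pytest

from ovipass.datasets import SIX_LINEAGE_PROFILE
from ovipass.profiles import normalize


@pytest.fixture
def six_lineage():
    """Six-lineage community with a 69-fold abundance range, rarest 0.9%."""
    return SIX_LINEAGE_PROFILE


@pytest.fixture
def even_pair():
    return normalize([1, 1])
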