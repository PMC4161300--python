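import pytest

from dmisnowball import presets
from dmisnowball.tables import RunConfig


@pytest.fixture
def solanum_tree():
    """Ultrametric study tree with early fraction 0.251."""
    return presets.SOLANUM_TREE


@pytest.fixture
def solanum_inventory():
    return presets.solanum_inventory()


@pytest.fixture
def config():
    return RunConfig(seed=7)
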