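import pytest

from pufapath.enzymes import load_activity_panels
from pufapath.pathway import build_graph


@pytest.fixture(scope="session")
def panels():
    return load_activity_panels()


@pytest.fixture(scope="session")
def default_graph(panels):
    return build_graph(panels)
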