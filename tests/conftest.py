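import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helper module

from biopbpk import compiler, fixtures
from biopbpk.platform import build_whole_body


@pytest.fixture(scope="session")
def toy_graphs():
    return fixtures.toy_models()


@pytest.fixture(scope="session")
def toy_compiled(toy_graphs):
    return {name: compiler.compile_graph(g) for name, g in toy_graphs.items()}


@pytest.fixture(scope="session")
def human_physiology():
    return fixtures.synth_physiology()["physiology"]["human"]


@pytest.fixture(scope="session")
def whole_body_graph(human_physiology):
    return build_whole_body(human_physiology)


@pytest.fixture(scope="session")
def whole_body_model(whole_body_graph):
    return compiler.compile_graph(whole_body_graph)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)


def random_point(model, rng, scale=10.0):
    """Random state/parameter environment for one compiled model."""
    y = rng.uniform(0.0, scale, model.n_states)
    p = rng.uniform(0.1, 2.0, len(model.parameter_names))
    return y, p
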