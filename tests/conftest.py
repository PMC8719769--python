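import numpy as np
import pytest

from davsnet.graph import TensorShape, build_davsnet_graph, count_parameters, propagate_shapes


@pytest.fixture(scope="session")
def canonical_graph():
    return build_davsnet_graph(TensorShape(640, 640, 3))


@pytest.fixture(scope="session")
def canonical_shapes(canonical_graph):
    return propagate_shapes(canonical_graph)


@pytest.fixture(scope="session")
def canonical_audit(canonical_graph, canonical_shapes):
    return count_parameters(canonical_graph, canonical_shapes)


@pytest.fixture(scope="session")
def tiny_samples():
    """Four small synthetic fundus samples shared across test modules."""
    from davsnet.synthetic import generate_sample

    return [generate_sample(size=(64, 64), seed=s) for s in range(4)]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
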