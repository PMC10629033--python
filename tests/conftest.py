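import numpy as np
import pytest

from layeralign import (
    EdgeRecord,
    EmbeddingConfig,
    GeneratorConfig,
    MultilayerNetwork,
    generate_multilayer,
)

# small, fast embedding settings used throughout the unit tests
FAST_EMBED = EmbeddingConfig(
    dimensions=24, num_walks=5, walk_length=20, window=3, epochs=2, seed=0
)


@pytest.fixture
def toy_network() -> MultilayerNetwork:
    """Two intralayer edges (layers 1, 2) and one interlayer edge (id 3)."""
    return MultilayerNetwork(
        edges=frozenset(
            {EdgeRecord("a", "b", 1), EdgeRecord("c", "d", 2), EdgeRecord("a", "c", 3)}
        ),
        layer_ids=(1, 2),
        interlayer_id=3,
    )


@pytest.fixture(scope="session")
def benchmark_network():
    """One generated two-layer benchmark network plus its identity truth."""
    return generate_multilayer(GeneratorConfig(seed=42))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
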