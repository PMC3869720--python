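import numpy as np
import pytest

from forestspat import Window, default_forest_spec, generate, reference_stem_map


@pytest.fixture(scope="session")
def window():
    return Window(800.0, 320.0)


@pytest.fixture(scope="session")
def square():
    return Window(100.0, 100.0)


@pytest.fixture(scope="session")
def desk_map():
    """One 10%-scale synthetic plot shared across tests."""
    return generate(default_forest_spec(0.1), seed=42)


@pytest.fixture(scope="session")
def reference_map():
    """The deterministic census-reproducing stem map."""
    return reference_stem_map()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
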