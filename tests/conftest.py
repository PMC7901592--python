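import numpy as np
import pytest
from hypothesis import settings

from embedlex import EmbeddingSource

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def tiny_source() -> EmbeddingSource:
    """Three 2-d keys: a=(1,0), b=(0.9,0.1), c=(0,1)."""
    return EmbeddingSource(
        name="tiny",
        vocabulary=["a", "b", "c"],
        vectors=np.array([[1.0, 0.0], [0.9, 0.1], [0.0, 1.0]]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
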