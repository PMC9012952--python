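import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_tucker2(rng):
    """A small exact Tucker-2 instance: (X, G, S, B) with orthonormal factors."""
    V, T, K, N = 30, 12, 3, 4
    S, _ = np.linalg.qr(rng.normal(size=(V, N)))
    B, _ = np.linalg.qr(rng.normal(size=(T, N)))
    G = rng.normal(size=(N, N, K))
    from slctkd.tensor_ops import tucker2_reconstruct

    X = tucker2_reconstruct(G, S, B)
    return X, G, S, B
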