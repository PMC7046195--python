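import numpy as np
import pytest

from revlearn.task import generate_block


@pytest.fixture(scope="session")
def det_block():
    return generate_block("deterministic", 88, 40, seed=11)


@pytest.fixture(scope="session")
def prob_block():
    return generate_block("probabilistic", 88, 48, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def toy_block(T: int, seed: int):
    """Tiny random cue/target/response triple for oracle comparisons."""
    r = np.random.default_rng(seed)
    return (
        r.integers(0, 2, (T, 3)).astype(np.int8),
        r.integers(0, 2, T).astype(np.int8),
        r.integers(0, 2, T).astype(np.int8),
    )
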