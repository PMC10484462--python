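import numpy as np
import pytest

from btspmap import MapParams, generate_environment_sequence, recurrent_learn


@pytest.fixture(scope="session")
def cosine_params():
    return MapParams.cosine(0.3, 0.3)


@pytest.fixture(scope="session")
def small_learned_system(cosine_params):
    """One modest learned recurrent system reused across read-only tests
    (N=32 slots, M=4 cells per slot, s=0.5, 60 environments)."""
    seq = generate_environment_sequence(N=32, M=4, s=0.5, n=60, seed=1234)
    rng = np.random.default_rng(99)
    W0 = rng.random((seq.n_cells, seq.n_cells))
    W, _ = recurrent_learn(W0, seq, cosine_params)
    return W, seq
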