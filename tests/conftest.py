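import numpy as np
import pytest

from ciphergeno import CkksContext, small_test_params


@pytest.fixture(scope="session")
def ctx():
    """Small-N context (N=64): same code paths as production, millisecond ops."""
    return CkksContext(small_test_params())


@pytest.fixture(scope="session")
def bundle(ctx):
    """Keys with every rotation step, shared across the suite."""
    return ctx.keygen(seed=1234, rotation_steps=tuple(range(1, ctx.slots)))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
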