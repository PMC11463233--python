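import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def derived_seed(*key: int) -> int:
    """Deterministic child seed below 2^31 from small integer keys."""
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0] % (2**31))
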