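import numpy as np
import pytest

from edgewalk.first_p_net import oracle_first_point, oracle_prob_map
from edgewalk.synthetic import generate_phantom, sample_spec


def make_phantom_set(n: int, seed: int, size: int = 96):
    """n (image, mask, contour, oracle prob map) tuples with derived seeds."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        s = int(rng.integers(2**31))
        img, mask, con = generate_phantom(sample_spec(np.random.default_rng(s), size=size, seed=s))
        out.append((img, mask, con, oracle_prob_map(con, size)))
    return out


@pytest.fixture(scope="session")
def phantom_96():
    from edgewalk.synthetic import PhantomSpec

    return generate_phantom(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def phantom_set_small():
    return make_phantom_set(5, seed=900)
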