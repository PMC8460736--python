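import numpy as np
import pytest
from hypothesis import settings

import kptmpred as kp
from kptmpred.alphabet import ALPHABET

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_windows(rng, n, zeta, alphabet=ALPHABET):
    """K-centered windows with uniformly random flanks."""
    width = 2 * zeta + 1
    out = []
    for _ in range(n):
        chars = rng.choice(list(alphabet), size=width)
        chars[zeta] = "K"
        out.append("".join(chars))
    return out


@pytest.fixture(scope="session")
def small_corpus():
    """A modest synthetic corpus shared by read-only tests."""
    data = kp.generate(kp.GeneratorConfig(n_proteins=40, seed=11))
    dataset = kp.build_benchmark(data.proteins, data.annotations, zeta=24)
    return data, dataset
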