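import numpy as np
import pytest

from nidm import ParamSet, SimNetwork


@pytest.fixture
def p() -> ParamSet:
    return ParamSet()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def triangle() -> SimNetwork:
    return SimNetwork(3, edges=[(0, 1), (1, 2), (0, 2)])


def random_network(rng: np.random.Generator, n: int, p_edge: float = 0.3) -> SimNetwork:
    net = SimNetwork(n)
    for u in range(n):
        for v in range(u + 1, n):
            if rng.random() < p_edge:
                net.add_edge(u, v)
    return net
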