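import numpy as np
import pytest

from mirlight import LuminanceImage, ModelConfig
from mirlight.crf import IlluminanceLevels


@pytest.fixture(scope="session")
def small_levels():
    """A coarse 5-level grid over a realistic indoor range, for enumeration."""
    return IlluminanceLevels.log_spaced(K=5, e_min=20, e_max=500)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def modified_cfg():
    return ModelConfig.preset("modified")


@pytest.fixture(scope="session")
def original_cfg():
    return ModelConfig.preset("original")


def exhaustive_map_energy(graph) -> float:
    """Independent exhaustive MAP oracle for tiny factor graphs.

    Enumerates every labeling and evaluates the energy directly from the
    model definition (unary tables, w·(Δln e)^p pairwise terms, and the
    corner rule for 2×2 blocks), vectorized over all K^N configurations.
    """
    K, N = graph.levels.K, graph.n_variables
    assert K ** N <= 4_000_000, "oracle restricted to tiny graphs"
    A = np.indices((K,) * N).reshape(N, -1)
    E = np.zeros(A.shape[1])
    for i in range(N):
        E += graph.unary[i, A[i]]
    d = graph.levels.delta
    for p in range(graph.n_pairs):
        diff = np.abs(A[graph.pair_a[p]] - A[graph.pair_b[p]])
        E += graph.pair_w[p] * (d * diff) ** graph.pairwise_power
    for tl, tr, bl, br in graph.cliques:
        top = A[tl] != A[tr]
        bottom = A[bl] != A[br]
        left = A[tl] != A[bl]
        right = A[tr] != A[br]
        cnt = top.astype(np.int64) + bottom + left + right
        free = (cnt == 0) | (cnt == 4) | ((cnt == 2) & ((top & bottom) | (left & right)))
        E += graph.w_straight * ~free
    return float(E.min())


@pytest.fixture(scope="session")
def map_oracle():
    return exhaustive_map_energy


@pytest.fixture()
def tiny_image(rng):
    return LuminanceImage(rng.uniform(5, 70, size=(3, 3)))
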