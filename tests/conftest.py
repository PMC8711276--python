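import numpy as np
import pytest

from carsdm import LandscapeSpec, build_neighbor_graph, make_landscape


@pytest.fixture(scope="session")
def small_stack():
    return make_landscape(LandscapeSpec(12, 15, 3, autocorr_range=2.0, seed=7))


@pytest.fixture(scope="session")
def small_graph(small_stack):
    return build_neighbor_graph(small_stack)


def moran_i(values: np.ndarray) -> float:
    """Lag-1 (rook) Moran's I of a 2-D field — independent oracle."""
    z = values - values.mean()
    num = 0.0
    w_sum = 0.0
    nr, nc = z.shape
    for dr, dc in ((0, 1), (1, 0)):
        a = z[: nr - dr, : nc - dc]
        b = z[dr:, dc:]
        num += 2.0 * float((a * b).sum())
        w_sum += 2.0 * a.size
    return (z.size / w_sum) * num / float((z**2).sum())
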