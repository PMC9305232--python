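import numpy as np
import pytest

from myconet import SyntheticNetworkParams, generate_network


@pytest.fixture(scope="session")
def default_params() -> SyntheticNetworkParams:
    return SyntheticNetworkParams(rng_seed=42)


@pytest.fixture(scope="session")
def small_network():
    """A quick-to-generate 128-px synthetic network for unit tests."""
    return generate_network(
        SyntheticNetworkParams(image_size_px=128, n_seeds=6, rng_seed=11)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def naive_box_count(mask: np.ndarray, sizes, offset=(0, 0)) -> list[int]:
    """Independent per-box double-loop oracle for box counting."""
    h, w = mask.shape
    out = []
    for s in sizes:
        r_edges = sorted({0, *range(offset[0] % s, h, s)})
        c_edges = sorted({0, *range(offset[1] % s, w, s)})
        n = 0
        for i, r in enumerate(r_edges):
            r1 = r_edges[i + 1] if i + 1 < len(r_edges) else h
            for j, c in enumerate(c_edges):
                c1 = c_edges[j + 1] if j + 1 < len(c_edges) else w
                if mask[r:r1, c:c1].any():
                    n += 1
        out.append(n)
    return out
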