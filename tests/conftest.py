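import numpy as np
import pytest

from nodulekit.boxgeom import Box


def random_box(rng: np.random.Generator, span: float = 10.0,
               min_side: float = 0.3) -> Box:
    """A random valid, non-degenerate box inside [0, span]^2."""
    x1 = rng.uniform(0, span - min_side)
    y1 = rng.uniform(0, span - min_side)
    w = rng.uniform(min_side, span - x1)
    h = rng.uniform(min_side, span - y1)
    return Box(x1, y1, x1 + w, y1 + h)


def random_box_pairs(seed: int, n: int, span: float = 10.0) -> list[tuple[Box, Box]]:
    rng = np.random.default_rng(seed)
    return [(random_box(rng, span), random_box(rng, span)) for _ in range(n)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
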