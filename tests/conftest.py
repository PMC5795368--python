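import numpy as np
import pytest

from pairvox import AnchorMap, Hyperparams, build_grid


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def grid_5x5():
    """20x20 frame, 4x4 superpixels, eta=1: the 25-anchor-cell geometry."""
    return build_grid(20, 20, 4, 4, 1, 1)


@pytest.fixture
def anchors_5x5(grid_5x5):
    return AnchorMap(grid_5x5)


@pytest.fixture
def hp():
    return Hyperparams()


def random_pair(rng, H, W, lo=0.0, hi=100.0):
    """A pair of independent rough random CIELAB frames."""
    return rng.uniform(lo, hi, (H, W, 3)), rng.uniform(lo, hi, (H, W, 3))
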