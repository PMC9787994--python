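import numpy as np
import pandas as pd
import pytest

from canopybird.diversity import TraitSpace
from canopybird.synthetic import LandscapeConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_landscape_config():
    """A landscape small enough for fast tests but large enough to group."""
    return LandscapeConfig(n_compartments=400, mean_area=0.4, area_sd=0.4, seed=3)


def make_space(points, index=None) -> TraitSpace:
    """Trait space directly from coordinates (identity embedding)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    index = index or [f"s{i}" for i in range(len(points))]
    coords = pd.DataFrame(
        points, index=index, columns=[f"pc{j + 1}" for j in range(points.shape[1])]
    )
    return TraitSpace(
        coords=coords, quality=1.0, sqrt_corrected=False, eigenvalues=np.array([])
    )


@pytest.fixture
def unit_square_space():
    return make_space([[0, 0], [1, 0], [0, 1], [1, 1]])
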