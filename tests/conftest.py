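import numpy as np
import pytest

from lsatrace.phantom import (make_straight_tube_phantom, make_y_phantom,
                              render_phantom)
from lsatrace.tracking import StepForestConfig, make_step_training_data, train_step_forest


@pytest.fixture(scope="session")
def straight_tube():
    """Noise-free straight tube (r = 0.3 mm, 0.1 mm spacing) with ground truth."""
    spec = make_straight_tube_phantom(radius=0.3, spacing=0.1, shape=(50, 50, 50))
    vol, gt = render_phantom(spec)
    return spec, vol, gt


@pytest.fixture(scope="session")
def y_phantom():
    """Noise-free Y junction at the default 40-degree branching angle."""
    spec = make_y_phantom()
    vol, gt = render_phantom(spec)
    return spec, vol, gt


@pytest.fixture(scope="session")
def straight_forest(straight_tube):
    """Step forest trained on the straight-tube phantom (small, seeded)."""
    _spec, vol, gt = straight_tube
    X, y = make_step_training_data(vol, gt, 250, 250, seed=0)
    return train_step_forest((X, y), StepForestConfig(n_trees=100, seed=0))


@pytest.fixture(scope="session")
def y_forest(y_phantom):
    _spec, vol, gt = y_phantom
    X, y = make_step_training_data(vol, gt, 250, 250, seed=0)
    return train_step_forest((X, y), StepForestConfig(n_trees=100, seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
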