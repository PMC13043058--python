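import numpy as np
import pytest

from latentsr.maze_env import build_gridworld, build_tolman_maze, load_maze_text
from latentsr.state_features import onehot_features


@pytest.fixture(scope="session")
def grid10():
    return build_gridworld(10, 10)


@pytest.fixture(scope="session")
def grid3():
    return build_gridworld(3, 3)


@pytest.fixture(scope="session")
def corridor4():
    """Four-state linear track: start at one end, goal at the other."""
    return load_maze_text("S..G", name="corridor4", max_steps=50)


@pytest.fixture(scope="session")
def tolman72():
    return build_tolman_maze("onehot-72")


@pytest.fixture(scope="session")
def tolman30():
    return build_tolman_maze("image-30")


@pytest.fixture(scope="session")
def grid10_onehot(grid10):
    return onehot_features(grid10)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
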