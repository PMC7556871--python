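import numpy as np
import pytest

from saltadyn.tracks import Trajectory


@pytest.fixture
def random_track():
    """Factory for random-walk trajectories with a seeded generator."""

    def make(n: int = 50, seed: int = 0, cell_id: str = "rand") -> Trajectory:
        rng = np.random.default_rng(seed)
        t = np.cumsum(rng.uniform(10.0, 40.0, n))
        xy = np.cumsum(rng.normal(0.0, 1.5, (n, 2)), axis=0)
        return Trajectory(cell_id=cell_id, t=t, x=xy[:, 0], y=xy[:, 1])

    return make
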