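import numpy as np
import pytest

import xfaces as xf


@pytest.fixture(scope="session")
def prototype_set() -> xf.PrototypeSet:
    """Default noiseless synthetic prototypes (43 markers, 5 s at 30 Hz)."""
    return xf.gen_prototype_trajectories(xf.PrototypeSpec(), seed=0)


@pytest.fixture(scope="session")
def style_grid(prototype_set) -> xf.StyleGrid:
    return xf.build_style_grid(prototype_set.prototypes, steps_per_axis=5)


@pytest.fixture(scope="session")
def lattice_points(style_grid):
    return sorted({(p.e, p.s) for p in style_grid.points})


@pytest.fixture(scope="session")
def single_condition_responses(lattice_points):
    """20 participants × 10 reps on the 25-cell lattice, one condition."""
    obs = xf.ObserverConfig(seed=11, conditions=(("monkey", 0),))
    return xf.gen_observer_responses(lattice_points, obs)


def make_linear_trajectory(n_frames=10, n_markers=4, velocity=(1.0, 0.0, 0.0), rate=30.0):
    """Markers on a line, all translating at constant velocity."""
    base = np.stack(
        [np.linspace(0, 10, n_markers), np.zeros(n_markers), np.zeros(n_markers)], axis=1
    )
    v = np.asarray(velocity)
    pos = base[None] + np.arange(n_frames)[:, None, None] * v[None, None, :]
    return xf.MarkerTrajectory(pos, frame_rate=rate)
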