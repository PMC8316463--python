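import numpy as np
import pandas as pd
import pytest

from pathplan import layout as lay
from pathplan import simulate as sim
from pathplan.gaze import AoiRegions


@pytest.fixture(scope="session")
def regions_by_condition():
    return {
        cid: AoiRegions.from_layout(lay.build_layout(cid)) for cid in range(1, 9)
    }


@pytest.fixture(scope="session")
def small_params():
    return sim.SimParams(n_participants=3, n_trials_per_cell=1, seed=11)


@pytest.fixture(scope="session")
def small_trials(small_params):
    trials, _ = sim.generate_dataset(small_params)
    return trials


def make_gaze(points, dt=1.0 / 120.0):
    """Gaze frame from [(x, y), ...] at a uniform sampling interval."""
    if not points:
        return pd.DataFrame({"t_s": [], "x_cm": [], "y_cm": []})
    t = np.arange(len(points)) * dt
    xs, ys = zip(*points)
    return pd.DataFrame({"t_s": t, "x_cm": xs, "y_cm": ys})
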