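import numpy as np
import pandas as pd
import pytest

from flumetrack import sim


@pytest.fixture
def short_config():
    """A desk-scale treatment run: 30 s at 5 fps."""
    return sim.SimConfig(fps=5.0, duration_s=30.0, seed=11)


@pytest.fixture
def six_fish_truth():
    cfg = sim.SimConfig(n_fish=6, velocity_cm_s=20.0, fps=50.0, duration_s=20.0, seed=5)
    return sim.simulate_trial(cfg)


def make_truth(positions: np.ndarray, fps: float = 50.0, **cfg_kwargs) -> sim.TruthTrajectorySet:
    """Hand-built ground truth from a (frames, fish, 3) position array."""
    T = positions.shape[0]
    cfg = sim.SimConfig(n_fish=positions.shape[1], fps=fps, duration_s=T / fps,
                        **cfg_kwargs)
    return sim.TruthTrajectorySet(positions=np.asarray(positions, dtype=float), config=cfg)


def traj_frame(records) -> pd.DataFrame:
    """Trajectory table from (fish_id, frame, x, y[, z]) tuples."""
    cols = ["fish_id", "frame", "x_cm", "y_cm", "z_cm"]
    n = len(records[0])
    return pd.DataFrame(records, columns=cols[:n])
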