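import numpy as np
import pytest

from zebra3d import SimConfig, StimulusSchedule, simulate_trajectory


@pytest.fixture(scope="session")
def two_cycle_config() -> SimConfig:
    """Two QT/ES cycles with offset, dropout and a mid-recording LED flash."""
    return SimConfig(n_fish=2, fps=60.0,
                     schedule=StimulusSchedule.alternating(30.0, 30.0, 2),
                     lateral_frame_offset=17, dropout_rate=0.05,
                     led_on_frame=150, seed=11)


@pytest.fixture(scope="session")
def clean_config() -> SimConfig:
    """Single cycle, no dropout, no offset — for exact round trips."""
    return SimConfig(n_fish=1, fps=60.0,
                     schedule=StimulusSchedule.alternating(30.0, 30.0, 1),
                     lateral_frame_offset=0, dropout_rate=0.0,
                     led_on_frame=60, seed=7)


@pytest.fixture(scope="session")
def labelled_traj(clean_config):
    return simulate_trajectory(clean_config, 0)


def straight_line_segment(n=60, v=2.0, fps=60.0, z=5.0):
    """Constant-velocity horizontal path along x (helper, not a fixture)."""
    from zebra3d import Segment
    t = np.arange(n) / fps
    xyz = np.column_stack([v * t, np.zeros(n), np.full(n, z)])
    return Segment(fish_id=0, phase="QT", start_s=0.0,
                   duration_s=(n - 1) / fps, xyz=xyz, fps=fps)
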