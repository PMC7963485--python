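import numpy as np
import pandas as pd
import pytest

from xenassay.tracking import CalibratedScale, Trajectory


def trajectory_from_arrays(t, x_mm, y_mm, heading_deg, fps, px_per_mm=5.0,
                           valid=None):
    """Build a Trajectory directly from known kinematics (bypasses vision)."""
    n = len(t)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    df = pd.DataFrame({
        "frame": np.arange(n),
        "time_s": np.asarray(t, float),
        "x_mm": np.asarray(x_mm, float),
        "y_mm": np.asarray(y_mm, float),
        "heading_deg": np.asarray(heading_deg, float),
        "major_mm": np.full(n, 7.0),
        "minor_mm": np.full(n, 2.5),
        "valid": valid,
    })
    scale = CalibratedScale(px_per_mm=px_per_mm, dish_center_px=(150.0, 150.0),
                            dish_diameter_px=px_per_mm * 60.0)
    return Trajectory(frames=df, fps=fps, scale=scale)


def trajectory_from_truth(truth: pd.DataFrame, fps: float,
                          px_per_mm: float = 4.0) -> Trajectory:
    """Wrap a synthetic ground-truth table as a Trajectory."""
    return trajectory_from_arrays(truth["time_s"], truth["x_mm"],
                                  truth["y_mm"], truth["heading_deg"], fps,
                                  px_per_mm)


@pytest.fixture(scope="session")
def behavior_video():
    """One rendered escape video shared across tests (seed fixed)."""
    from xenassay.synthetic import BehaviorSimParams, EscapeParams, make_behavior_video

    params = BehaviorSimParams(seed=11, escape=EscapeParams(turn_deg=60.0))
    frames, truth, meta = make_behavior_video(params)
    return params, frames, truth, meta


@pytest.fixture(scope="session")
def small_stack():
    """One scaled-down two-channel stack with truth."""
    from xenassay.synthetic import StackSimParams, make_stack_pair

    params = StackSimParams(seed=7)
    pair, truth = make_stack_pair(params)
    return params, pair, truth
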