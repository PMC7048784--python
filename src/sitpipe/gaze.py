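"""Gaze-kinematics features from world-coordinate gaze-angle series.

Per axis (horizontal = ``gaze_angle_x``, vertical = ``gaze_angle_y``), four
features are computed over the retained frames: the mean angle, the mean
absolute deviation from the participant's own median angle (robust to
seating height/position), the mean gaze speed, and the mean gaze
acceleration.  Speeds are absolute first differences divided by the actual
timestamp difference; accelerations are the analogous differences of the
speed series.  Frame filtering can leave temporal holes, so differences are
only taken across consecutive frames whose gap does not exceed two nominal
frame periods — longer gaps break the differentiation chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .openface import FrameTable

AXES = {"horizontal": "gaze_angle_x", "vertical": "gaze_angle_y"}


@dataclass(frozen=True)
class AxisKinematics:
    mean_angle: float
    abs_dev_median: float
    mean_speed: float
    mean_accel: float


def _chain_diffs(theta: np.ndarray, t: np.ndarray, max_gap: float):
    """Finite differences |dx|/dt across pairs with dt <= max_gap.

    Returns (rates, midpoint_times, chain_ok) where chain_ok marks pairs
    usable for the next differentiation level (both endpoints in-chain).
    """
    dt = np.diff(t)
    ok = dt <= max_gap
    rates = np.abs(np.diff(theta)) / dt
    mid = (t[:-1] + t[1:]) / 2
    return rates[ok], mid[ok], ok


def gaze_kinematics(ft: FrameTable, nominal_fps: float | None = None) -> dict[str, AxisKinematics]:
    """Per-axis gaze kinematics; requires at least three usable frames.

    ``nominal_fps`` sets the nominal frame period for the gap rule; by
    default it is inferred from the median timestamp difference.
    """
    t = ft.timestamps
    if len(t) < 3:
        return {ax: AxisKinematics(np.nan, np.nan, np.nan, np.nan) for ax in AXES}
    period = 1.0 / nominal_fps if nominal_fps else float(np.median(np.diff(t)))
    max_gap = 2.0 * period

    out: dict[str, AxisKinematics] = {}
    for axis, col in AXES.items():
        theta = ft.frames[col].to_numpy(float)
        mean_angle = float(theta.mean())
        abs_dev = float(np.abs(theta - np.median(theta)).mean())

        speeds, t_mid, _ = _chain_diffs(theta, t, max_gap)
        mean_speed = float(speeds.mean()) if len(speeds) else np.nan
        if len(speeds) >= 2:
            # acceleration from consecutive speed samples; the same gap rule
            # applies to the speed-sample midpoints
            accels, _, _ = _chain_diffs(speeds, t_mid, max_gap)
            mean_accel = float(accels.mean()) if len(accels) else np.nan
        else:
            mean_accel = np.nan
        out[axis] = AxisKinematics(mean_angle, abs_dev, mean_speed, mean_accel)
    return out


def gaze_kinematics_table(ft: FrameTable, nominal_fps: float | None = None) -> pd.DataFrame:
    """Tidy per-axis kinematics: person_id, axis, and the four features."""
    kin = gaze_kinematics(ft, nominal_fps)
    rows = [
        (ft.person_id, ax, k.mean_angle, k.abs_dev_median, k.mean_speed, k.mean_accel)
        for ax, k in kin.items()
    ]
    return pd.DataFrame(
        rows,
        columns=["person_id", "axis", "mean_angle", "abs_dev_median", "mean_speed", "mean_accel"],
    )
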