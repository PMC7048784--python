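import numpy as np
import pandas as pd
import pytest

from sitpipe.openface import (
    AU_INTENSITY_COLS,
    AU_PRESENCE_COLS,
    INTENSITY_AUS,
    FrameTable,
)


def make_frame_table(
    person_id="p1",
    timestamps=None,
    confidence=None,
    success=None,
    intensities=None,
    presences=None,
    gaze_x=None,
    gaze_y=None,
) -> FrameTable:
    """Small hand-rolled frame table; unspecified channels are zero."""
    ts = np.asarray(timestamps if timestamps is not None else np.arange(10) / 30.0, float)
    n = len(ts)
    df = pd.DataFrame({"frame": np.arange(1, n + 1), "timestamp": ts})
    df["confidence"] = confidence if confidence is not None else np.full(n, 0.99)
    df["success"] = success if success is not None else np.ones(n, int)
    for au, col in zip(INTENSITY_AUS, AU_INTENSITY_COLS):
        df[col] = (intensities or {}).get(au, np.zeros(n))
    for au, col in zip(INTENSITY_AUS, AU_PRESENCE_COLS):
        df[col] = (presences or {}).get(au, np.zeros(n, int))
    df["gaze_angle_x"] = gaze_x if gaze_x is not None else np.zeros(n)
    df["gaze_angle_y"] = gaze_y if gaze_y is not None else np.zeros(n)
    return FrameTable(person_id=person_id, frames=df)


@pytest.fixture(scope="session")
def small_cohort():
    """A small paper-calibrated cohort shared across tests (6+6 subjects,
    short audio) — enough to exercise every pipeline stage quickly."""
    from sitpipe import simulate as sim

    spec = sim.paper_preset(n_per_group=6, seed=11, audio_duration=2.0)
    return sim.simulate_cohort(spec, with_audio=True)
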