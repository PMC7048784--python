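"""Reading, writing and quality control of per-frame face-tracking tables.

The pipeline consumes the CSV dialect written by OpenFace 2.x: one row per
video frame with a timestamp, a tracking-confidence score, a success flag,
17 action-unit intensity channels (``AU01_r`` ... ``AU45_r``, 0-5 scale),
the matching presence channels (``AU01_c`` ... ``AU45_c``, 0/1) and the
world-coordinate gaze angles in radians (``gaze_angle_x``, ``gaze_angle_y``).
OpenFace pads its header names with spaces; headers are matched after
stripping whitespace and extra columns are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: The 17 action units for which OpenFace emits an intensity channel.
INTENSITY_AUS: tuple[str, ...] = (
    "AU01", "AU02", "AU04", "AU05", "AU06", "AU07", "AU09", "AU10",
    "AU12", "AU14", "AU15", "AU17", "AU20", "AU23", "AU25", "AU26", "AU45",
)

AU_INTENSITY_COLS = tuple(f"{au}_r" for au in INTENSITY_AUS)
AU_PRESENCE_COLS = tuple(f"{au}_c" for au in INTENSITY_AUS)
GAZE_COLS = ("gaze_angle_x", "gaze_angle_y")
REQUIRED_COLS = (
    ("timestamp", "confidence", "success")
    + AU_INTENSITY_COLS + AU_PRESENCE_COLS + GAZE_COLS
)

#: Default tracking-quality thresholds.
CONFIDENCE_THRESHOLD = 0.75
TRACKED_FRACTION_THRESHOLD = 0.90


class FrameTableError(ValueError):
    """Malformed or inconsistent frame table."""


@dataclass
class FrameTable:
    """Per-frame tracking record stream for one person.

    ``frames`` holds one row per video frame with canonical (stripped)
    column names.  Timestamps are seconds on the shared stimulus clock.
    """

    person_id: str
    frames: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLS if c not in self.frames.columns]
        if missing:
            raise FrameTableError(
                f"frame table for {self.person_id!r} missing column(s): {missing}"
            )
        ts = self.frames["timestamp"].to_numpy(float)
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise FrameTableError(
                f"timestamps not strictly increasing for {self.person_id!r}"
            )
        conf = self.frames["confidence"].to_numpy(float)
        if len(conf) and (conf.min() < 0 or conf.max() > 1):
            raise FrameTableError("confidence values outside [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def timestamps(self) -> np.ndarray:
        return self.frames["timestamp"].to_numpy(float)

    def intensity(self, au: str) -> np.ndarray:
        """Intensity series of one action unit (e.g. ``"AU12"``)."""
        col = f"{au}_r"
        if col not in self.frames.columns:
            raise KeyError(f"unknown action unit {au!r}")
        return self.frames[col].to_numpy(float)

    def presence(self, au: str) -> np.ndarray:
        col = f"{au}_c"
        if col not in self.frames.columns:
            raise KeyError(f"unknown action unit {au!r}")
        return self.frames[col].to_numpy(float)


@dataclass(frozen=True)
class QCReport:
    """Participant-level tracking-quality summary.

    A participant is included when at least 90% of frames survive the
    frame filter and the mean tracking confidence is at least 0.75.
    """

    person_id: str
    fraction_tracked: float
    mean_confidence: float
    n_frames_total: int
    n_frames_retained: int
    included: bool


def read_frame_table(path, person_id: str | None = None) -> FrameTable:
    """Read an OpenFace-dialect CSV into a :class:`FrameTable`.

    Column order is irrelevant, header whitespace is stripped, and columns
    beyond the required set are dropped.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise FrameTableError(f"{path}: missing required column(s): {missing}")
    keep = [c for c in ("frame",) + REQUIRED_COLS if c in df.columns]
    df = df[keep].copy()
    if person_id is None:
        import os

        person_id = os.path.splitext(os.path.basename(str(path)))[0]
    return FrameTable(person_id=person_id, frames=df.reset_index(drop=True))


def write_frame_table(ft: FrameTable, path) -> None:
    """Write a frame table back out in the OpenFace CSV dialect."""
    df = ft.frames.copy()
    if "frame" not in df.columns:
        df.insert(0, "frame", np.arange(1, len(df) + 1))
    df.to_csv(path, index=False, float_format="%.6f")


def filter_frames(ft: FrameTable, conf_threshold: float = CONFIDENCE_THRESHOLD) -> FrameTable:
    """Drop frames that were not tracked successfully or fall below the
    confidence threshold.  Order is preserved; the input is untouched."""
    if not 0.0 <= conf_threshold <= 1.0:
        raise ValueError("conf_threshold must lie in [0, 1]")
    mask = (ft.frames["success"].to_numpy() == 1) & (
        ft.frames["confidence"].to_numpy(float) >= conf_threshold
    )
    return replace(ft, frames=ft.frames.loc[mask].reset_index(drop=True))


def participant_qc(
    ft: FrameTable,
    conf_threshold: float = CONFIDENCE_THRESHOLD,
    tracked_threshold: float = TRACKED_FRACTION_THRESHOLD,
    confidence_over_all_frames: bool = True,
) -> QCReport:
    """Summarize tracking quality and apply the participant inclusion rule.

    ``confidence_over_all_frames`` selects whether mean confidence is taken
    over all frames (default) or only over frames passing the filter.
    """
    if ft.n_frames == 0:
        raise FrameTableError("participant_qc requires a non-empty frame table")
    retained = filter_frames(ft, conf_threshold)
    fraction = retained.n_frames / ft.n_frames
    conf_src = ft if confidence_over_all_frames else retained
    mean_conf = float(conf_src.frames["confidence"].mean()) if conf_src.n_frames else 0.0
    included = fraction >= tracked_threshold and mean_conf >= conf_threshold
    return QCReport(
        person_id=ft.person_id,
        fraction_tracked=float(fraction),
        mean_confidence=mean_conf,
        n_frames_total=ft.n_frames,
        n_frames_retained=retained.n_frames,
        included=bool(included),
    )
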