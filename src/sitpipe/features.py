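"""Secondary feature matrices for the diagnostic classifier.

Each frame-level channel (17 AU intensity channels; 2 gaze-angle channels)
is summarized by six order-invariant statistics — mean, sd, min, max,
skewness, excess kurtosis — separately in each of the seven conversation
parts (the six segments plus the whole-conversation aggregate):

* face:  17 channels x 7 parts x 6 stats = 714, + gender = 715 columns
* gaze:   2 channels x 7 parts x 6 stats =  84, + gender =  85 columns
* voice: 57 per-recording prosody values,        + gender =  58 columns

Gender enters every block as a feature; when blocks are combined the
duplicated gender columns collapse to one (715 + 85 + 58 − 2 = 856).
Missing values (e.g. an empty segment) stay NaN here and are imputed by
the training-fold median at model-fitting time, never during assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .openface import INTENSITY_AUS, FrameTable
from .protocol import WHOLE, SegmentSchedule, slice_segment
from .voice import VoiceFeatures

STAT_NAMES = ("mean", "sd", "min", "max", "skew", "kurt")
META_COLS = ("subject_id", "label", "gender", "age")


def channel_stats(series) -> dict[str, float]:
    """Six summary statistics of a 1-D series.

    sd uses the n−1 denominator; skewness is the biased moment ratio g1 and
    kurtosis the biased excess g2 = m4/m2² − 3.  A constant series has
    sd = 0 and NaN skew/kurtosis; series shorter than 2 get NaN for
    sd/skew/kurt.
    """
    x = np.asarray(series, float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n == 0:
        return dict.fromkeys(STAT_NAMES, np.nan)
    out = {"mean": float(x.mean()), "min": float(x.min()), "max": float(x.max())}
    if n < 2:
        out.update(sd=np.nan, skew=np.nan, kurt=np.nan)
        return out
    out["sd"] = float(x.std(ddof=1))
    m2 = float(((x - x.mean()) ** 2).mean())
    if m2 == 0:
        out.update(skew=np.nan, kurt=np.nan)
        return out
    m3 = float(((x - x.mean()) ** 3).mean())
    m4 = float(((x - x.mean()) ** 4).mean())
    out["skew"] = m3 / m2**1.5
    out["kurt"] = m4 / m2**2 - 3.0
    return out


def _part_channel_features(
    ft: FrameTable, sched: SegmentSchedule, channels: dict, prefix: str
) -> pd.Series:
    """channel_stats for every (part, channel); ``channels`` maps
    short name → column name in the frame table."""
    vals: dict[str, float] = {}
    for part in sched.analyzed_names + [WHOLE]:
        sliced = slice_segment(ft, sched, part)
        for short, col in channels.items():
            series = sliced.frames[col].to_numpy(float) if sliced.n_frames else []
            stats = channel_stats(series) if len(series) else dict.fromkeys(STAT_NAMES, np.nan)
            for stat in STAT_NAMES:
                vals[f"{prefix}.{part}.{short}.{stat}"] = stats[stat]
    return pd.Series(vals)


def build_face_features(
    ft: FrameTable, sched: SegmentSchedule, gender: int
) -> pd.Series:
    """715-column face vector: 17 AU intensity channels x 7 parts x 6 stats + gender."""
    channels = {au: f"{au}_r" for au in INTENSITY_AUS}
    vec = _part_channel_features(ft, sched, channels, "face")
    vec["gender"] = float(gender)
    return vec


def build_gaze_features(
    ft: FrameTable, sched: SegmentSchedule, gender: int
) -> pd.Series:
    """85-column gaze vector: 2 gaze-angle channels x 7 parts x 6 stats + gender."""
    channels = {"x": "gaze_angle_x", "y": "gaze_angle_y"}
    vec = _part_channel_features(ft, sched, channels, "gaze")
    vec["gender"] = float(gender)
    return vec


def build_voice_features(vf: VoiceFeatures, gender: int) -> pd.Series:
    """58-column voice vector: the 57 prosody values + gender."""
    vec = vf.as_series()
    vec.index = [f"voice.{name}" for name in vec.index]
    vec["gender"] = float(gender)
    return vec


@dataclass
class FeatureMatrix:
    """Subjects x named features, with the diagnostic metadata alongside.

    ``data`` holds the feature columns (including a single ``gender``
    column); ``meta`` carries subject_id, label (ASD/NT), gender and age,
    row-aligned with ``data``.
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.data) != len(self.meta):
            raise ValueError("feature and metadata row counts differ")
        if self.meta["label"].isna().any():
            raise ValueError("missing labels are not allowed")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate feature columns")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def labels(self) -> np.ndarray:
        return (self.meta["label"] == "ASD").to_numpy(int)

    def modality(self, tag: str) -> "FeatureMatrix":
        """Sub-matrix of one modality (face/gaze/voice), keeping gender."""
        cols = [c for c in self.data.columns if c.startswith(f"{tag}.")]
        return FeatureMatrix(self.data[cols + ["gender"]].copy(), self.meta.copy())

    def to_frame(self) -> pd.DataFrame:
        """Metadata columns first; the feature block's gender column is the
        metadata one, so it appears exactly once."""
        data = self.data.drop(columns=["gender"], errors="ignore")
        return pd.concat(
            [self.meta.reset_index(drop=True), data.reset_index(drop=True)], axis=1
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        meta = df[list(META_COLS)].copy()
        data = df.drop(columns=[c for c in META_COLS if c != "gender"])
        return cls(data, meta)


def assemble_block(vectors: dict[str, pd.Series], meta: pd.DataFrame) -> FeatureMatrix:
    """Stack per-subject vectors (subject_id → Series) into a FeatureMatrix,
    row-aligned with ``meta`` (columns subject_id, label, gender, age)."""
    data = pd.DataFrame([vectors[s] for s in meta["subject_id"]])
    data.index = range(len(data))
    return FeatureMatrix(data, meta.reset_index(drop=True))


def combine(*blocks: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation of modality blocks with gender deduplicated.

    All blocks must cover the same subjects in the same order.
    """
    blocks = [b for b in blocks if b is not None]
    if not blocks:
        raise ValueError("at least one block required")
    ids = blocks[0].meta["subject_id"].tolist()
    for b in blocks[1:]:
        if b.meta["subject_id"].tolist() != ids:
            raise ValueError("blocks cover different subjects")
    parts = [b.data.drop(columns=["gender"], errors="ignore") for b in blocks]
    data = pd.concat(parts, axis=1)
    data["gender"] = blocks[0].data["gender"].to_numpy()
    return FeatureMatrix(data, blocks[0].meta.copy())
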