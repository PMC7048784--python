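"""Conversation structure of the simulated interaction and stream slicing.

The simulated dialog alternates between prerecorded excerpts in which the
actress speaks (neutral: setting a table; positive: liked food; negative:
disliked food) and answer windows in which the participant speaks while the
actress displays listening behavior.  Analysis operates on six such
segments plus a ``whole``-conversation aggregate; the warm-up that precedes
them is never analyzed and is not part of the schedule clock.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import yaml

from .openface import FrameTable

VALENCES = ("neutral", "positive", "negative", "none")
SPEAKERS = ("actress", "participant", "both")

#: Name of the synthetic whole-conversation aggregate.
WHOLE = "whole"


class ScheduleError(ValueError):
    """Invalid segment schedule."""


@dataclass(frozen=True)
class Segment:
    name: str
    start: float
    end: float
    valence: str
    speaker: str
    analyzed: bool = True


@dataclass(frozen=True)
class SegmentSchedule:
    """Ordered, pairwise-disjoint, half-open [start, end) conversation parts."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.start)
        for s in segs:
            if s.end <= s.start:
                raise ScheduleError(f"segment {s.name!r}: end must exceed start")
            if s.valence not in VALENCES:
                raise ScheduleError(f"segment {s.name!r}: unknown valence {s.valence!r}")
            if s.speaker not in SPEAKERS:
                raise ScheduleError(f"segment {s.name!r}: unknown speaker {s.speaker!r}")
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ScheduleError(f"segments {a.name!r} and {b.name!r} overlap")
        names = [s.name for s in segs]
        if len(set(names)) != len(names):
            raise ScheduleError("segment names must be unique")
        object.__setattr__(self, "segments", tuple(segs))

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.segments]

    @property
    def analyzed_names(self) -> list[str]:
        return [s.name for s in self.segments if s.analyzed]

    @property
    def duration(self) -> float:
        return max(s.end for s in self.segments)

    def __getitem__(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(f"unknown segment {name!r}")


def default_schedule() -> SegmentSchedule:
    """Six-segment schedule of the simulated dialog, seconds past warm-up.

    Actress excerpts last 26/24/26 s (neutral/positive/negative); each
    participant answer window is 30 s.
    """
    rows = [
        ("neutral_listen", 0.0, 26.0, "neutral", "actress"),
        ("neutral_answer", 26.0, 56.0, "neutral", "participant"),
        ("positive_listen", 56.0, 80.0, "positive", "actress"),
        ("positive_answer", 80.0, 110.0, "positive", "participant"),
        ("negative_listen", 110.0, 136.0, "negative", "actress"),
        ("negative_answer", 136.0, 166.0, "negative", "participant"),
    ]
    return SegmentSchedule(
        segments=tuple(Segment(n, a, b, v, sp) for n, a, b, v, sp in rows)
    )


def load_schedule(path=None) -> SegmentSchedule:
    """Load a schedule from a YAML config, or return the default.

    The config holds a ``segments:`` list of mappings with keys
    ``name/start/end/valence/speaker`` and optional ``analyzed``.
    A config without a ``segments`` key yields the default schedule.
    """
    if path is None:
        return default_schedule()
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    rows = cfg.get("segments")
    if not rows:
        return default_schedule()
    segs = []
    for row in rows:
        try:
            segs.append(
                Segment(
                    name=str(row["name"]),
                    start=float(row["start"]),
                    end=float(row["end"]),
                    valence=str(row.get("valence", "none")),
                    speaker=str(row.get("speaker", "both")),
                    analyzed=bool(row.get("analyzed", True)),
                )
            )
        except KeyError as exc:
            raise ScheduleError(f"segment entry missing key {exc}") from exc
    return SegmentSchedule(segments=tuple(segs))


def save_schedule(sched: SegmentSchedule, path) -> None:
    data = {
        "segments": [
            {
                "name": s.name,
                "start": s.start,
                "end": s.end,
                "valence": s.valence,
                "speaker": s.speaker,
                "analyzed": s.analyzed,
            }
            for s in sched.segments
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def slice_segment(ft: FrameTable, sched: SegmentSchedule, name: str) -> FrameTable:
    """Frames whose timestamp falls in [start, end) of the named segment.

    The aggregate name ``whole`` returns the frames of every analyzed
    segment (in time order, without duplicates).
    """
    ts = ft.timestamps
    if name == WHOLE:
        import numpy as np

        mask = np.zeros(len(ts), dtype=bool)
        for seg in sched.segments:
            if seg.analyzed:
                mask |= (ts >= seg.start) & (ts < seg.end)
    else:
        seg = sched[name]
        mask = (ts >= seg.start) & (ts < seg.end)
    return _dc_replace(ft, frames=ft.frames.loc[mask].reset_index(drop=True))
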