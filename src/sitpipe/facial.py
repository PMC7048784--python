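"""Facial action-unit biomarkers: part-wise activity, social smiling, mimicry.

Occurrence of an action unit in a conversation part is the mean of its
binary presence channel over the QC-passing frames of that part; intensity
is the mean of the 0-5 intensity channel.  Social smiling summarizes AU12
(lip-corner puller) and AU6 (cheek raiser) over the whole conversation.

Facial mimicry is quantified as a windowed, lag-searched correlation
between the actress's and the participant's intensity series for one action
unit: the participant series is shifted back by a candidate reaction lag,
aligned to the actress frames by nearest timestamp, split into
non-overlapping 10-s windows, correlated per window, and the per-window
correlations are averaged on the Fisher-z scale.  The reported score is the
aggregate at the lag that maximizes it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .openface import FrameTable
from .protocol import WHOLE, SegmentSchedule

#: Action units entering the mimicry analysis: joy (AU6 orbicularis oculi,
#: AU12 zygomaticus major) and disgust (AU4 corrugator, AU9 levator labii).
MIMICRY_AUS = ("AU06", "AU12", "AU04", "AU09")

DEFAULT_LAG_GRID = tuple(np.arange(0.0, 3.0 + 1e-9, 0.25))
DEFAULT_WINDOW = 10.0
MIN_WINDOW_SAMPLES = 10


@dataclass(frozen=True)
class MimicryScore:
    person_id: str
    au: str
    score: float  # Fisher-z-mean windowed correlation at the best lag; NaN if unusable
    lag_selected: float
    n_windows_used: int


def au_segment_summary(
    ft: FrameTable, sched: SegmentSchedule, aus=None
) -> pd.DataFrame:
    """Occurrence and mean intensity per (segment, AU).

    Returns a tidy frame with columns ``person_id, segment, au, occurrence,
    intensity`` over every analyzed segment plus the ``whole`` aggregate.
    Segments with no frames yield NaN, never zero.
    """
    from .openface import INTENSITY_AUS
    from .protocol import slice_segment

    if aus is None:
        aus = INTENSITY_AUS
    rows = []
    for name in sched.analyzed_names + [WHOLE]:
        part = slice_segment(ft, sched, name)
        for au in aus:
            if part.n_frames == 0:
                occ = inten = np.nan
            else:
                occ = float(part.presence(au).mean())
                inten = float(part.intensity(au).mean())
            rows.append((ft.person_id, name, au, occ, inten))
    return pd.DataFrame(
        rows, columns=["person_id", "segment", "au", "occurrence", "intensity"]
    )


def social_smiling(ft: FrameTable, sched: SegmentSchedule) -> dict:
    """AU12/AU6 occurrence and intensity over the whole conversation."""
    summ = au_segment_summary(ft, sched, aus=("AU12", "AU06"))
    whole = summ[summ["segment"] == WHOLE].set_index("au")
    return {
        "AU12_occ": float(whole.loc["AU12", "occurrence"]),
        "AU12_int": float(whole.loc["AU12", "intensity"]),
        "AU6_occ": float(whole.loc["AU06", "occurrence"]),
        "AU6_int": float(whole.loc["AU06", "intensity"]),
    }


def _windowed_fisher_corr(
    t_ref: np.ndarray,
    x_ref: np.ndarray,
    t_other: np.ndarray,
    x_other: np.ndarray,
    window: float,
    tol: float,
) -> tuple[float, int]:
    """Fisher-z mean of per-window Pearson correlations after nearest-
    timestamp alignment of ``other`` onto ``ref``; returns (score, n_windows)."""
    # nearest alignment of the other series onto the reference clock
    idx = np.searchsorted(t_other, t_ref)
    idx = np.clip(idx, 1, len(t_other) - 1) if len(t_other) > 1 else np.zeros_like(idx)
    left = np.abs(t_ref - t_other[idx - 1])
    right = np.abs(t_other[idx] - t_ref)
    nearest = np.where(left <= right, idx - 1, idx)
    dist = np.minimum(left, right)
    ok = dist <= tol
    if ok.sum() < MIN_WINDOW_SAMPLES:
        return np.nan, 0
    t = t_ref[ok]
    a = x_ref[ok]
    b = x_other[nearest[ok]]

    start, stop = t[0], t[-1]
    zs = []
    n_win = int(np.floor((stop - start) / window))
    for k in range(max(n_win, 1)):
        lo, hi = start + k * window, start + (k + 1) * window
        m = (t >= lo) & (t < hi)
        if m.sum() < MIN_WINDOW_SAMPLES:
            continue
        aa, bb = a[m], b[m]
        if aa.std() == 0 or bb.std() == 0:
            continue
        r = float(np.corrcoef(aa, bb)[0, 1])
        r = np.clip(r, -0.999999, 0.999999)
        zs.append(np.arctanh(r))
    if not zs:
        return np.nan, 0
    return float(np.tanh(np.mean(zs))), len(zs)


def mimicry_correlation(
    participant: FrameTable,
    actress: FrameTable,
    au: str,
    window: float = DEFAULT_WINDOW,
    lag_grid=DEFAULT_LAG_GRID,
) -> MimicryScore:
    """Lag-searched windowed correlation of one AU's intensity series.

    Positive lags model the participant reacting after the actress: the
    participant series is shifted back in time by each candidate lag before
    alignment.  Windows with fewer than 10 aligned samples or zero variance
    on either side are skipped; remaining per-window correlations are
    combined by Fisher-z mean.  With no usable window at any lag the score
    is NaN and ``n_windows_used`` is 0.
    """
    t_a = actress.timestamps
    x_a = actress.intensity(au)
    t_p = participant.timestamps
    x_p = participant.intensity(au)
    if len(t_a) < 2 or len(t_p) < 2:
        return MimicryScore(participant.person_id, au, np.nan, np.nan, 0)
    frame_period = float(np.median(np.diff(t_a)))
    tol = frame_period / 2

    best = (-np.inf, np.nan, 0)
    for lag in lag_grid:
        score, n_win = _windowed_fisher_corr(t_a, x_a, t_p - lag, x_p, window, tol)
        if n_win and score > best[0]:
            best = (score, float(lag), n_win)
    if best[2] == 0:
        return MimicryScore(participant.person_id, au, np.nan, np.nan, 0)
    return MimicryScore(participant.person_id, au, best[0], best[1], best[2])


def mimicry_table(
    participant: FrameTable,
    actress: FrameTable,
    aus=MIMICRY_AUS,
    window: float = DEFAULT_WINDOW,
    lag_grid=DEFAULT_LAG_GRID,
) -> pd.DataFrame:
    """Tidy mimicry scores for several action units."""
    rows = []
    for au in aus:
        ms = mimicry_correlation(participant, actress, au, window, lag_grid)
        rows.append((ms.person_id, au, ms.score, ms.lag_selected, ms.n_windows_used))
    return pd.DataFrame(rows, columns=["person_id", "au", "score", "lag", "n_windows"])
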