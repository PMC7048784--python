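"""Prosodic and spectral voice features from mono recordings.

The extractor follows the standard Praat-style definitions:

* **Pitch** — short-time normalized autocorrelation corrected by the
  analysis window's own autocorrelation (Boersma's method).  A frame is
  voiced when the best corrected peak in the candidate lag range reaches
  the voicing threshold; a small octave cost favors the shorter lag when
  a pure tone makes the fundamental ambiguous.
* **Jitter / shimmer** — cycle-to-cycle perturbation of glottal periods
  and peak amplitudes (local, local absolute, rap, ppq5, ddp; local,
  local dB, apq3, apq5, apq11, dda).  Cycles are located as successive
  waveform maxima inside windows of one predicted period, only within
  contiguous voiced stretches.
* **HNR** — 10·log10(r/(1−r)) from the per-frame harmonicity r, clipped
  to [−20, 40] dB, aggregated as mean/median/sd over voiced frames.
* **MFCC** — magnitude spectrogram → 64 triangular mel filters →
  log (floor 1e-10) → orthonormal DCT-II → first 40 coefficients,
  averaged over frames.

Together with the root-mean-square energy this yields the 57-value
per-recording voice summary (40 MFCC means, F0 mean/sd, 5 jitter,
6 shimmer, 3 HNR aggregates, energy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dct, irfft, rfft
from scipy.io import wavfile
from scipy.signal.windows import hann

DEFAULT_FMIN = 75.0
DEFAULT_FMAX = 500.0
DEFAULT_VOICING_THRESHOLD = 0.45
OCTAVE_COST = 0.01
MEDIAN_SNAP_COST = 0.15  # per-octave penalty toward the track median (pass 2)
HNR_CLIP_DB = (-20.0, 40.0)
LOG_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# WAV plumbing

def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono PCM/float WAV; returns (float64 wave in [-1, 1], rate)."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.ndim} channels")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    else:
        data = data.astype(np.float64)
    return data, int(rate)


def write_wav(path, wave: np.ndarray, rate: int) -> None:
    """Write a float wave as 16-bit PCM, normalizing only if it clips."""
    peak = np.max(np.abs(wave)) if len(wave) else 0.0
    scaled = wave / peak if peak > 1.0 else wave
    wavfile.write(path, rate, (scaled * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# Pitch

@dataclass
class PitchTrack:
    """Frame-wise pitch track; unvoiced frames carry NaN f0/harmonicity."""

    time: np.ndarray
    f0: np.ndarray
    harmonicity_r: np.ndarray
    frame: float
    hop: float

    @property
    def voiced(self) -> np.ndarray:
        return ~np.isnan(self.f0)

    @property
    def n_voiced(self) -> int:
        return int(self.voiced.sum())


def _frame_signal(wave: np.ndarray, frame_len: int, hop_len: int) -> np.ndarray:
    if len(wave) < frame_len:
        raise ValueError("signal shorter than one analysis frame")
    return sliding_window_view(wave, frame_len)[::hop_len]


def estimate_pitch(
    wave: np.ndarray,
    rate: int,
    fmin: float = DEFAULT_FMIN,
    fmax: float = DEFAULT_FMAX,
    frame: float = 0.04,
    hop: float = 0.01,
    voicing_threshold: float = DEFAULT_VOICING_THRESHOLD,
) -> PitchTrack:
    """Autocorrelation pitch estimation with window-autocorrelation correction."""
    if rate < 4 * fmax:
        raise ValueError("sampling rate must be at least 4x the pitch ceiling")
    wave = np.asarray(wave, float)
    frame_len = int(round(frame * rate))
    hop_len = max(int(round(hop * rate)), 1)
    frames = _frame_signal(wave, frame_len, hop_len)
    n_frames = frames.shape[0]
    times = (np.arange(n_frames) * hop_len + frame_len / 2) / rate

    lag_min = max(int(np.floor(rate / fmax)), 2)
    lag_max = int(np.ceil(rate / fmin))
    nfft = 1 << int(np.ceil(np.log2(frame_len + lag_max + 1)))

    win = hann(frame_len, sym=False)
    # window autocorrelation (normalized), for Boersma's correction
    w_spec = np.abs(rfft(win, nfft)) ** 2
    r_w = irfft(w_spec, nfft)[: lag_max + 1]
    r_w = r_w / r_w[0]

    x = (frames - frames.mean(axis=1, keepdims=True)) * win
    spec = np.abs(rfft(x, nfft, axis=1)) ** 2
    r_x = irfft(spec, nfft, axis=1)[:, : lag_max + 1]
    energy = r_x[:, 0].copy()
    silent = energy <= 0
    energy[silent] = 1.0
    r = r_x / energy[:, None] / np.maximum(r_w, 1e-6)[None, :]

    lags = np.arange(lag_min, lag_max + 1)
    band = r[:, lag_min : lag_max + 1]

    def _peak(score: np.ndarray):
        """Per-frame argmax of ``score`` with parabolic refinement of the
        *uncosted* correlation around it."""
        j = np.argmax(score, axis=1) + lag_min
        jm = np.clip(j - 1, 0, lag_max)
        jp = np.clip(j + 1, 0, lag_max)
        y0 = np.take_along_axis(r, jm[:, None], 1)[:, 0]
        y1 = np.take_along_axis(r, j[:, None], 1)[:, 0]
        y2 = np.take_along_axis(r, jp[:, None], 1)[:, 0]
        denom = y0 - 2 * y1 + y2
        offset = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        offset = np.clip(offset, -0.5, 0.5)
        return rate / (j + offset), y1 - 0.25 * (y0 - y2) * offset

    # pass 1: octave cost prefers the shorter lag among near-equal peaks
    score1 = band - OCTAVE_COST * np.log2(fmin * lags / rate)
    f0, r_peak = _peak(score1)

    # pass 2: any periodic signal has equal correlation peaks at integer
    # multiples of the true period, and noise can flip the argmax to a
    # subharmonic.  Re-score with a mild penalty for straying from the
    # median f0 of the confident frames.
    confident = (r_peak >= max(0.6, voicing_threshold)) & ~silent
    if confident.any():
        med = float(np.median(f0[confident]))
        penalty = MEDIAN_SNAP_COST * np.abs(np.log2((rate / lags) / med))
        f0, r_peak = _peak(band - penalty[None, :])

    voiced = (r_peak >= voicing_threshold) & ~silent & (f0 >= fmin) & (f0 <= fmax)
    f0 = np.where(voiced, f0, np.nan)
    harm = np.where(voiced, np.clip(r_peak, 1e-6, 1 - 1e-6), np.nan)
    return PitchTrack(time=times, f0=f0, harmonicity_r=harm, frame=frame, hop=hop)


# ---------------------------------------------------------------------------
# Glottal-cycle point process

@dataclass
class PeriodSequence:
    """Per-cycle periods and peak amplitudes, grouped by voiced stretch.

    Perturbation measures never difference across stretch boundaries.
    """

    stretches: list = field(default_factory=list)  # list of (T array, A array)

    @property
    def n_periods(self) -> int:
        return int(sum(len(T) for T, _ in self.stretches))

    def periods(self) -> list[np.ndarray]:
        return [T for T, _ in self.stretches]

    def amplitudes(self) -> list[np.ndarray]:
        return [A for _, A in self.stretches]


def _refine_peak(wave: np.ndarray, idx: int) -> tuple[float, float]:
    """Sub-sample peak position/amplitude via a least-squares parabola
    over five samples (noise-averaging)."""
    if idx < 2 or idx >= len(wave) - 2:
        return float(idx), float(abs(wave[idx]))
    y = wave[idx - 2 : idx + 3]
    x = np.arange(-2.0, 3.0)
    # closed-form LS fit y ~ a x^2 + b x + c on x = -2..2
    a = (y @ (x**2 - 2.0)) / 14.0
    b = (y @ x) / 10.0
    c = (y @ np.array([-6.0, 24.0, 34.0, 24.0, -6.0])) / 70.0
    if a >= -1e-12:
        return float(idx), float(abs(wave[idx]))
    off = np.clip(-b / (2 * a), -1.0, 1.0)
    return float(idx + off), float(abs(a * off**2 + b * off + c))


def extract_periods(wave: np.ndarray, track: PitchTrack, rate: int) -> PeriodSequence:
    """Locate successive cycle peaks within each voiced stretch.

    Peaks are waveform maxima inside consecutive windows of one local
    period (predicted from the pitch track); stretches shorter than three
    cycles are dropped.
    """
    wave = np.asarray(wave, float)
    voiced = track.voiced
    seq = PeriodSequence()
    if not voiced.any():
        return seq

    # contiguous voiced runs of pitch frames
    idx = np.flatnonzero(voiced)
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        t0 = track.time[run[0]] - track.frame / 2
        t1 = track.time[run[-1]] + track.frame / 2
        run_t = track.time[run]
        run_f0 = track.f0[run]

        def local_period(t: float) -> float:
            k = int(np.argmin(np.abs(run_t - t)))
            return 1.0 / run_f0[k]

        peaks_t: list[float] = []
        peaks_a: list[float] = []
        pos = max(int(t0 * rate), 0)
        end = min(int(t1 * rate), len(wave))
        while pos < end:
            T = local_period(pos / rate)
            w0, w1 = pos, pos + int(round(T * rate))
            if w1 > end:  # never search a truncated window (short periods)
                break
            j = w0 + int(np.argmax(wave[w0:w1]))
            pj, aj = _refine_peak(wave, j)
            peaks_t.append(pj / rate)
            peaks_a.append(abs(aj))
            # next search window starts half a period past this peak
            pos = int(round(pj + 0.5 * local_period(pj / rate) * rate))
            if pos <= w0:
                pos = w1
        T_arr = np.diff(np.asarray(peaks_t))
        A_arr = np.asarray(peaks_a[1:])
        good = T_arr > 0
        T_arr, A_arr = T_arr[good], A_arr[good]
        if len(T_arr) >= 3:
            seq.stretches.append((T_arr, A_arr))
    return seq


# ---------------------------------------------------------------------------
# Perturbation measures

def _as_stretches(x) -> list[np.ndarray]:
    if isinstance(x, PeriodSequence):
        raise TypeError("pass PeriodSequence.periods() or .amplitudes()")
    if isinstance(x, (list, tuple)) and len(x) and np.ndim(x[0]) == 1:
        return [np.asarray(s, float) for s in x]
    return [np.asarray(x, float)]


def _pooled_neighborhood_dev(stretches: list[np.ndarray], k: int) -> float:
    """mean |x_i − k-point centered neighborhood mean|, pooled over stretches."""
    devs = []
    half = k // 2
    for s in stretches:
        if len(s) < k:
            continue
        windows = sliding_window_view(s, k)
        center = s[half : half + len(windows)]
        devs.append(np.abs(center - windows.mean(axis=1)))
    if not devs:
        return np.nan
    return float(np.concatenate(devs).mean())


def jitter_measures(T) -> dict[str, float]:
    """The five Praat-style jitter measures from a period sequence.

    Accepts a flat array or a list of per-stretch arrays; differences are
    taken within stretches only.  Fewer than three periods → all NaN.
    """
    stretches = _as_stretches(T)
    allT = np.concatenate(stretches) if stretches else np.array([])
    nan = {k: np.nan for k in ("local", "local_abs", "rap", "ppq5", "ddp")}
    if len(allT) < 3:
        return nan
    if np.any(allT <= 0):
        raise ValueError("periods must be positive")
    mean_T = allT.mean()
    diffs = [np.abs(np.diff(s)) for s in stretches if len(s) >= 2]
    local_abs = float(np.concatenate(diffs).mean()) if diffs else np.nan
    rap = _pooled_neighborhood_dev(stretches, 3)
    ppq5 = _pooled_neighborhood_dev(stretches, 5)
    return {
        "local": local_abs / mean_T,
        "local_abs": local_abs,
        "rap": rap / mean_T if np.isfinite(rap) else np.nan,
        "ppq5": ppq5 / mean_T if np.isfinite(ppq5) else np.nan,
        "ddp": 3 * rap / mean_T if np.isfinite(rap) else np.nan,
    }


def shimmer_measures(A) -> dict[str, float]:
    """The six Praat-style shimmer measures from an amplitude sequence.

    apq11 requires at least 11 amplitudes and is NaN otherwise.
    """
    stretches = _as_stretches(A)
    allA = np.concatenate(stretches) if stretches else np.array([])
    nan = {k: np.nan for k in ("local", "local_db", "apq3", "apq5", "apq11", "dda")}
    if len(allA) < 3:
        return nan
    if np.any(allA <= 0):
        raise ValueError("amplitudes must be positive")
    mean_A = allA.mean()
    diffs = [s for s in stretches if len(s) >= 2]
    abs_d = np.concatenate([np.abs(np.diff(s)) for s in diffs])
    db_d = np.concatenate([np.abs(20 * np.log10(s[1:] / s[:-1])) for s in diffs])
    apq3 = _pooled_neighborhood_dev(stretches, 3)
    apq5 = _pooled_neighborhood_dev(stretches, 5)
    apq11 = _pooled_neighborhood_dev(stretches, 11)
    return {
        "local": float(abs_d.mean()) / mean_A,
        "local_db": float(db_d.mean()),
        "apq3": apq3 / mean_A if np.isfinite(apq3) else np.nan,
        "apq5": apq5 / mean_A if np.isfinite(apq5) else np.nan,
        "apq11": apq11 / mean_A if np.isfinite(apq11) else np.nan,
        "dda": 3 * apq3 / mean_A if np.isfinite(apq3) else np.nan,
    }


# ---------------------------------------------------------------------------
# Harmonics-to-noise ratio

def hnr(track: PitchTrack) -> dict[str, float]:
    """HNR aggregates (dB) over voiced frames: 10·log10(r/(1−r)), clipped."""
    r = track.harmonicity_r[track.voiced]
    if len(r) == 0:
        return {"mean": np.nan, "median": np.nan, "sd": np.nan}
    h = np.clip(10 * np.log10(r / (1 - r)), *HNR_CLIP_DB)
    return {
        "mean": float(h.mean()),
        "median": float(np.median(h)),
        "sd": float(h.std(ddof=1)) if len(h) > 1 else np.nan,
    }


# ---------------------------------------------------------------------------
# MFCC

def _mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, float) / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (np.asarray(m, float) / 2595.0) - 1.0)


def mel_filterbank(rate: int, nfft: int, n_mel: int) -> np.ndarray:
    """Triangular mel filters spanning 0 to rate/2; shape (n_mel, nfft//2+1)."""
    edges = _mel_inv(np.linspace(_mel(0.0), _mel(rate / 2), n_mel + 2))
    freqs = np.linspace(0, rate / 2, nfft // 2 + 1)
    fb = np.zeros((n_mel, len(freqs)))
    for m in range(n_mel):
        lo, mid, hi = edges[m], edges[m + 1], edges[m + 2]
        up = (freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - freqs) / max(hi - mid, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0, None)
    return fb


def mel_log_energies(
    wave: np.ndarray,
    rate: int,
    frame: float = 0.025,
    hop: float = 0.010,
    n_mel: int = 64,
) -> np.ndarray:
    """Log mel filterbank energies, shape (n_frames, n_mel)."""
    wave = np.asarray(wave, float)
    frame_len = int(round(frame * rate))
    hop_len = max(int(round(hop * rate)), 1)
    frames = _frame_signal(wave, frame_len, hop_len)
    nfft = 1 << int(np.ceil(np.log2(frame_len)))
    win = hann(frame_len, sym=False)
    mag = np.abs(rfft(frames * win, nfft, axis=1))
    fb = mel_filterbank(rate, nfft, n_mel)
    return np.log(np.maximum(mag @ fb.T, LOG_FLOOR))


def mfcc_frames(
    wave: np.ndarray,
    rate: int,
    n_coeff: int = 40,
    frame: float = 0.025,
    hop: float = 0.010,
    n_mel: int = 64,
) -> np.ndarray:
    """Per-frame MFCCs (orthonormal DCT-II of log mel energies)."""
    if n_coeff > n_mel:
        raise ValueError("n_coeff must not exceed n_mel")
    logE = mel_log_energies(wave, rate, frame, hop, n_mel)
    return dct(logE, type=2, norm="ortho", axis=1)[:, :n_coeff]


def mfcc_mean(wave, rate, n_coeff: int = 40, frame: float = 0.025,
              hop: float = 0.010, n_mel: int = 64) -> np.ndarray:
    """Per-coefficient mean MFCC over frames (the per-recording summary)."""
    return mfcc_frames(wave, rate, n_coeff, frame, hop, n_mel).mean(axis=0)


# ---------------------------------------------------------------------------
# Per-recording summary

VOICE_SCALAR_FIELDS = (
    "f0_mean", "f0_sd",
    "jitter_local", "jitter_local_abs", "jitter_rap", "jitter_ppq5", "jitter_ddp",
    "shimmer_local", "shimmer_local_db", "shimmer_apq3", "shimmer_apq5",
    "shimmer_apq11", "shimmer_dda",
    "hnr_mean", "hnr_median", "hnr_sd",
    "rms_energy",
)


@dataclass
class VoiceFeatures:
    """57-value prosody summary: 17 scalars + 40 MFCC means."""

    f0_mean: float
    f0_sd: float
    jitter_local: float
    jitter_local_abs: float
    jitter_rap: float
    jitter_ppq5: float
    jitter_ddp: float
    shimmer_local: float
    shimmer_local_db: float
    shimmer_apq3: float
    shimmer_apq5: float
    shimmer_apq11: float
    shimmer_dda: float
    hnr_mean: float
    hnr_median: float
    hnr_sd: float
    rms_energy: float
    mfcc_mean: np.ndarray

    def as_series(self) -> pd.Series:
        vals = {f: getattr(self, f) for f in VOICE_SCALAR_FIELDS}
        for i, v in enumerate(self.mfcc_mean):
            vals[f"mfcc_{i:02d}"] = float(v)
        return pd.Series(vals)


def voice_summary(
    wave: np.ndarray,
    rate: int,
    fmin: float = DEFAULT_FMIN,
    fmax: float = DEFAULT_FMAX,
    voicing_threshold: float = DEFAULT_VOICING_THRESHOLD,
    n_mfcc: int = 40,
) -> VoiceFeatures:
    """Full per-recording voice feature extraction."""
    wave = np.asarray(wave, float)
    track = estimate_pitch(wave, rate, fmin, fmax, voicing_threshold=voicing_threshold)
    f0 = track.f0[track.voiced]
    seq = extract_periods(wave, track, rate)
    jit = jitter_measures(seq.periods()) if seq.n_periods else jitter_measures([])
    shim = (
        shimmer_measures(seq.amplitudes()) if seq.n_periods else shimmer_measures([])
    )
    h = hnr(track)
    return VoiceFeatures(
        f0_mean=float(f0.mean()) if len(f0) else np.nan,
        f0_sd=float(f0.std(ddof=1)) if len(f0) > 1 else np.nan,
        jitter_local=jit["local"],
        jitter_local_abs=jit["local_abs"],
        jitter_rap=jit["rap"],
        jitter_ppq5=jit["ppq5"],
        jitter_ddp=jit["ddp"],
        shimmer_local=shim["local"],
        shimmer_local_db=shim["local_db"],
        shimmer_apq3=shim["apq3"],
        shimmer_apq5=shim["apq5"],
        shimmer_apq11=shim["apq11"],
        shimmer_dda=shim["dda"],
        hnr_mean=h["mean"],
        hnr_median=h["median"],
        hnr_sd=h["sd"],
        rms_energy=float(np.sqrt(np.mean(wave**2))),
        mfcc_mean=mfcc_mean(wave, rate, n_coeff=n_mfcc),
    )
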