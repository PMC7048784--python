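"""Synthetic simulated-interaction cohorts for end-to-end pipeline testing.

The clinical recordings behind this pipeline cannot be redistributed, so
every stage is exercised on simulated cohorts instead.  The generator
emulates the data-generating process at the level the pipeline consumes:

* a deterministic **actress reference track** — smooth action-unit
  activity elevated for joy (AU6/AU12) while she speaks about liked food
  and while she listens, and for disgust/frowning (AU4/AU9) in the
  disliked-food excerpt; identical for every participant;
* **participant frame tables** — AU presence/intensity channels derived
  from low-pass-filtered Gaussian latent processes whose thresholds hit
  per-segment occurrence targets in expectation; the joy/disgust latents
  are coupled to a lag-shifted copy of the actress latent with a
  per-subject mimicry coupling; gaze angles follow a mean-reverting
  process calibrated to stationary spread and mean speed; tracking
  confidence is high with occasional dropouts;
* **voiced audio** — per-cycle harmonic synthesis with controlled
  fundamental frequency, period perturbation (jitter), amplitude
  perturbation (shimmer) and additive noise at a prescribed
  harmonics-to-noise ratio.

Group-level calibration targets follow the published group descriptives
(AU12 whole-conversation occurrence 0.40 NT vs 0.09 ASD, AU6 0.12 vs
0.02, negative-part AU4 intensity 0.03 vs 0.08, mimicry 0.19 vs 0.08,
sex-specific F0 and HNR, near-null gaze differences).  A ``null`` preset
removes every group difference.  Identical seeds give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, lfilter
from scipy.stats import norm

from .openface import AU_INTENSITY_COLS, AU_PRESENCE_COLS, INTENSITY_AUS, FrameTable
from .protocol import SegmentSchedule, default_schedule

FEMALE, MALE = 1, 0

#: Per-segment multipliers applied to whole-conversation activity targets,
#: approximately time-weighted to average 1 over the conversation.
_SEG_WEIGHTS = {
    "joy": {"neutral": 0.6, "positive": 1.8, "negative": 0.65},
    "disgust": {"neutral": 0.7, "positive": 0.6, "negative": 1.7},
    "flat": {"neutral": 1.0, "positive": 1.0, "negative": 1.0},
}
_AU_FAMILY = {"AU06": "joy", "AU12": "joy", "AU04": "disgust", "AU09": "disgust"}
COUPLED_AUS = ("AU06", "AU12", "AU04", "AU09")


@dataclass(frozen=True)
class GroupEffects:
    """Calibration targets for one diagnostic group."""

    au12_occ: float
    au6_occ: float
    au12_int: float
    au6_int: float
    au4_int: float
    au9_int: float
    mimicry_coupling: float
    f0_female: float
    f0_female_sd: float
    f0_male: float
    f0_male_sd: float
    hnr_female: float
    hnr_female_sd: float
    hnr_male: float
    hnr_male_sd: float
    jitter: float
    shimmer: float
    gaze_mean_x: float
    gaze_mean_y: float
    gaze_sd_x: float
    gaze_sd_y: float
    gaze_speed_x: float
    gaze_speed_y: float
    gaze_drift: float
    age_range: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("au12_occ", "au6_occ", "mimicry_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def f0(self, gender: int) -> tuple[float, float]:
        return (
            (self.f0_female, self.f0_female_sd)
            if gender == FEMALE
            else (self.f0_male, self.f0_male_sd)
        )

    def hnr(self, gender: int) -> tuple[float, float]:
        return (
            (self.hnr_female, self.hnr_female_sd)
            if gender == FEMALE
            else (self.hnr_male, self.hnr_male_sd)
        )


NT_EFFECTS = GroupEffects(
    au12_occ=0.40, au6_occ=0.12, au12_int=0.52, au6_int=0.40,
    au4_int=0.03, au9_int=0.05, mimicry_coupling=0.19,
    f0_female=209.08, f0_female_sd=17.97, f0_male=121.68, f0_male_sd=11.68,
    hnr_female=10.32, hnr_female_sd=1.47, hnr_male=10.84, hnr_male_sd=1.42,
    jitter=0.015, shimmer=0.06,
    gaze_mean_x=0.02, gaze_mean_y=-0.25, gaze_sd_x=0.025, gaze_sd_y=0.038,
    gaze_speed_x=0.65, gaze_speed_y=0.71, gaze_drift=0.0,
    age_range=(18.0, 49.0),
)

ASD_EFFECTS = GroupEffects(
    au12_occ=0.09, au6_occ=0.02, au12_int=0.16, au6_int=0.30,
    au4_int=0.08, au9_int=0.06, mimicry_coupling=0.08,
    f0_female=218.91, f0_female_sd=16.16, f0_male=139.67, f0_male_sd=16.22,
    hnr_female=6.91, hnr_female_sd=2.12, hnr_male=8.50, hnr_male_sd=1.44,
    jitter=0.015, shimmer=0.06,
    gaze_mean_x=0.01, gaze_mean_y=-0.23, gaze_sd_x=0.038, gaze_sd_y=0.041,
    gaze_speed_x=0.67, gaze_speed_y=0.64, gaze_drift=0.0,
    age_range=(22.0, 62.0),
)


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition bundle for one synthetic cohort."""

    n_per_group: int = 40
    gender_mix: float = 0.5  # fraction female
    seed: int = 0
    fps: float = 30.0
    audio_rate: int = 16000
    audio_duration: float = 8.0  # seconds of voiced speech synthesized per subject
    reaction_lag: float = 0.5  # participant mimicry lag behind the actress, s
    severity_informative: bool = True  # False: severity unrelated to group
    effects: dict = field(
        default_factory=lambda: {"NT": NT_EFFECTS, "ASD": ASD_EFFECTS}
    )

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0.0 <= self.gender_mix <= 1.0:
            raise ValueError("gender_mix must lie in [0, 1]")


def paper_preset(**overrides) -> CohortSpec:
    """Cohort calibrated to the published group descriptives."""
    return CohortSpec(**overrides)


def null_preset(**overrides) -> CohortSpec:
    """Cohort with every group difference removed (both groups use the
    NT calibration; severity is uninformative)."""
    return CohortSpec(
        effects={"NT": NT_EFFECTS, "ASD": NT_EFFECTS},
        severity_informative=False,
        **overrides,
    )


# ---------------------------------------------------------------------------
# Latent-process machinery

def _smooth_std_noise(rng, shape, fps: float, cutoff: float = 0.5) -> np.ndarray:
    """Low-pass-filtered white noise, standardized per row.

    Yields approximately standard-normal, smooth (cutoff ~0.5 Hz) latent
    series; rows are independent channels.
    """
    white = rng.standard_normal(shape)
    b, a = butter(2, cutoff / (fps / 2))
    y = lfilter(b, a, white, axis=-1)
    mu = y.mean(axis=-1, keepdims=True)
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return (y - mu) / sd


def _segment_valence(sched: SegmentSchedule, ts: np.ndarray) -> list[tuple[np.ndarray, str]]:
    out = []
    for seg in sched.segments:
        mask = (ts >= seg.start) & (ts < seg.end)
        out.append((mask, seg.valence))
    return out


def _au_channels_from_latent(
    z: np.ndarray,
    ts: np.ndarray,
    sched: SegmentSchedule,
    family: str,
    occ_target: float,
    int_target: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Presence/intensity from a standardized latent: presence thresholds
    hit the per-segment occurrence target in expectation; intensities are
    shifted-rectified latents scaled to the per-segment mean target."""
    weights = _SEG_WEIGHTS[family]
    presence = np.zeros_like(z)
    intensity = np.zeros_like(z)
    rect = np.maximum(z + 1.0, 0.0)
    rect_mean = norm.pdf(1.0) + norm.cdf(1.0)  # E[max(Z+1, 0)], Z ~ N(0,1)
    for mask, valence in _segment_valence(sched, ts):
        w = weights.get(valence, 1.0)
        p = float(np.clip(occ_target * w, 1e-3, 0.95))
        thr = norm.isf(p)
        presence[mask] = (z[mask] > thr).astype(float)
        scale = np.clip(int_target * w, 1e-4, None) / rect_mean
        intensity[mask] = np.clip(rect[mask] * scale, 0.0, 5.0)
    return presence, intensity


def _frame_table(
    person_id: str,
    ts: np.ndarray,
    presence: dict[str, np.ndarray],
    intensity: dict[str, np.ndarray],
    gaze_x: np.ndarray,
    gaze_y: np.ndarray,
    confidence: np.ndarray,
    success: np.ndarray,
) -> FrameTable:
    df = pd.DataFrame({"frame": np.arange(1, len(ts) + 1), "timestamp": ts})
    df["confidence"] = confidence
    df["success"] = success.astype(int)
    for au, col in zip(INTENSITY_AUS, AU_INTENSITY_COLS):
        df[col] = np.round(intensity[au], 6)
    for au, col in zip(INTENSITY_AUS, AU_PRESENCE_COLS):
        df[col] = presence[au].astype(int)
    df["gaze_angle_x"] = np.round(gaze_x, 6)
    df["gaze_angle_y"] = np.round(gaze_y, 6)
    return FrameTable(person_id=person_id, frames=df)


#: Actress whole-conversation activity targets (occurrence, intensity).
_ACTRESS_TARGETS = {
    "AU06": (0.45, 0.8), "AU12": (0.55, 1.0),
    "AU04": (0.10, 0.12), "AU09": (0.06, 0.06),
}
_BACKGROUND_OCC = 0.08
_BACKGROUND_INT = 0.15


def actress_reference(
    sched: SegmentSchedule | None = None, seed: int = 0, fps: float = 30.0
) -> tuple[FrameTable, dict[str, np.ndarray]]:
    """Deterministic actress track shared by the whole cohort.

    Returns the frame table and the standardized latent series per AU
    (used to couple participants' mimicry channels).
    """
    sched = sched or default_schedule()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 917]))
    n = int(round(sched.duration * fps))
    ts = np.arange(n) / fps
    latents = _smooth_std_noise(rng, (len(INTENSITY_AUS), n), fps)
    presence, intensity, lat = {}, {}, {}
    for i, au in enumerate(INTENSITY_AUS):
        z = latents[i]
        lat[au] = z
        family = _AU_FAMILY.get(au, "flat")
        occ, inten = _ACTRESS_TARGETS.get(au, (_BACKGROUND_OCC, _BACKGROUND_INT))
        presence[au], intensity[au] = _au_channels_from_latent(
            z, ts, sched, family, occ, inten
        )
    gaze = 0.02 * _smooth_std_noise(rng, (2, n), fps)
    ft = _frame_table(
        "actress", ts, presence, intensity, gaze[0], gaze[1] - 0.1,
        np.ones(n), np.ones(n),
    )
    return ft, lat


def _gaze_series(rng, n, fps, mean, sd, speed, drift) -> np.ndarray:
    """Mean-reverting (AR(1)) gaze-angle series calibrated to a stationary
    sd and a mean absolute speed."""
    step = speed / fps  # target E|delta theta| per frame
    root = step * np.sqrt(np.pi / 2) / max(sd, 1e-6)
    a = float(np.clip(1.0 - root**2 / 2.0, -0.95, 0.999))
    innov_sd = sd * np.sqrt(max(1 - a**2, 1e-6))
    eps = rng.standard_normal(n) * innov_sd
    theta = np.empty(n)
    theta[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        theta[i] = a * theta[i - 1] + eps[i]
    return mean + theta + drift * np.arange(n) / fps


def synthesize_voice(
    f0: float,
    jitter_local: float,
    shimmer_local: float,
    hnr_db: float,
    duration: float,
    rate: int,
    seed: int = 0,
    n_harmonics: int = 6,
) -> np.ndarray:
    """Per-cycle harmonic voice synthesis with controlled perturbations.

    Cycle periods are T0·(1+eps) with eps ~ N(0, s_j), s_j calibrated so the
    expected local jitter equals ``jitter_local`` (E|eps_i+1 − eps_i| =
    2s/sqrt(pi)); amplitudes analogously for ``shimmer_local``.  White noise
    is added at power P_h·10^(−hnr_db/10).
    """
    if not 60.0 <= f0 <= 600.0:
        raise ValueError("f0 must lie in [60, 600] Hz")
    if duration < 0.5:
        raise ValueError("duration must be >= 0.5 s")
    rng = np.random.default_rng(seed)
    T0 = 1.0 / f0
    sigma_j = jitter_local * np.sqrt(np.pi) / 2
    sigma_s = shimmer_local * np.sqrt(np.pi) / 2

    n_cycles = int(np.ceil(duration / T0)) + 2
    T = T0 * np.clip(1 + sigma_j * rng.standard_normal(n_cycles), 0.5, 1.5)
    A = np.clip(1 + sigma_s * rng.standard_normal(n_cycles), 0.1, 2.0)
    pulses = np.concatenate([[0.0], np.cumsum(T)])  # pulse (peak) times

    n = int(round(duration * rate))
    t = np.arange(n) / rate
    idx = np.clip(np.searchsorted(pulses, t, side="right") - 1, 0, n_cycles - 1)
    phase = (t - pulses[idx]) / T[idx]
    # cosine phases align all harmonics at the pulse times: one dominant,
    # well-defined peak per cycle, so measured inter-peak intervals equal
    # the injected periods
    wave = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        wave += np.cos(2 * np.pi * k * phase) / k
    # smooth amplitude envelope through the per-pulse amplitudes, so the
    # peak amplitude at pulse i equals A_i
    wave *= np.interp(t, pulses[: len(A)], A)

    ph = float(np.mean(wave**2))
    noise_sd = np.sqrt(ph * 10 ** (-hnr_db / 10))
    wave = wave + noise_sd * rng.standard_normal(n)
    peak = np.max(np.abs(wave))
    return wave * (0.5 / peak) if peak > 0 else wave


@dataclass
class Participant:
    frames: FrameTable
    wave: np.ndarray | None
    info: dict


def simulate_participant(
    spec: CohortSpec,
    group: str,
    gender: int,
    actress_latents: dict[str, np.ndarray],
    sched: SegmentSchedule,
    seed,
    person_id: str = "sub",
    with_audio: bool = True,
) -> Participant:
    """One participant's frame table (and optionally audio).

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    eff_nt = spec.effects["NT"]
    eff = spec.effects[group]

    # per-subject effect multiplier: interpolates this subject between the
    # NT calibration (g = 0) and its group calibration (g = 1, on average)
    if group == "ASD":
        g = float(np.clip(1.0 + 0.35 * rng.standard_normal(), 0.2, 1.8))
    else:
        g = 0.0

    def blend(nt_val, grp_val, logit=False):
        if logit:
            lo = _logit(nt_val) + (_logit(grp_val) - _logit(nt_val)) * g
            return _expit(lo)
        return nt_val + (grp_val - nt_val) * g

    n = int(round(sched.duration * spec.fps))
    ts = np.arange(n) / spec.fps

    # subject-level target draws (between-subject heterogeneity)
    occ12 = _expit(_logit(blend(eff_nt.au12_occ, eff.au12_occ, logit=True))
                   + 0.6 * rng.standard_normal())
    occ6 = _expit(_logit(blend(eff_nt.au6_occ, eff.au6_occ, logit=True))
                  + 0.6 * rng.standard_normal())
    int12 = blend(eff_nt.au12_int, eff.au12_int) * np.exp(0.35 * rng.standard_normal())
    int6 = blend(eff_nt.au6_int, eff.au6_int) * np.exp(0.35 * rng.standard_normal())
    int4 = blend(eff_nt.au4_int, eff.au4_int) * np.exp(0.35 * rng.standard_normal())
    int9 = blend(eff_nt.au9_int, eff.au9_int) * np.exp(0.35 * rng.standard_normal())
    coupling = float(np.clip(
        blend(eff_nt.mimicry_coupling, eff.mimicry_coupling)
        + 0.06 * rng.standard_normal(), 0.0, 0.95,
    ))

    targets = {
        "AU12": (occ12, int12), "AU06": (occ6, int6),
        "AU04": (0.10, int4), "AU09": (0.06, int9),
    }

    lag_frames = int(round(spec.reaction_lag * spec.fps))
    latents = _smooth_std_noise(rng, (len(INTENSITY_AUS), n), spec.fps)
    presence, intensity = {}, {}
    for i, au in enumerate(INTENSITY_AUS):
        noise_z = latents[i]
        if au in COUPLED_AUS and coupling > 0:
            a = actress_latents[au]
            shifted = np.concatenate([np.full(lag_frames, a[0]), a])[:n]
            z = coupling * shifted + np.sqrt(1 - coupling**2) * noise_z
        else:
            z = noise_z
        family = _AU_FAMILY.get(au, "flat")
        occ, inten = targets.get(au, (_BACKGROUND_OCC, _BACKGROUND_INT))
        presence[au], intensity[au] = _au_channels_from_latent(
            z, ts, sched, family, occ, inten
        )

    # gaze: subject means and spreads drawn from the group's between-subject
    # distributions (the published absolute-deviation SD of 0.01 rad maps to
    # a gaze-sd spread of 0.01*sqrt(pi/2))
    mean_x = rng.normal(blend(eff_nt.gaze_mean_x, eff.gaze_mean_x), 0.06)
    mean_y = rng.normal(blend(eff_nt.gaze_mean_y, eff.gaze_mean_y), 0.12)
    speed_x = max(rng.normal(blend(eff_nt.gaze_speed_x, eff.gaze_speed_x), 0.20), 0.1)
    speed_y = max(rng.normal(blend(eff_nt.gaze_speed_y, eff.gaze_speed_y), 0.30), 0.1)
    sd_spread = 0.01 * np.sqrt(np.pi / 2)
    sd_x = max(rng.normal(blend(eff_nt.gaze_sd_x, eff.gaze_sd_x), sd_spread), 0.008)
    sd_y = max(rng.normal(blend(eff_nt.gaze_sd_y, eff.gaze_sd_y), sd_spread), 0.008)
    gx = _gaze_series(rng, n, spec.fps, mean_x, sd_x, speed_x, eff.gaze_drift)
    gy = _gaze_series(rng, n, spec.fps, mean_y, sd_y, speed_y, eff.gaze_drift)

    confidence = np.clip(rng.normal(0.99, 0.013, n), 0.0, 1.0)
    success = np.ones(n)
    dropout = rng.random(n) < 0.01
    success[dropout] = 0

    ft = _frame_table(person_id, ts, presence, intensity, gx, gy, confidence, success)

    # voice
    f0_mu_nt, f0_sd_nt = eff_nt.f0(gender)
    f0_mu_g, _ = eff.f0(gender)
    _, f0_sd_g = eff.f0(gender)
    f0_i = rng.normal(blend(f0_mu_nt, f0_mu_g), f0_sd_g if group == "ASD" else f0_sd_nt)
    f0_i = float(np.clip(f0_i, 70.0, 420.0))
    hnr_mu_nt, hnr_sd_nt = eff_nt.hnr(gender)
    hnr_mu_g, hnr_sd_g = eff.hnr(gender)
    hnr_i = float(rng.normal(blend(hnr_mu_nt, hnr_mu_g),
                             hnr_sd_g if group == "ASD" else hnr_sd_nt))
    jitter_i = eff.jitter * np.exp(0.3 * rng.standard_normal())
    shimmer_i = eff.shimmer * np.exp(0.3 * rng.standard_normal())
    wave = None
    if with_audio:
        wave = synthesize_voice(
            f0_i, jitter_i, shimmer_i, hnr_i, spec.audio_duration,
            spec.audio_rate, seed=np.random.default_rng(ss.spawn(1)[0]).integers(2**31),
        )

    age = float(rng.uniform(*eff.age_range))
    # severity: ADOS-like score scaling with the subject's effect multiplier
    if spec.severity_informative and group == "ASD":
        severity = 7.0 + 3.0 * g + rng.normal(0, 0.8)
    else:
        severity = 2.0 + abs(rng.normal(0, 1.0))

    info = {
        "group": group, "gender": gender, "age": age, "severity": severity,
        "effect_multiplier": g, "f0": f0_i, "hnr": hnr_i,
        "jitter": jitter_i, "shimmer": shimmer_i,
        "au12_occ_target": occ12, "mimicry_coupling": coupling,
    }
    return Participant(frames=ft, wave=wave, info=info)


@dataclass
class Cohort:
    """Bundle of one simulated cohort: shared actress track, per-subject
    frame tables and waves, and the metadata table."""

    spec: CohortSpec
    schedule: SegmentSchedule
    actress: FrameTable
    frames: dict[str, FrameTable]
    waves: dict[str, np.ndarray | None]
    metadata: pd.DataFrame


def simulate_cohort(
    spec: CohortSpec, sched: SegmentSchedule | None = None, with_audio: bool = True
) -> Cohort:
    """Simulate a full two-group cohort under one seed."""
    sched = sched or default_schedule()
    actress, latents = actress_reference(sched, seed=spec.seed, fps=spec.fps)
    root = np.random.SeedSequence([spec.seed, 4242])
    frames: dict[str, FrameTable] = {}
    waves: dict[str, np.ndarray | None] = {}
    rows = []
    child_seeds = root.spawn(2 * spec.n_per_group)
    k = 0
    for group in ("NT", "ASD"):
        n_female = int(round(spec.gender_mix * spec.n_per_group))
        genders = [FEMALE] * n_female + [MALE] * (spec.n_per_group - n_female)
        for j, gender in enumerate(genders):
            pid = f"{group}{j + 1:03d}"
            part = simulate_participant(
                spec, group, gender, latents, sched, child_seeds[k],
                person_id=pid, with_audio=with_audio,
            )
            k += 1
            frames[pid] = part.frames
            waves[pid] = part.wave
            rows.append({"subject_id": pid, "label": group, **part.info})
    meta = pd.DataFrame(rows).drop(columns=["group"])
    return Cohort(
        spec=spec, schedule=sched, actress=actress,
        frames=frames, waves=waves, metadata=meta,
    )


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write a cohort to disk: OpenFace-dialect CSVs, WAVs, metadata,
    and the schedule config."""
    import os

    from .openface import write_frame_table
    from .protocol import save_schedule
    from .voice import write_wav

    os.makedirs(out_dir, exist_ok=True)
    write_frame_table(cohort.actress, os.path.join(out_dir, "actress.csv"))
    for pid, ft in cohort.frames.items():
        write_frame_table(ft, os.path.join(out_dir, f"{pid}.csv"))
        wave = cohort.waves.get(pid)
        if wave is not None:
            write_wav(os.path.join(out_dir, f"{pid}.wav"), wave, cohort.spec.audio_rate)
    cohort.metadata.to_csv(os.path.join(out_dir, "metadata.csv"), index=False)
    save_schedule(cohort.schedule, os.path.join(out_dir, "schedule.yaml"))


def _logit(p: float) -> float:
    p = float(np.clip(p, 1e-6, 1 - 1e-6))
    return float(np.log(p / (1 - p)))


def _expit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))
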