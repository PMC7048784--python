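"""End-to-end orchestration: simulate/load → QC → extract → features →
group statistics → classification.

Every stage is a thin wrapper over the library modules and writes a tidy
artifact into the run directory:

``qc_report.csv``          participant tracking-quality report
``facial_biomarkers.csv``  per-(segment, AU) occurrence/intensity
``mimicry.csv``            lag-searched windowed mimicry correlations
``gaze_biomarkers.csv``    per-axis gaze kinematics
``voice_features.csv``     per-recording prosody summary
``features.csv``           subjects x secondary features (+ metadata)
``stats.csv``              univariate group statistics, Holm-adjusted
``cv_result.csv``          per-subject out-of-sample probabilities
``metrics.json``           classifier metrics + config hash
``roc.csv``                ROC curve points
``run.log``                stage log with seed and config hash

All randomness flows from the single root seed; a rerun with the same
configuration and seed reproduces the artifacts bit-for-bit (timing
information goes only to the log).
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd

from . import classify as clf
from . import facial, features, gaze, openface, simulate, stats, voice
from .protocol import WHOLE, SegmentSchedule, default_schedule


@dataclass
class RunConfig:
    out_dir: str = "run"
    input_dir: str | None = None  # cohort on disk; None → simulate
    schedule: str | None = None  # YAML schedule; None → default
    preset: str = "paper"  # simulate preset: paper | null
    n_per_group: int = 40
    seed: int = 0
    # QC thresholds
    conf_threshold: float = 0.75
    tracked_threshold: float = 0.90
    # mimicry
    mimicry_window: float = 10.0
    mimicry_lag_max: float = 3.0
    mimicry_lag_step: float = 0.25
    # voice
    fmin: float = 75.0
    fmax: float = 500.0
    audio_duration: float = 8.0
    # classifier
    modality: str = "combined"  # face | gaze | voice | combined
    grid: tuple = ((1, 2, 4, 8, 16, 32, 64), (1, 2, 4, 8, 16, 32, 64))
    n_trees: int = 1000
    inner_n_trees: int | None = None
    threshold: float = 0.5
    with_audio: bool = True

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output location is
        excluded, so reruns into different directories are comparable)."""
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Build a RunConfig from a YAML mapping of field names."""
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid" in cfg:
            cfg["grid"] = tuple(tuple(g) for g in cfg["grid"])
        return cls(**cfg)


def _log(fh, msg: str) -> None:
    fh.write(f"[{time.strftime('%H:%M:%S')}] {msg}\n")
    fh.flush()


def load_cohort_dir(input_dir: str, audio_rate: int = 16000) -> simulate.Cohort:
    """Read a cohort previously written with :func:`sitpipe.simulate.write_cohort`."""
    from .protocol import load_schedule

    meta = pd.read_csv(os.path.join(input_dir, "metadata.csv"))
    sched_path = os.path.join(input_dir, "schedule.yaml")
    sched = load_schedule(sched_path if os.path.exists(sched_path) else None)
    actress = openface.read_frame_table(os.path.join(input_dir, "actress.csv"), "actress")
    frames, waves = {}, {}
    for pid in meta["subject_id"]:
        frames[pid] = openface.read_frame_table(os.path.join(input_dir, f"{pid}.csv"), pid)
        wav_path = os.path.join(input_dir, f"{pid}.wav")
        if os.path.exists(wav_path):
            waves[pid], audio_rate = voice.read_wav(wav_path)
        else:
            waves[pid] = None
    spec = simulate.CohortSpec(
        n_per_group=max((meta["label"] == "NT").sum(), 2), audio_rate=audio_rate
    )
    return simulate.Cohort(
        spec=spec, schedule=sched, actress=actress,
        frames=frames, waves=waves, metadata=meta,
    )


def _write_csv(df: pd.DataFrame, path: str, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def group_statistics(
    summaries: pd.DataFrame,
    mimicry: pd.DataFrame,
    gaze_tab: pd.DataFrame,
    voice_tab: pd.DataFrame | None,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """The headline univariate comparisons with Holm correction per family.

    Between groups: whole-conversation AU12/AU6 occurrence and intensity
    (social smiling), positive-part AU12 occurrence, negative-part AU4
    intensity, AU6 mimicry, the eight gaze features; paired within
    subjects: positive-vs-neutral AU12/AU6 activity; for voice, the
    group x gender ANOVA on F0 mean and HNR median.
    """
    meta_idx = meta.set_index("subject_id")
    is_asd = meta_idx["label"] == "ASD"

    def split(series: pd.Series):
        asd = series[series.index.map(is_asd).fillna(False)].dropna()
        nt = series[~series.index.map(is_asd).fillna(True)].dropna()
        return asd.to_numpy(), nt.to_numpy()

    rows = []

    def add(family, feature, res: stats.GroupTestResult):
        rows.append({
            "family": family, "feature": feature, "test": res.test_name,
            "statistic": res.statistic, "p": res.p, "effect_size": res.effect_size,
        })

    piv = summaries.pivot_table(
        index="person_id", columns=["segment", "au"],
        values=["occurrence", "intensity"],
    )
    face_contrasts = [
        ("AU12_occ_whole", ("occurrence", WHOLE, "AU12")),
        ("AU12_int_whole", ("intensity", WHOLE, "AU12")),
        ("AU6_occ_whole", ("occurrence", WHOLE, "AU06")),
        ("AU6_int_whole", ("intensity", WHOLE, "AU06")),
        ("AU12_occ_positive", ("occurrence", "positive_answer", "AU12")),
        ("AU4_int_negative", ("intensity", "negative_answer", "AU04")),
    ]
    for name, key in face_contrasts:
        if key not in piv.columns:
            continue
        asd, nt = split(piv[key])
        if len(asd) >= 2 and len(nt) >= 2:
            add("face", name, stats.mann_whitney(asd, nt))

    # paired part-vs-neutral contrasts across all subjects
    for name, stat, au in [
        ("AU12_int_pos_vs_neu", "intensity", "AU12"),
        ("AU6_int_pos_vs_neu", "intensity", "AU06"),
        ("AU12_occ_pos_vs_neu", "occurrence", "AU12"),
    ]:
        pos_key = (stat, "positive_answer", au)
        neu_key = (stat, "neutral_answer", au)
        if pos_key in piv.columns and neu_key in piv.columns:
            paired = piv[[pos_key, neu_key]].dropna()
            if len(paired) >= 3:
                add("face", name,
                    stats.wilcoxon_signed(paired[pos_key].to_numpy(),
                                          paired[neu_key].to_numpy()))

    if mimicry is not None and len(mimicry):
        au6 = mimicry[mimicry["au"] == "AU06"].set_index("person_id")["score"]
        asd, nt = split(au6)
        if len(asd) >= 2 and len(nt) >= 2:
            add("face", "mimicry_AU6", stats.mann_whitney(asd, nt))

    gz = gaze_tab.pivot_table(index="person_id", columns="axis")
    for col in gz.columns:
        asd, nt = split(gz[col])
        if len(asd) >= 2 and len(nt) >= 2:
            add("gaze", f"{col[0]}_{col[1]}", stats.mann_whitney(asd, nt))

    if voice_tab is not None and len(voice_tab):
        vt = voice_tab.set_index("person_id")
        groups = vt.index.map(meta_idx["label"])
        genders = vt.index.map(meta_idx["gender"])
        for feat in ("f0_mean", "hnr_median"):
            if feat not in vt.columns:
                continue
            ok = vt[feat].notna()
            try:
                res = stats.anova_group_gender(
                    vt.loc[ok, feat], groups[ok], genders[ok]
                )
            except ValueError:
                continue
            add("voice", f"{feat}_group", res["group"])
            add("voice", f"{feat}_gender", res["gender"])
        for feat in ("jitter_local", "shimmer_local", "rms_energy"):
            if feat in vt.columns:
                asd, nt = split(vt[feat])
                if len(asd) >= 2 and len(nt) >= 2:
                    add("voice", feat, stats.mann_whitney(asd, nt))

    out = pd.DataFrame(rows)
    if len(out):
        out["adjusted_p"] = np.nan
        for fam in out["family"].unique():
            m = out["family"] == fam
            out.loc[m, "adjusted_p"] = stats.holm_correct(out.loc[m, "p"].to_numpy())
    return out


def extract_cohort_features(
    cohort: simulate.Cohort, cfg: RunConfig, qc_pass: list[str]
):
    """Run all extractors over QC-passing participants.

    Returns (summaries, mimicry, gaze table, voice table, FeatureMatrix).
    """
    sched = cohort.schedule
    lag_grid = np.arange(0.0, cfg.mimicry_lag_max + 1e-9, cfg.mimicry_lag_step)
    actress_f = openface.filter_frames(cohort.actress, cfg.conf_threshold)

    summaries, mim_rows, gaze_rows, voice_rows = [], [], [], []
    face_vecs, gaze_vecs, voice_vecs = {}, {}, {}
    meta = cohort.metadata.set_index("subject_id")
    for pid in qc_pass:
        ft = openface.filter_frames(cohort.frames[pid], cfg.conf_threshold)
        gender = int(meta.loc[pid, "gender"])
        summaries.append(facial.au_segment_summary(ft, sched))
        mim_rows.append(facial.mimicry_table(ft, actress_f,
                                             window=cfg.mimicry_window,
                                             lag_grid=lag_grid))
        gaze_rows.append(gaze.gaze_kinematics_table(ft))
        face_vecs[pid] = features.build_face_features(ft, sched, gender)
        gaze_vecs[pid] = features.build_gaze_features(ft, sched, gender)
        wave = cohort.waves.get(pid)
        if cfg.with_audio and wave is not None:
            vf = voice.voice_summary(wave, cohort.spec.audio_rate,
                                     fmin=cfg.fmin, fmax=cfg.fmax)
            voice_vecs[pid] = features.build_voice_features(vf, gender)
            row = vf.as_series()
            row["person_id"] = pid
            voice_rows.append(row)

    summaries = pd.concat(summaries, ignore_index=True)
    mimicry = pd.concat(mim_rows, ignore_index=True)
    gaze_tab = pd.concat(gaze_rows, ignore_index=True)
    voice_tab = pd.DataFrame(voice_rows) if voice_rows else None

    fmeta = (
        meta.loc[qc_pass]
        .reset_index()[["subject_id", "label", "gender", "age"]]
    )
    face_fm = features.assemble_block(face_vecs, fmeta)
    gaze_fm = features.assemble_block(gaze_vecs, fmeta)
    voice_fm = features.assemble_block(voice_vecs, fmeta) if voice_vecs else None
    blocks = [face_fm, gaze_fm] + ([voice_fm] if voice_fm is not None else [])
    combined = features.combine(*blocks)
    fms = {"face": face_fm, "gaze": gaze_fm, "voice": voice_fm, "combined": combined}
    return summaries, mimicry, gaze_tab, voice_tab, fms


def run_pipeline(cfg: RunConfig, cohort: simulate.Cohort | None = None) -> str:
    """Execute the full workflow; returns the run directory path."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    cfg_hash = cfg.config_hash()
    log_path = os.path.join(cfg.out_dir, "run.log")
    with open(log_path, "w") as log:
        _log(log, f"run start seed={cfg.seed} config_hash={cfg_hash}")

        if cohort is None:
            if cfg.input_dir:
                _log(log, f"loading cohort from {cfg.input_dir}")
                cohort = load_cohort_dir(cfg.input_dir)
            else:
                _log(log, f"simulating cohort preset={cfg.preset} n={cfg.n_per_group}")
                from .protocol import load_schedule

                maker = simulate.null_preset if cfg.preset == "null" else simulate.paper_preset
                spec = maker(n_per_group=cfg.n_per_group, seed=cfg.seed,
                             audio_duration=cfg.audio_duration)
                cohort = simulate.simulate_cohort(
                    spec, sched=load_schedule(cfg.schedule),
                    with_audio=cfg.with_audio,
                )

        # --- QC
        qc_reports = [
            openface.participant_qc(ft, cfg.conf_threshold, cfg.tracked_threshold)
            for ft in cohort.frames.values()
        ]
        qc_df = pd.DataFrame([vars(r) for r in qc_reports])
        _write_csv(qc_df, os.path.join(cfg.out_dir, "qc_report.csv"), cfg_hash)
        qc_pass = qc_df.loc[qc_df["included"], "person_id"].tolist()
        _log(log, f"qc: {len(qc_pass)}/{len(qc_df)} participants retained")
        if len(qc_pass) < 4:
            raise RuntimeError("qc: fewer than 4 participants retained")

        # --- extraction + features
        summaries, mimicry, gaze_tab, voice_tab, fms = extract_cohort_features(
            cohort, cfg, qc_pass
        )
        _write_csv(summaries, os.path.join(cfg.out_dir, "facial_biomarkers.csv"), cfg_hash)
        _write_csv(mimicry, os.path.join(cfg.out_dir, "mimicry.csv"), cfg_hash)
        _write_csv(gaze_tab, os.path.join(cfg.out_dir, "gaze_biomarkers.csv"), cfg_hash)
        if voice_tab is not None:
            vt = voice_tab.reset_index(drop=True)
            cols = ["person_id"] + [c for c in vt.columns if c != "person_id"]
            _write_csv(vt[cols], os.path.join(cfg.out_dir, "voice_features.csv"), cfg_hash)
        fm = fms[cfg.modality if cfg.modality in fms else "combined"]
        if fm is None:
            raise RuntimeError(f"modality {cfg.modality!r} unavailable (no audio?)")
        _write_csv(fms["combined"].to_frame(),
                   os.path.join(cfg.out_dir, "features.csv"), cfg_hash)
        _log(log, f"features: {fms['combined'].n_subjects} subjects x "
                  f"{fms['combined'].data.shape[1]} columns")

        # --- group statistics
        stats_df = group_statistics(summaries, mimicry, gaze_tab, voice_tab,
                                    cohort.metadata)
        _write_csv(stats_df, os.path.join(cfg.out_dir, "stats.csv"), cfg_hash)
        _log(log, f"stats: {len(stats_df)} tests")

        # --- classification
        cv = clf.loo_nested_cv(fm, grid=cfg.grid, n_trees=cfg.n_trees,
                               seed=cfg.seed, inner_n_trees=cfg.inner_n_trees)
        _write_csv(cv.to_frame(), os.path.join(cfg.out_dir, "cv_result.csv"), cfg_hash)
        _write_csv(clf.roc_curve_points(cv.probabilities, cv.labels),
                   os.path.join(cfg.out_dir, "roc.csv"), cfg_hash)

        metrics = cv.metrics()
        baseline = clf.majority_vote_predictions(cv.labels)
        metrics["mcnemar_vs_majority"] = clf.mcnemar_vs_baseline(
            cv.predictions, baseline, cv.labels
        )
        if "severity" in cohort.metadata.columns:
            sev = cohort.metadata.set_index("subject_id").loc[
                cv.subject_ids, "severity"
            ].to_numpy(float)
            if np.std(sev) > 0 and np.std(cv.probabilities) > 0:
                metrics["severity_correlation"] = clf.severity_correlation(
                    cv.probabilities, sev
                )
        metrics["seed"] = cfg.seed
        metrics["modality"] = cfg.modality
        metrics["config_hash"] = cfg_hash
        with open(os.path.join(cfg.out_dir, "metrics.json"), "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
        _log(log, f"classify: auc={metrics['auc']:.3f} "
                  f"accuracy={metrics['accuracy']:.3f}")
        _log(log, "run complete")
    return cfg.out_dir
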