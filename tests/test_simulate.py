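"""Synthetic-cohort generator: determinism, construction, calibration."""

import numpy as np
import pytest

from sitpipe import simulate as sim
from sitpipe.facial import mimicry_correlation
from sitpipe.protocol import default_schedule, slice_segment


@pytest.fixture(scope="module")
def sched():
    return default_schedule()


@pytest.fixture(scope="module")
def actress(sched):
    return sim.actress_reference(sched, seed=5)


class TestActress:
    def test_same_seed_bit_identical(self, sched, actress):
        ft2, _ = sim.actress_reference(sched, seed=5)
        ft, _ = actress
        assert ft.frames.equals(ft2.frames)

    def test_smiles_more_in_positive_than_negative(self, sched, actress):
        ft, _ = actress
        pos = slice_segment(ft, sched, "positive_listen").intensity("AU12").mean()
        neg = slice_segment(ft, sched, "negative_listen").intensity("AU12").mean()
        assert pos > neg

    def test_frowns_in_negative_excerpt(self, sched, actress):
        ft, _ = actress
        neg = slice_segment(ft, sched, "negative_listen").intensity("AU04").mean()
        neu = slice_segment(ft, sched, "neutral_listen").intensity("AU04").mean()
        assert neg > neu

    def test_frame_table_invariants(self, actress):
        ft, _ = actress
        assert np.all(np.diff(ft.timestamps) > 0)
        for au in ("AU12", "AU04"):
            assert set(np.unique(ft.presence(au))) <= {0.0, 1.0}
            assert ft.intensity(au).min() >= 0


class TestParticipant:
    def test_same_seed_identical(self, sched, actress):
        _, lat = actress
        spec = sim.paper_preset(n_per_group=2)
        a = sim.simulate_participant(spec, "ASD", 1, lat, sched, 42, with_audio=False)
        b = sim.simulate_participant(spec, "ASD", 1, lat, sched, 42, with_audio=False)
        assert a.frames.frames.equals(b.frames.frames)
        assert a.info == b.info

    def test_full_coupling_yields_near_perfect_mimicry(self, sched, actress):
        ft_act, lat = actress
        eff = sim.NT_EFFECTS.__class__(**{**vars(sim.NT_EFFECTS), "mimicry_coupling": 1.0})
        spec = sim.CohortSpec(
            n_per_group=2, reaction_lag=0.0,
            effects={"NT": eff, "ASD": sim.ASD_EFFECTS},
        )
        part = sim.simulate_participant(spec, "NT", 1, lat, sched, 3, with_audio=False)
        ms = mimicry_correlation(part.frames, ft_act, "AU12", lag_grid=(0.0,))
        assert ms.score > 0.85

    def test_zero_coupling_mimicry_centers_on_zero(self, sched, actress):
        ft_act, lat = actress
        eff = sim.NT_EFFECTS.__class__(**{**vars(sim.NT_EFFECTS), "mimicry_coupling": 0.0})
        spec = sim.CohortSpec(n_per_group=2, effects={"NT": eff, "ASD": sim.ASD_EFFECTS})
        scores = []
        for seed in range(40):
            part = sim.simulate_participant(
                spec, "NT", 0, lat, sched, 1000 + seed, with_audio=False
            )
            ms = mimicry_correlation(part.frames, ft_act, "AU12", lag_grid=(0.0,))
            scores.append(ms.score)
        scores = np.asarray(scores)
        se = scores.std(ddof=1) / np.sqrt(len(scores))
        # per-subject coupling jitter (sd 0.06, clipped at 0) adds a small
        # positive offset; the mean must stay near zero
        assert abs(scores.mean()) < 0.06 + 3 * se

    def test_occurrence_calibration(self, sched, actress):
        """Whole-conversation AU12 occurrence hits its target on average."""
        _, lat = actress
        spec = sim.paper_preset(n_per_group=2)
        occs = []
        for seed in range(30):
            part = sim.simulate_participant(
                spec, "NT", 1, lat, sched, 2000 + seed, with_audio=False
            )
            occs.append(part.frames.presence("AU12").mean())
        assert np.mean(occs) == pytest.approx(0.40, abs=0.05)

    def test_infeasible_occurrence_target_rejected(self):
        with pytest.raises(ValueError):
            sim.GroupEffects(**{**vars(sim.NT_EFFECTS), "au12_occ": 1.5})

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            sim.CohortSpec(n_per_group=1)


class TestVoiceSynthesis:
    def test_same_seed_identical_wave(self):
        a = sim.synthesize_voice(180, 0.01, 0.05, 15, 1.0, 16000, seed=9)
        b = sim.synthesize_voice(180, 0.01, 0.05, 15, 1.0, 16000, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_out_of_range_f0_rejected(self):
        with pytest.raises(ValueError):
            sim.synthesize_voice(700, 0, 0, 20, 1.0, 16000)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sim.synthesize_voice(200, 0, 0, 20, 0.2, 16000)


class TestCohort:
    def test_metadata_row_count_and_determinism(self):
        spec = sim.paper_preset(n_per_group=3, seed=8)
        a = sim.simulate_cohort(spec, with_audio=False)
        b = sim.simulate_cohort(spec, with_audio=False)
        assert len(a.metadata) == 6
        assert a.metadata.equals(b.metadata)
        pid = a.metadata.subject_id.iloc[0]
        assert a.frames[pid].frames.equals(b.frames[pid].frames)

    def test_severity_tracks_effect_multiplier(self):
        spec = sim.paper_preset(n_per_group=25, seed=3)
        coh = sim.simulate_cohort(spec, with_audio=False)
        asd = coh.metadata[coh.metadata.label == "ASD"]
        r = np.corrcoef(asd.severity, asd.effect_multiplier)[0, 1]
        assert r > 0.5

    def test_null_preset_groups_exchangeable(self):
        from scipy.stats import ks_2samp

        spec = sim.null_preset(n_per_group=15, seed=21)
        coh = sim.simulate_cohort(spec, with_audio=False)
        meta = coh.metadata.set_index("subject_id")
        feats = {
            "au12_occ": lambda ft: ft.presence("AU12").mean(),
            "au4_int": lambda ft: ft.intensity("AU04").mean(),
            "gaze_sd": lambda ft: ft.frames["gaze_angle_x"].std(),
        }
        for name, fn in feats.items():
            vals = {pid: fn(ft) for pid, ft in coh.frames.items()}
            asd = [v for p, v in vals.items() if meta.loc[p, "label"] == "ASD"]
            nt = [v for p, v in vals.items() if meta.loc[p, "label"] == "NT"]
            assert ks_2samp(asd, nt).pvalue > 0.01, name

    def test_write_cohort_round_trip(self, tmp_path):
        from sitpipe.pipeline import load_cohort_dir

        spec = sim.paper_preset(n_per_group=2, seed=4, audio_duration=0.6)
        coh = sim.simulate_cohort(spec, with_audio=True)
        sim.write_cohort(coh, tmp_path)
        back = load_cohort_dir(str(tmp_path))
        assert set(back.frames) == set(coh.frames)
        pid = coh.metadata.subject_id.iloc[0]
        np.testing.assert_allclose(
            back.frames[pid].frames["AU12_r"], coh.frames[pid].frames["AU12_r"],
            atol=1e-6,
        )
        assert back.waves[pid] is not None
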