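"""The synthetic-speech generator: determinism, ground truth, and fixtures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phonoscope.synth import (
    CohortSpec,
    UtteranceSpec,
    random_pause_schedule,
    synth_cohort,
    synth_feature_table,
    synth_symptom_scores,
    synth_utterance,
)


class TestUtteranceSpec:
    def test_overlapping_pauses_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            UtteranceSpec(duration_s=10.0, pause_schedule=[(1.0, 3.0), (2.0, 4.0)])

    def test_pause_outside_duration_rejected(self):
        with pytest.raises(ValueError):
            UtteranceSpec(duration_s=5.0, pause_schedule=[(4.0, 6.0)])

    def test_noise_mix_bounds(self):
        with pytest.raises(ValueError):
            UtteranceSpec(noise_mix=1.5)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 1000),
        n_pauses=st.integers(1, 8),
        dur=st.floats(20.0, 60.0),
    )
    def test_random_schedules_are_valid(self, seed, n_pauses, dur):
        rng = np.random.default_rng(seed)
        sched = random_pause_schedule(dur, n_pauses, 0.7, 0.2, rng)
        assert len(sched) == n_pauses
        last = 0.0
        for s, e in sched:
            assert s >= last and e > s and e <= dur
            last = e

    def test_infeasible_schedule_raises(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="cannot fit"):
            random_pause_schedule(10.0, 20, 2.0, 0.0, rng)


class TestUtterance:
    def test_ground_truth_records_construction(self):
        sched = [(2.0, 2.5), (5.0, 5.6)]
        spec = UtteranceSpec(duration_s=10.0, pause_schedule=sched, seed=1)
        sample, gt = synth_utterance(spec)
        assert gt.pause_count == 2
        assert gt.pause_schedule == sched
        assert gt.speech_time_s == pytest.approx(10.0 - 1.1)
        assert sample.duration == pytest.approx(10.0)
        assert np.max(np.abs(sample.samples)) <= 1.0

    def test_same_seed_is_bit_identical(self):
        spec = UtteranceSpec(duration_s=3.0, pause_schedule=[], seed=9)
        a1, _ = synth_utterance(spec)
        a2, _ = synth_utterance(spec)
        np.testing.assert_array_equal(a1.samples, a2.samples)

    def test_pauses_are_silent(self):
        spec = UtteranceSpec(duration_s=6.0, pause_schedule=[(2.0, 3.0)], seed=2)
        sample, _ = synth_utterance(spec)
        seg = sample.samples[int(2.05 * 16000) : int(2.95 * 16000)]
        assert np.abs(seg).max() == 0.0


class TestCohort:
    def test_default_design_shape(self):
        spec = CohortSpec(n_participants=2, duration_s=8.0, master_seed=0)
        corpus, meta = synth_cohort(spec)
        assert len(corpus) == 3 * 2 * 4
        assert meta["participant_id"].nunique() == 6
        assert set(meta["group"]) == {"HC", "MDD", "SSD"}
        assert (meta.groupby("participant_id").size() == 4).all()

    def test_master_seed_reproduces_metadata_exactly(self):
        spec = CohortSpec(n_participants=2, duration_s=8.0, master_seed=5)
        _, m1 = synth_cohort(spec)
        _, m2 = synth_cohort(spec)
        pd.testing.assert_frame_equal(m1, m2)

    def test_patient_groups_have_planted_pause_deficit(self):
        spec = CohortSpec(n_participants=8, duration_s=30.0, master_seed=3)
        _, meta = synth_cohort(spec)
        gm = meta.groupby("group")["true_ppm"].mean()
        assert gm["MDD"] < gm["HC"]
        assert gm["SSD"] < gm["HC"]

    def test_wav_corpus_written(self, tmp_path):
        spec = CohortSpec(n_participants=1, duration_s=6.0, master_seed=1)
        corpus, _ = synth_cohort(spec, out_dir=tmp_path)
        wavs = list(tmp_path.glob("*.wav"))
        assert len(wavs) == 12
        assert (tmp_path / "metadata.csv").exists()
        from phonoscope.audio_io import read_audio

        back = read_audio(wavs[0])
        assert back.duration == pytest.approx(6.0, abs=0.01)


class TestFeatureTableFixture:
    def test_shape_and_metadata(self):
        table = synth_feature_table(5, {"HC": np.zeros(38), "MDD": np.ones(38)}, seed=0)
        assert len(table) == 2 * 5 * 4
        assert table.groupby("participant_id").size().eq(4).all()

    def test_effect_vector_shifts_group_mean(self):
        vec = np.zeros(38)
        vec[0] = 2.0
        table = synth_feature_table(40, {"HC": np.zeros(38), "MDD": vec}, seed=1)
        col = table.columns[3]
        diff = table.loc[table["group"] == "MDD", col].mean() - table.loc[
            table["group"] == "HC", col
        ].mean()
        assert diff == pytest.approx(2.0, abs=0.3)

    def test_within_participant_correlation_is_planted(self):
        table = synth_feature_table(
            60, {"HC": np.zeros(38)}, within_participant_rho=0.8, seed=2
        )
        col = table.columns[3]
        wide = table.pivot_table(index="participant_id", columns="picture_id", values=col)
        r = np.corrcoef(wide[1], wide[2])[0, 1]
        assert r == pytest.approx(0.8, abs=0.15)

    def test_wrong_effect_length_raises(self):
        with pytest.raises(ValueError, match="length 38"):
            synth_feature_table(4, {"HC": np.zeros(5)})


class TestSymptomScores:
    def _table(self, seed=0, n=20):
        return synth_feature_table(n, {"SSD": np.zeros(38), "HC": np.zeros(38)}, seed=seed)

    def test_null_target_gives_near_zero_correlation(self):
        rs = []
        for seed in range(10):
            table = self._table(seed)
            scores = synth_symptom_scores(table, {}, seed=seed)
            merged = table.join(scores, on="participant_id")
            pm = merged.groupby("participant_id").mean(numeric_only=True)
            rs.append(np.corrcoef(pm["lhr_sd"], pm["HAMD"])[0, 1])
        assert abs(np.mean(rs)) < 0.15

    def test_extreme_target_is_nearly_perfect(self):
        table = self._table(0, n=30)
        scores = synth_symptom_scores(table, {("SANS", "SSD"): ("acf1", 0.99)}, seed=0)
        merged = table.join(scores, on="participant_id")
        pm = merged[merged["group"] == "SSD"].groupby("participant_id").mean(numeric_only=True)
        assert abs(np.corrcoef(pm["acf1"], pm["SANS"])[0, 1]) > 0.9

    def test_scores_are_constant_within_participant(self):
        table = self._table(1)
        scores = synth_symptom_scores(table, seed=1)
        merged = table.join(scores, on="participant_id")
        assert (merged.groupby("participant_id")["HAMD"].nunique() == 1).all()

    def test_invalid_target_r_raises(self):
        table = self._table(2)
        with pytest.raises(ValueError):
            synth_symptom_scores(table, {("HAMD", "SSD"): ("ppm", 1.0)}, seed=0)
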