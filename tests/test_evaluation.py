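"""Period labeling, the TP-FP metric and the pseudo-online loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import smrdecode as sd
from smrdecode.evaluation import DecoderConfig, eeg_grid, emg_grid, run_design_grid
from smrdecode.windows import BOUNDARY, MOVE, REST


class TestLabelPeriods:
    def test_per_trial_frame_counts(self, default_session, short_protocol):
        labels = sd.label_periods(default_session)
        n_trials = short_protocol.n_trials
        # move frames fully inside each 5 s task period: floor(4500/40)+1 = 113
        assert int(np.sum(labels == MOVE)) == 113 * n_trials
        # rest frames fully inside each 3 s ITI: floor(2500/40)+1 = 63
        assert int(np.sum(labels == REST)) == 63 * n_trials

    def test_cue_straddling_frames_are_boundary(self, default_session):
        labels = sd.label_periods(default_session)
        fs = default_session.fs
        starts = np.arange(labels.size) * 20
        for go, _ in default_session.task_spans()[:3]:
            go_s = int(round(go * fs))
            straddle = (starts < go_s) & (starts + 250 > go_s)
            assert np.all(labels[straddle] == BOUNDARY)
            after = starts == go_s
            assert np.all(labels[after] == MOVE)

    def test_unsorted_events_rejected(self, default_session):
        from smrdecode.windows import label_frames

        with pytest.raises(ValueError):
            label_frames(np.array([2.0, 1.0]), np.array(["go", "end"]), 5000)


class TestComputeTpFp:
    def _labels(self, n_move=500, n_rest=500):
        return np.concatenate([np.full(n_move, MOVE, np.int8),
                               np.full(n_rest, REST, np.int8)])

    def test_perfect_predictions_score_one(self):
        labels = self._labels()
        tp, fp, score = sd.compute_tp_fp(labels.copy(), labels)
        assert (tp, fp, score) == (1.0, 0.0, 1.0)

    def test_constant_move_predictions_score_zero(self):
        labels = self._labels()
        tp, fp, score = sd.compute_tp_fp(np.full(labels.size, MOVE), labels)
        assert tp == 1.0 and fp == 1.0 and score == 0.0

    def test_random_predictions_near_zero(self, rng):
        labels = self._labels(5000, 5000)
        preds = rng.integers(0, 2, labels.size)
        _, _, score = sd.compute_tp_fp(preds, labels)
        assert abs(score) < 0.05

    def test_boundary_frames_excluded(self):
        labels = np.array([MOVE, BOUNDARY, REST], np.int8)
        preds = np.array([MOVE, MOVE, REST], np.int8)
        tp, fp, score = sd.compute_tp_fp(preds, labels)
        assert (tp, fp, score) == (1.0, 0.0, 1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_antisymmetry_under_prediction_flip(self, seed):
        rng = np.random.default_rng(seed)
        labels = self._labels(200, 300)
        preds = rng.integers(0, 2, labels.size).astype(np.int8)
        _, _, s = sd.compute_tp_fp(preds, labels)
        _, _, s_flip = sd.compute_tp_fp(1 - preds, labels)
        assert s_flip == pytest.approx(-s, abs=1e-12)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            sd.compute_tp_fp(np.array([MOVE]), np.array([MOVE]))


class TestDecoderConfig:
    def test_grid_sizes(self):
        assert len(eeg_grid()) == 54
        assert len(emg_grid()) == 12
        assert len(sd.full_grid()) == 66

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            DecoderConfig(modality="eeg", spatial_filter="csp")
        with pytest.raises(ValueError):
            DecoderConfig(modality="eeg", band="gamma")
        with pytest.raises(ValueError):
            DecoderConfig(modality="emg", arm_set="left", muscle_set="all_four")
        with pytest.raises(ValueError):
            DecoderConfig(modality="emg", arm_set="both", muscle_set="all_four",
                          band="beta")
        with pytest.raises(ValueError):
            DecoderConfig(modality="meg")


class TestRunPseudoOnline:
    def test_unmodulated_session_scores_near_zero(self, flat_session):
        config = DecoderConfig(modality="eeg", electrode_set="bihemispheric",
                               spatial_filter="car", band="beta",
                               classifier="threshold")
        res = sd.run_pseudo_online(flat_session, config)
        assert abs(res.score) < 0.15
        assert res.score == res.tp - res.fp

    def test_informative_session_beats_chance(self, default_session):
        config = DecoderConfig(modality="eeg", electrode_set="bihemispheric",
                               spatial_filter="car", band="beta",
                               classifier="asvm")
        res = sd.run_pseudo_online(default_session, config)
        assert res.score > 0.3

    def test_deterministic(self, default_session):
        config = DecoderConfig(classifier="asvm")
        a = sd.run_pseudo_online(default_session, config)
        b = sd.run_pseudo_online(default_session, config)
        assert (a.tp, a.fp) == (b.tp, b.fp)

    def test_trial_permuted_labels_score_near_zero(self, default_session):
        """Permuting period labels at the trial level destroys the score."""
        from smrdecode import windows
        from smrdecode.decoders import SmrThresholdDecoder

        frames = sd.extract_eeg_features(default_session, "car",
                                         "bihemispheric", "beta")
        labels = frames.labels.copy()
        rng = np.random.default_rng(0)
        slices = windows.period_slices(labels)
        perm = rng.permutation([lab for lab, _, _ in slices])
        for (lab, a, b), new in zip(slices, perm):
            labels[a:b] = new
        pred = SmrThresholdDecoder().stream(frames.matrix(), labels)
        try:
            _, _, score = sd.compute_tp_fp(pred, labels)
            assert abs(score) < 0.2
        except ValueError:
            pass  # a permutation may produce a single-class labeling

    def test_gated_metric_variant(self, default_session):
        config = DecoderConfig(classifier="threshold")
        raw = sd.run_pseudo_online(default_session, config, metric="output")
        gated = sd.run_pseudo_online(default_session, config, metric="gated")
        assert -1.0 <= gated.score <= 1.0
        assert gated.score == pytest.approx(raw.score, abs=0.3)


@pytest.fixture(scope="module")
def tiny_sessions():
    protocol = sd.TrialProtocol(trials_per_block=3, blocks_per_session=1)
    return list(sd.synthetic_cohort(2, 1, protocol, seed=77))


class TestRunDesignGrid:

    def test_full_eeg_grid_row_count(self, tiny_sessions):
        res = run_design_grid(tiny_sessions, eeg_grid())
        assert len(res) == 108  # 2 sessions x 54 cells
        for col in ("patient", "session", "electrode_set", "spatial_filter",
                    "band", "classifier", "tp", "fp", "score"):
            assert col in res.columns
        assert np.allclose(res.score, res.tp - res.fp)

    def test_restricted_grid(self, tiny_sessions):
        configs = [DecoderConfig(classifier=c) for c in ("threshold", "asvm")]
        res = run_design_grid(tiny_sessions[:1], configs)
        assert len(res) == 2
        assert set(res.classifier) == {"threshold", "asvm"}

    def test_grid_matches_single_runs(self, tiny_sessions):
        config = DecoderConfig(modality="eeg", electrode_set="ipsilesional",
                               spatial_filter="laplacian", band="alpha",
                               classifier="threshold")
        res = run_design_grid(tiny_sessions[:1], [config])
        single = sd.run_pseudo_online(tiny_sessions[0], config)
        assert res.iloc[0].tp == pytest.approx(single.tp)
        assert res.iloc[0].fp == pytest.approx(single.fp)
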