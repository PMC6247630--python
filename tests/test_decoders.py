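"""Decoder behavior: threshold classifier, adaptive SVM, orthosis gate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import smrdecode as sd
from smrdecode._svm import batch_svm
from smrdecode.decoders import AdaptiveSvmDecoder, OrthosisGate, SmrThresholdDecoder
from smrdecode.windows import BOUNDARY, MOVE, REST


class TestThresholdDecoder:
    def _stream(self, *periods):
        """Build (X, labels) from (label, value, n_frames) periods."""
        X, labels = [], []
        for label, value, n in periods:
            X.extend([value] * n)
            labels.extend([label] * n)
        return np.array(X)[:, None], np.array(labels, np.int8)

    def test_midpoint_threshold_after_one_trial_each(self):
        dec = SmrThresholdDecoder()
        X, y = self._stream((REST, 2.0, 5), (MOVE, 4.0, 5))
        dec.stream(X, y)
        assert dec.threshold_ == pytest.approx(3.0)

    def test_running_mean_update(self):
        dec = SmrThresholdDecoder()
        X, y = self._stream((REST, 2.0, 5), (MOVE, 4.0, 5), (MOVE, 6.0, 5))
        dec.stream(X, y)
        # move history mean (4+6)/2 = 5 -> threshold (2+5)/2 = 3.5
        assert dec.threshold_ == pytest.approx(3.5)

    def test_classification_side_and_tie_rule(self):
        dec = SmrThresholdDecoder(modulation="erd")
        X, y = self._stream((REST, 4.0, 5), (MOVE, 2.0, 5))
        dec.stream(X, y)
        assert dec.threshold_ == pytest.approx(3.0)
        assert dec.predict([[2.5]])[0] == MOVE
        assert dec.predict([[3.0]])[0] == REST  # exact tie -> rest
        assert dec.predict([[3.5]])[0] == REST

    def test_polarity_flip_inverts_nontied_outputs(self, rng):
        X, y = self._stream((REST, 4.0, 8), (MOVE, 2.0, 8), (REST, 4.2, 8),
                            (MOVE, 1.8, 8))
        X = X + 0.01 * rng.standard_normal(X.shape)
        erd = SmrThresholdDecoder(modulation="erd").stream(X, y)
        ers = SmrThresholdDecoder(modulation="ers").stream(X, y)
        ready = np.arange(len(y)) >= 16  # after both histories exist
        assert np.all(erd[ready] != ers[ready])

    def test_rest_only_history_emits_rest(self):
        dec = SmrThresholdDecoder()
        X, y = self._stream((REST, 2.0, 5), (REST, 2.5, 5))
        pred = dec.stream(X, y)
        assert dec.threshold_ is None
        assert np.all(pred == REST)

    def test_threshold_between_class_means(self, default_session):
        frames = sd.extract_eeg_features(default_session, "car",
                                         "bihemispheric", "beta")
        dec = SmrThresholdDecoder()
        dec.stream(frames.matrix(), frames.labels)
        lo = min(np.mean(dec.rest_history_), np.mean(dec.move_history_))
        hi = max(np.mean(dec.rest_history_), np.mean(dec.move_history_))
        assert lo <= dec.threshold_ <= hi


def _labeled_stream(rng, n, d, sep=0.5, drift_sd=0.0, block=(40, 10, 45, 5)):
    """Synthetic feature stream with rest/boundary/move period structure and
    an optional common random-walk drift along the discriminant direction."""
    labels = np.zeros(n, np.int8)
    r, b1, m, b2 = block
    period = r + b1 + m + b2
    for k in range(0, n, period):
        labels[k:k + r] = REST
        labels[k + r:k + r + b1] = BOUNDARY
        labels[k + r + b1:k + r + b1 + m] = MOVE
        labels[k + r + b1 + m:k + period] = BOUNDARY
    X = rng.standard_normal((n, d))
    X[:, 0] += sep * (labels == MOVE)
    if drift_sd > 0:
        drift = np.cumsum(rng.normal(0.0, drift_sd, n))
        X[:, 0] += drift
    return X, labels


class TestAdaptiveSvmDecoder:
    def test_warmup_predicts_rest(self, rng):
        X, labels = _labeled_stream(rng, 200, 4)
        dec = AdaptiveSvmDecoder(min_fill=1000)
        pred = dec.stream(X, labels)
        assert not dec.is_ready
        assert np.all(pred == REST)

    def test_separable_buffers_classified_perfectly(self, rng):
        dec = AdaptiveSvmDecoder(min_fill=5, standardize=False)
        dec._reset(3)
        pts = []
        for i in range(30):
            label = MOVE if i % 2 else REST
            x = rng.standard_normal(3) + (4.0 if label == MOVE else -4.0)
            dec.partial_fit_frame(x, label)
            pts.append((x, label))
        X = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        assert np.array_equal(dec.predict(X), y)
        margins = np.abs(dec.decision_function(X))
        assert margins.min() > 0.99

    def test_model_equals_batch_retraining_on_buffers(self, rng):
        """After a long add/evict history the decision function matches a
        cold batch SVM fit on the exact buffer contents."""
        X, labels = _labeled_stream(rng, 1500, 6)
        dec = AdaptiveSvmDecoder(buffer_frames=60, min_fill=5)
        dec._reset(6)
        for i in range(0, 1500, 10):
            if labels[i] != BOUNDARY:
                dec.partial_fit_frame(X[i], int(labels[i]))
        Xb = np.vstack(dec._rest_buf + dec._move_buf)
        yb = np.concatenate([-np.ones(len(dec._rest_buf)),
                             np.ones(len(dec._move_buf))])
        Xz = (Xb - dec.mean_) / dec.scale_
        w, b = batch_svm(Xz, yb)
        probes = rng.standard_normal((30, 6))
        dv_batch = (probes - dec.mean_) / dec.scale_ @ w + b
        assert np.abs(dec.decision_function(probes) - dv_batch).max() < 1e-6

    def test_stream_kernel_matches_per_frame_api(self, rng):
        X, labels = _labeled_stream(rng, 800, 5)
        fast = AdaptiveSvmDecoder(buffer_frames=40, min_fill=5)
        pred_fast = fast.stream(X, labels)
        slow = AdaptiveSvmDecoder(buffer_frames=40, min_fill=5)
        slow._reset(5)
        pred_slow = np.full(len(labels), REST, np.int8)
        for i in range(0, len(labels), slow.update_stride):
            if labels[i] != BOUNDARY:
                slow.partial_fit_frame(X[i], int(labels[i]))
            if slow.is_ready:
                stop = min(i + slow.update_stride, len(labels))
                pred_slow[i:stop] = slow.predict(X[i:stop])
        assert np.array_equal(pred_fast, pred_slow)
        assert np.allclose(fast.coef_, slow.coef_, atol=1e-9)

    def test_class_swap_negates_decisions(self, rng):
        X, labels = _labeled_stream(rng, 1000, 4)
        a = AdaptiveSvmDecoder()
        a.stream(X, labels)
        swapped = labels.copy()
        swapped[labels == REST] = MOVE
        swapped[labels == MOVE] = REST
        b = AdaptiveSvmDecoder()
        b.stream(X, swapped)
        probes = rng.standard_normal((20, 4))
        assert np.allclose(a.decision_function(probes),
                           -b.decision_function(probes), atol=1e-6)

    def test_feature_dimension_change_rejected(self, rng):
        dec = AdaptiveSvmDecoder()
        dec._reset(4)
        dec.partial_fit_frame(rng.standard_normal(4), REST)
        with pytest.raises(ValueError, match="dimension"):
            dec.partial_fit_frame(rng.standard_normal(5), MOVE)

    def test_adaptive_tracks_drift_better_than_static_batch(self):
        """Stationary data: adaptive == one batch SVM on the same total data.
        Drifting data: the adaptive decoder is strictly better."""
        from scipy.stats import ranksums, wilcoxon

        def score(drift_sd, seed):
            rng = np.random.default_rng(seed)
            X, labels = _labeled_stream(rng, 4000, 4, sep=0.8, drift_sd=drift_sd)
            adaptive = AdaptiveSvmDecoder(buffer_frames=100, min_fill=5)
            pred_a = adaptive.stream(X, labels)
            _, _, s_a = sd.compute_tp_fp(pred_a, labels)
            idx = np.arange(0, len(labels), 10)
            idx = idx[labels[idx] != BOUNDARY]
            Xb, yb = X[idx], np.where(labels[idx] == MOVE, 1.0, -1.0)
            mu, sdev = Xb.mean(0), np.maximum(Xb.std(0), 1e-12)
            w, b = batch_svm((Xb - mu) / sdev, yb)
            pred_s = np.where((X - mu) / sdev @ w + b > 0, MOVE, REST)
            _, _, s_s = sd.compute_tp_fp(pred_s, labels)
            return s_a, s_s

        stationary = np.array([score(0.0, s) for s in range(20)])
        drifting = np.array([score(0.05, 100 + s) for s in range(20)])
        # stationary: score distributions indistinguishable
        p_stat = ranksums(stationary[:, 0], stationary[:, 1]).pvalue
        assert abs(stationary[:, 0].mean() - stationary[:, 1].mean()) < 0.05
        assert p_stat > 0.05
        # drifting: adaptive strictly higher
        diffs = drifting[:, 0] - drifting[:, 1]
        assert diffs.mean() > 0.0
        assert wilcoxon(drifting[:, 0], drifting[:, 1],
                        alternative="greater").pvalue < 0.05


def _gate_oracle(outputs, n_consecutive=5):
    """Independent re-derivation of the gate semantics: the orthosis state
    flips when the last n outputs agree and differ from the current state;
    a command is emitted exactly at the flip."""
    state = REST
    commands = []
    for i in range(len(outputs)):
        run = 1
        while run <= i and outputs[i - run] == outputs[i]:
            run += 1
        if run >= n_consecutive and outputs[i] != state:
            state = outputs[i]
            commands.append("move_command" if state == MOVE else "stop_command")
        else:
            commands.append("hold")
    return commands


class TestOrthosisGate:
    def test_five_consecutive_move_commands_on_fifth(self):
        gate = OrthosisGate()
        cmds = gate.run([MOVE] * 5)
        assert cmds == ["hold"] * 4 + ["move_command"]
        assert gate.orthosis_state == MOVE

    def test_broken_run_resets(self):
        gate = OrthosisGate()
        cmds = gate.run([MOVE] * 4 + [REST])
        assert all(c == "hold" for c in cmds)
        assert gate.orthosis_state == REST

    def test_stop_after_five_rest_from_moving(self):
        gate = OrthosisGate(initial_state=MOVE)
        cmds = gate.run([REST] * 5)
        assert cmds[-1] == "stop_command"
        assert gate.orthosis_state == REST

    @given(st.lists(st.sampled_from([REST, MOVE]), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_bruteforce_oracle(self, outputs):
        assert OrthosisGate().run(outputs) == _gate_oracle(outputs)

    def test_never_two_commands_without_state_flip(self, rng):
        outputs = rng.integers(0, 2, 500)
        cmds = OrthosisGate().run(outputs)
        real = [c for c in cmds if c != "hold"]
        for a, b in zip(real, real[1:]):
            assert a != b

    def test_invalid_output_rejected(self):
        with pytest.raises(ValueError):
            OrthosisGate().step(7)
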