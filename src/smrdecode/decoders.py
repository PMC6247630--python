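"""The two movement-intention classifiers and the orthosis gating logic.

Both classifiers are sklearn-style estimators.  Their native mode of
operation is *streaming*: frames arrive every 40 ms, the classifier emits a
rest/move output for each, and adapts itself from the cue-derived ground
truth labels on its own schedule (per labeled period for the threshold
classifier, every 400 ms for the adaptive SVM).  ``fit(X, y)`` replays a
whole labeled frame stream through that schedule; ``stream(X, y)`` does the
same while returning the causal frame-by-frame predictions that the
pseudo-online evaluation scores.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import windows
from ._svm import LinearSvm, _asvm_stream
from .windows import BOUNDARY, MOVE, REST


def _check_frames(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("frame features must be a (n_frames, n_features) array")
    if not np.all(np.isfinite(X)):
        raise ValueError("frame features must be finite")
    return X


class SmrThresholdDecoder(ClassifierMixin, BaseEstimator):
    """Adaptive two-distribution threshold classifier.

    The feature of a frame is the mean log band power over the selected
    electrode-frequency pairs.  The classifier keeps one history of
    per-period mean powers for rest and one for movement attempts; the
    decision threshold is the midpoint of the two history means and is
    re-derived after every completed period, so it adapts as the two
    distributions move over a session.

    Parameters
    ----------
    modulation : {'erd', 'ers'}
        'erd': power below threshold maps to movement (desynchronization,
        the contingent-positive setting).  'ers' inverts the polarity for
        contingent-negative semantics.
    history_window : int or None
        Optional forgetting horizon: keep only the last k period means per
        class.  Default keeps the full session history.
    """

    def __init__(self, modulation: str = "erd", history_window: int | None = None):
        self.modulation = modulation
        self.history_window = history_window

    def _reset(self) -> None:
        if self.modulation not in ("erd", "ers"):
            raise ValueError("modulation must be 'erd' or 'ers'")
        if self.history_window is not None and self.history_window < 1:
            raise ValueError("history_window must be >= 1 or None")
        self.rest_history_: list[float] = []
        self.move_history_: list[float] = []
        self.threshold_: float | None = None
        self.classes_ = np.array([REST, MOVE])

    def update_period(self, period_power: float | np.ndarray, label: int) -> None:
        """Append one completed period's mean feature power and re-derive
        the threshold."""
        value = float(np.mean(period_power))
        if label == MOVE:
            self.move_history_.append(value)
        elif label == REST:
            self.rest_history_.append(value)
        else:
            raise ValueError("period label must be REST or MOVE")
        if self.history_window is not None:
            del self.rest_history_[:-self.history_window]
            del self.move_history_[:-self.history_window]
        if self.rest_history_ and self.move_history_:
            self.threshold_ = 0.5 * (
                float(np.mean(self.rest_history_)) + float(np.mean(self.move_history_))
            )

    def _classify_power(self, p: np.ndarray) -> np.ndarray:
        """Threshold rule; exact ties map to rest."""
        if self.threshold_ is None:
            return np.full(p.shape, REST, dtype=np.int8)
        if self.modulation == "erd":
            return np.where(p < self.threshold_, MOVE, REST).astype(np.int8)
        return np.where(p > self.threshold_, MOVE, REST).astype(np.int8)

    def stream(self, X, y) -> np.ndarray:
        """Causal pseudo-online replay: predict every frame, adapt after
        every completed labeled period.  Returns per-frame predictions."""
        X = _check_frames(X)
        y = np.asarray(y)
        self._reset()
        power = X.mean(axis=1)
        pred = np.empty(len(power), dtype=np.int8)
        pos = 0
        for label, a, b in windows.period_slices(y):
            pred[pos:b] = self._classify_power(power[pos:b])
            self.update_period(power[a:b], label)
            pos = b
        pred[pos:] = self._classify_power(power[pos:])
        return pred

    def fit(self, X, y):
        self.stream(X, y)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "threshold_"):
            raise RuntimeError("decoder is not fitted")
        return self._classify_power(_check_frames(X).mean(axis=1))


class AdaptiveSvmDecoder(ClassifierMixin, BaseEstimator):
    """Linear SVM on rolling two-minute class buffers, retrained every 400 ms.

    Every ``update_stride``-th frame (10 frames = 400 ms at the 40 ms frame
    cadence) is appended to the buffer of its ground-truth period; each
    buffer keeps the most recent ``buffer_frames`` entries (300 = 2 min of
    class time), evicting the oldest.  After every buffer change the model
    is brought to the exact C-SVM solution of the current buffer contents
    (warm-started active-set solve — equivalent to batch retraining).
    Frames are classified with the current model at the full 40 ms cadence;
    until both buffers hold ``min_fill`` frames the prediction is rest.

    Features are z-scored with buffer-derived mean/SD refreshed at each
    retrain (``standardize=False`` disables this).
    """

    def __init__(self, C: float = 1.0, buffer_frames: int = 300,
                 update_stride: int = 10, min_fill: int = 10,
                 standardize: bool = True, kkt_tol: float = 1e-10):
        self.C = C
        self.buffer_frames = buffer_frames
        self.update_stride = update_stride
        self.min_fill = min_fill
        self.standardize = standardize
        self.kkt_tol = kkt_tol

    def _reset(self, n_features: int) -> None:
        if min(self.buffer_frames, self.update_stride, self.min_fill) < 1:
            raise ValueError("buffer_frames, update_stride and min_fill must be >= 1")
        self._rest_buf: list[np.ndarray] = []
        self._move_buf: list[np.ndarray] = []
        self._solver = LinearSvm(C=self.C, kkt_tol=self.kkt_tol)
        self.n_features_in_ = n_features
        self.coef_: np.ndarray | None = None
        self.intercept_: float = 0.0
        self.mean_ = np.zeros(n_features)
        self.scale_ = np.ones(n_features)
        self.n_updates_ = 0
        self.classes_ = np.array([REST, MOVE])

    @property
    def is_ready(self) -> bool:
        return self.coef_ is not None

    def partial_fit_frame(self, x: np.ndarray, label: int) -> None:
        """Buffer update + exact retrain for one 400 ms step."""
        x = np.asarray(x, dtype=float).ravel()
        if x.size != self.n_features_in_:
            raise ValueError("feature dimension changed mid-stream")
        if label == REST:
            buf, insert_at = self._rest_buf, len(self._rest_buf)
            evict_at = 0
        elif label == MOVE:
            buf = self._move_buf
            insert_at = len(self._rest_buf) + len(self._move_buf)
            evict_at = len(self._rest_buf)
        else:
            raise ValueError("buffer label must be REST or MOVE")
        buf.append(x)
        self._solver.insert_point(insert_at)
        if len(buf) > self.buffer_frames:
            buf.pop(0)
            self._solver.remove_point(evict_at)
        if (len(self._rest_buf) >= self.min_fill
                and len(self._move_buf) >= self.min_fill):
            self._retrain()
        self.n_updates_ += 1

    def _retrain(self) -> None:
        Xb = np.vstack(self._rest_buf + self._move_buf)
        yb = np.concatenate([
            np.full(len(self._rest_buf), -1.0),
            np.full(len(self._move_buf), 1.0),
        ])
        if self.standardize:
            self.mean_ = Xb.mean(axis=0)
            self.scale_ = np.maximum(Xb.std(axis=0), 1e-12)
        w, b = self._solver.solve((Xb - self.mean_) / self.scale_, yb)
        self.coef_ = w
        self.intercept_ = b

    def decision_function(self, X) -> np.ndarray:
        """Signed distance to the current hyperplane; positive = move."""
        if not self.is_ready:
            raise RuntimeError("decoder has no model yet (buffers below min_fill)")
        X = _check_frames(X)
        return (X - self.mean_) / self.scale_ @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        X = _check_frames(X)
        if not self.is_ready:
            return np.full(X.shape[0], REST, dtype=np.int8)
        return np.where(self.decision_function(X) > 0, MOVE, REST).astype(np.int8)

    def stream(self, X, y) -> np.ndarray:
        """Causal pseudo-online replay; returns per-frame predictions.

        Every ``update_stride``-th frame with a non-boundary label is
        appended to its class buffer and the model retrained; the frames of
        that 400 ms segment are then classified with the updated model.
        Until the model exists every prediction is rest.

        Runs in a compiled kernel; frame-by-frame calls to
        :meth:`partial_fit_frame` / :meth:`predict` follow the identical
        update schedule and produce the same model.
        """
        X = _check_frames(X)
        y = np.ascontiguousarray(y, dtype=np.int8)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        self._reset(X.shape[1])
        pred, w, b, mu, sd, ready, n_updates = _asvm_stream(
            np.ascontiguousarray(X), y, float(self.C), int(self.buffer_frames),
            int(self.update_stride), int(self.min_fill), bool(self.standardize),
            float(self.kkt_tol), 200000, REST, MOVE, BOUNDARY,
        )
        if ready:
            self.coef_ = w
            self.intercept_ = float(b)
            self.mean_ = mu
            self.scale_ = sd
        self.n_updates_ = int(n_updates)
        return pred

    def fit(self, X, y):
        self.stream(X, y)
        return self


class OrthosisGate:
    """Debouncing gate between classifier outputs and orthosis commands.

    The orthosis changes state only after five consecutive identical
    classifier outputs; a command (positive velocity for move, zero
    velocity for stop) is emitted at the moment of the state change and the
    gate holds otherwise.
    """

    MOVE_COMMAND = "move_command"
    STOP_COMMAND = "stop_command"
    HOLD = "hold"

    def __init__(self, n_consecutive: int = 5, initial_state: int = REST):
        if n_consecutive < 1:
            raise ValueError("n_consecutive must be >= 1")
        self.n_consecutive = n_consecutive
        self.orthosis_state = initial_state  # REST = stopped, MOVE = moving
        self.run_length = 0
        self.last_output: int | None = None

    def step(self, output: int) -> str:
        """Advance the gate by one classifier output; returns the command."""
        if output not in (REST, MOVE):
            raise ValueError("classifier output must be REST or MOVE")
        if output == self.last_output:
            self.run_length += 1
        else:
            self.run_length = 1
            self.last_output = output
        if self.run_length >= self.n_consecutive and output != self.orthosis_state:
            self.orthosis_state = output
            return self.MOVE_COMMAND if output == MOVE else self.STOP_COMMAND
        return self.HOLD

    def run(self, outputs) -> list[str]:
        """Commands for a whole output sequence."""
        return [self.step(int(o)) for o in outputs]


def gated_states(outputs, n_consecutive: int = 5, initial_state: int = REST) -> np.ndarray:
    """Orthosis movement state after each classifier output.

    The gated-command metric variant scores these states instead of the raw
    40 ms classifier outputs.
    """
    gate = OrthosisGate(n_consecutive, initial_state)
    states = np.empty(len(outputs), dtype=np.int8)
    for i, o in enumerate(outputs):
        gate.step(int(o))
        states[i] = gate.orthosis_state
    return states
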