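"""Sliding-window frame grid and rest/move period labeling.

All decoding operates on 500 ms windows advanced in 40 ms steps, mirroring
the online system's update rate.  A window is labeled ``move`` when its full
500 ms support lies inside a cued movement-attempt period (go cue to end
cue), ``rest`` when it lies inside an inter-trial interval, and ``boundary``
otherwise (instruction gaps and windows straddling a cue).  Boundary frames
are excluded from performance counting and from classifier adaptation.
"""

from __future__ import annotations

import numpy as np

WINDOW_S = 0.5
STEP_S = 0.04

REST, MOVE, BOUNDARY = 0, 1, 2
LABEL_NAMES = ("rest", "move", "boundary")


def n_frames(n_samples: int, fs: float = 500.0) -> int:
    """Number of sliding windows fitting in ``n_samples``.

    Closed form: ``floor((n_samples - window) / step) + 1`` with the window
    and step expressed in samples.
    """
    win = int(round(WINDOW_S * fs))
    step = int(round(STEP_S * fs))
    if n_samples < win:
        return 0
    return (n_samples - win) // step + 1


def frame_bounds(n_samples: int, fs: float = 500.0) -> tuple[np.ndarray, np.ndarray]:
    """Start (inclusive) and end (exclusive) sample index of every frame."""
    win = int(round(WINDOW_S * fs))
    step = int(round(STEP_S * fs))
    nf = n_frames(n_samples, fs)
    starts = np.arange(nf, dtype=np.int64) * step
    return starts, starts + win


def frame_times(n_samples: int, fs: float = 500.0) -> np.ndarray:
    """Window end time in seconds for every frame."""
    _, ends = frame_bounds(n_samples, fs)
    return ends / fs


def label_frames(
    event_times: np.ndarray,
    event_kinds: np.ndarray,
    n_samples: int,
    fs: float = 500.0,
) -> np.ndarray:
    """Assign a period label to every sliding window.

    Comparisons are done in integer samples so that frames touching a cue
    boundary are labeled deterministically.

    Returns
    -------
    ndarray of int8
        ``REST`` (0), ``MOVE`` (1) or ``BOUNDARY`` (2) per frame.
    """
    event_times = np.asarray(event_times, dtype=float)
    kinds = np.asarray(event_kinds)
    if event_times.size and np.any(np.diff(event_times) < 0):
        raise ValueError("event stream must be sorted in time")
    starts, ends = frame_bounds(n_samples, fs)
    labels = np.full(starts.size, BOUNDARY, dtype=np.int8)
    ev_samp = np.round(event_times * fs).astype(np.int64)

    def _mark(open_kind: str, close_kind: str, value: int) -> None:
        open_t = None
        for t, k in zip(ev_samp, kinds):
            if k == open_kind:
                if value == MOVE and open_t is not None:
                    raise ValueError("overlapping movement periods in event stream")
                open_t = t
            elif k == close_kind and open_t is not None:
                sel = (starts >= open_t) & (ends <= t)
                labels[sel] = value
                open_t = None

    _mark("iti_start", "instruction", REST)
    _mark("go", "end", MOVE)
    return labels


def period_slices(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous runs of identically labeled non-boundary frames.

    Returns ``(label, start, stop)`` triples; used by the trial-wise
    threshold-classifier update, where each run is one rest or movement
    period.
    """
    labels = np.asarray(labels)
    out: list[tuple[int, int, int]] = []
    i = 0
    n = labels.size
    while i < n:
        if labels[i] == BOUNDARY:
            i += 1
            continue
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        out.append((int(labels[i]), i, j))
        i = j
    return out
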