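"""Autoregressive log-power features on sliding windows.

Each 500 ms window is fitted with a 16th-order autoregressive model using
the Burg lattice recursion; the parametric power spectral density of the
fitted model is evaluated at the 20 bin centers 2, 4, ..., 40 Hz and the
natural logarithm is applied.  The Burg recursion is implemented as a
numba-compiled batch over windows because a factorial-design run needs
several hundred thousand fits per session; coefficients agree with the
reference recursion in statsmodels to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from numpy.lib.stride_tricks import sliding_window_view

from . import windows
from .montage import (
    BIN_CENTERS_HZ,
    MOTOR_CHANNELS,
    band_indices,
    resolve_band,
    resolve_electrode_set,
)
from .spatial import apply_spatial_filter

AR_ORDER = 16
#: log-power sentinel for zero-variance windows: log of a tiny positive power.
LOGPOWER_FLOOR = float(np.log(np.finfo(float).tiny))


@njit(cache=True)
def _burg_batch(x: np.ndarray, order: int):  # pragma: no cover - numba
    """Burg AR coefficients for a batch of windows.

    Convention: ``x[t] = sum_k a[k] * x[t-k] + e[t]``; returns ``(a, s2)``
    with ``a`` of shape (n_windows, order) and the driving-noise variance
    ``s2`` from the error-power recursion ``E_m = E_{m-1} (1 - k_m^2)``.
    """
    B, N = x.shape
    a = np.zeros((B, order))
    s2 = np.empty(B)
    aprev = np.empty(order)
    f = np.empty(N)
    b = np.empty(N)
    for w in range(B):
        e = 0.0
        for t in range(N):
            v = x[w, t]
            f[t] = v
            b[t] = v
            e += v * v
        e /= N
        for m in range(1, order + 1):
            num = 0.0
            den = 0.0
            for t in range(m, N):
                num += f[t] * b[t - 1]
                den += f[t] * f[t] + b[t - 1] * b[t - 1]
            k = 2.0 * num / den if den > 0.0 else 0.0
            for i in range(m - 1):
                aprev[i] = a[w, i]
            a[w, m - 1] = k
            for i in range(m - 1):
                a[w, i] = aprev[i] - k * aprev[m - 2 - i]
            for t in range(N - 1, m - 1, -1):
                fo = f[t]
                f[t] = fo - k * b[t - 1]
                b[t] = b[t - 1] - k * fo
            e *= 1.0 - k * k
        s2[w] = e
    return a, s2


def burg_coefficients(x: np.ndarray, order: int = AR_ORDER):
    """Burg AR fit of one window or a batch of windows.

    Parameters
    ----------
    x : ndarray, shape (n_samples,) or (n_windows, n_samples)
    order : int
        AR model order.

    Returns
    -------
    a : ndarray
        Coefficients, same leading shape as ``x``.
    s2 : ndarray or float
        Estimated driving-noise variance.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] <= order:
        raise ValueError(f"window of {x.shape[1]} samples too short for AR({order})")
    a, s2 = _burg_batch(x, order)
    return (a[0], float(s2[0])) if single else (a, s2)


def ar_log_psd(a: np.ndarray, s2: np.ndarray, freqs: np.ndarray,
               fs: float = 500.0) -> np.ndarray:
    """Natural-log AR power spectral density evaluated at ``freqs``.

    ``log PSD(f) = log(s2 / fs) - log |1 - sum_k a_k exp(-2 pi i f k / fs)|^2``.
    Zero-variance fits map to the log-power floor sentinel.
    """
    a = np.atleast_2d(a)
    s2 = np.atleast_1d(np.asarray(s2, dtype=float))
    k = np.arange(1, a.shape[1] + 1)
    E = np.exp(-2j * np.pi * np.outer(np.asarray(freqs, float), k) / fs)  # (F, p)
    denom = np.abs(1.0 - a @ E.T) ** 2  # (B, F)
    tiny = np.finfo(float).tiny
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.log(np.maximum(s2[:, None] / (fs * denom), tiny))
    return np.where((s2 > 0)[:, None], vals, LOGPOWER_FLOOR)


def burg_log_spectrum(window: np.ndarray, order: int = AR_ORDER,
                      fs: float = 500.0,
                      freqs: tuple[float, ...] = BIN_CENTERS_HZ) -> np.ndarray:
    """Log-power feature vector of a single window (20 values by default).

    The window is demeaned before the AR fit.  A constant (zero-variance)
    window yields the log-power floor in every bin rather than an error.
    """
    x = np.asarray(window, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("burg_log_spectrum expects a single-channel window")
    x = x - x.mean()
    if not np.any(x):
        return np.full(len(freqs), LOGPOWER_FLOOR)
    a, s2 = burg_coefficients(x, order)
    return ar_log_psd(a[None, :], np.array([s2]), np.asarray(freqs), fs)[0]


@dataclass
class SpectralFrames:
    """Sliding-window log-power features of one session.

    ``logpower`` has shape (n_frames, n_channels, n_bins); ``labels`` holds
    the rest/move/boundary code of every frame (see :mod:`smrdecode.windows`).
    """

    t_end: np.ndarray
    logpower: np.ndarray
    channels: tuple[str, ...]
    bin_centers: tuple[float, ...]
    labels: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.logpower.shape[0]

    def matrix(self) -> np.ndarray:
        """Features flattened to (n_frames, n_channels * n_bins)."""
        return self.logpower.reshape(self.n_frames, -1)

    def select(self, channels=None, band: str | None = None) -> "SpectralFrames":
        """Restrict to a channel subset and/or a named frequency band."""
        ch = self.channels if channels is None else tuple(channels)
        ch_idx = [self.channels.index(c) for c in ch]
        if band is None:
            b_idx = list(range(len(self.bin_centers)))
            centers = self.bin_centers
        else:
            centers = resolve_band(band)
            b_idx = [self.bin_centers.index(f) for f in centers]
        lp = self.logpower[:, ch_idx][:, :, b_idx]
        return SpectralFrames(self.t_end, lp, ch, centers, self.labels)

    def to_frame(self):
        """Long-format pandas DataFrame (t_end, channel, bin_hz, value, label)."""
        import pandas as pd

        nf, nc, nb = self.logpower.shape
        return pd.DataFrame(
            {
                "t_end": np.repeat(self.t_end, nc * nb),
                "channel": np.tile(np.repeat(self.channels, nb), nf),
                "bin_hz": np.tile(self.bin_centers, nf * nc),
                "value": self.logpower.ravel(),
                "label": np.repeat(
                    np.asarray(windows.LABEL_NAMES)[self.labels], nc * nb
                ),
            }
        )


def _windowed_log_psd(x: np.ndarray, fs: float, order: int) -> np.ndarray:
    """Log AR-PSD of all sliding windows of one channel; (n_frames, 20)."""
    win = int(round(windows.WINDOW_S * fs))
    step = int(round(windows.STEP_S * fs))
    segs = sliding_window_view(x, win)[::step]
    segs = np.ascontiguousarray(segs - segs.mean(axis=1, keepdims=True))
    out = np.empty((segs.shape[0], len(BIN_CENTERS_HZ)))
    chunk = 20000
    for lo in range(0, segs.shape[0], chunk):
        part = segs[lo:lo + chunk]
        a, s2 = _burg_batch(part, order)
        out[lo:lo + chunk] = ar_log_psd(a, s2, np.asarray(BIN_CENTERS_HZ), fs)
    return out


def extract_eeg_features(
    session,
    spatial_filter: str = "none",
    electrode_set: str = "bihemispheric",
    band: str | None = "alpha_beta",
    channels: tuple[str, ...] | None = None,
    order: int = AR_ORDER,
) -> SpectralFrames:
    """Spectral feature frames of a session for one design cell.

    The spatial filter is applied to the full montage before any channel
    subsetting.  ``channels`` overrides the electrode-set resolution and
    ``band=None`` keeps all 20 bins; together they give the full-montage,
    full-spectrum frames used for feature screening.
    """
    if session.n_samples < int(round(windows.WINDOW_S * session.fs)):
        raise ValueError("session shorter than one 500 ms analysis window")
    filtered = apply_spatial_filter(session.eeg, spatial_filter, session.eeg_channels)
    if channels is None:
        channels = resolve_electrode_set(electrode_set, session.lesion_side)
    if band is None:
        b_idx = list(range(len(BIN_CENTERS_HZ)))
        centers = BIN_CENTERS_HZ
    else:
        b_idx = band_indices(band)
        centers = resolve_band(band)
    labels = session.frame_labels()
    t_end = windows.frame_times(session.n_samples, session.fs)
    lp = np.empty((t_end.size, len(channels), len(b_idx)))
    for j, ch in enumerate(channels):
        full = _windowed_log_psd(
            filtered[session.eeg_channels.index(ch)], session.fs, order
        )
        lp[:, j, :] = full[:, b_idx]
    return SpectralFrames(t_end, lp, tuple(channels), centers, labels)


def motor_feature_tensor(session, spatial_filter: str,
                         order: int = AR_ORDER) -> SpectralFrames:
    """Full 20-bin feature tensor over the six motor channels.

    Shared cache for factorial-grid runs: every electrode-set x band cell of
    one spatial filter is a pure slice of this tensor.
    """
    filtered = apply_spatial_filter(session.eeg, spatial_filter, session.eeg_channels)
    labels = session.frame_labels()
    t_end = windows.frame_times(session.n_samples, session.fs)
    lp = np.empty((t_end.size, len(MOTOR_CHANNELS), len(BIN_CENTERS_HZ)))
    for j, ch in enumerate(MOTOR_CHANNELS):
        lp[:, j, :] = _windowed_log_psd(
            filtered[session.eeg_channels.index(ch)], session.fs, order
        )
    return SpectralFrames(t_end, lp, MOTOR_CHANNELS, BIN_CENTERS_HZ, labels)
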