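"""R-square screening of electrode-frequency pairs.

Replaces the visual-inspection step of the original calibration procedure
with its quantitative core: rank every (channel, frequency-bin) pair by the
squared point-biserial correlation between the rest/move period label and
the log band power across frames.  For two groups this r² equals
``t² / (t² + df)`` with ``t`` the pooled two-sample t statistic.
"""

from __future__ import annotations

import numpy as np

from . import windows
from .spectral import SpectralFrames


def rsquare_map(frames: SpectralFrames) -> np.ndarray:
    """r² per (channel, bin), shape (n_channels, n_bins).

    Boundary frames are excluded.  Raises if only one class is present.
    """
    keep = frames.labels != windows.BOUNDARY
    y = (frames.labels[keep] == windows.MOVE).astype(float)
    if y.size == 0 or y.min() == y.max():
        raise ValueError("r-square screening needs both rest and move frames")
    X = frames.logpower[keep]  # (n, ch, bins)
    n = y.size
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    cov = np.tensordot(yc, Xc, axes=(0, 0)) / n
    vx = (Xc ** 2).mean(axis=0)
    vy = yc.var()
    denom = vx * vy
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, cov ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    return r2


def rsquare_screening(frames: SpectralFrames) -> list[tuple[str, float, float]]:
    """Ranked ``(channel, bin_hz, r2)`` list, best discriminating pair first.

    Ties are broken deterministically by (channel index, bin index).
    """
    r2 = rsquare_map(frames)
    nc, nb = r2.shape
    order = sorted(
        ((i, j) for i in range(nc) for j in range(nb)),
        key=lambda ij: (-r2[ij], ij[0], ij[1]),
    )
    return [
        (frames.channels[i], float(frames.bin_centers[j]), float(r2[i, j]))
        for i, j in order
    ]
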