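"""Spatial filters: common average reference and small Laplacian."""

from __future__ import annotations

import numpy as np

from .montage import EEG_CHANNELS, LAPLACIAN_NEIGHBORS

SPATIAL_FILTERS = ("none", "car", "laplacian")


def apply_car(eeg: np.ndarray) -> np.ndarray:
    """Common average reference: subtract the instantaneous cross-channel mean.

    Parameters
    ----------
    eeg : ndarray, shape (n_channels, n_samples)

    Returns
    -------
    ndarray
        Re-referenced copy; the cross-channel mean of every sample is 0.
    """
    eeg = np.asarray(eeg, dtype=float)
    if eeg.ndim != 2 or eeg.shape[0] < 2:
        raise ValueError("CAR needs a (n_channels >= 2, n_samples) array")
    return eeg - eeg.mean(axis=0, keepdims=True)


def apply_small_laplacian(
    eeg: np.ndarray,
    channels: tuple[str, ...] = EEG_CHANNELS,
    neighbors: dict[str, tuple[str, ...]] = LAPLACIAN_NEIGHBORS,
) -> np.ndarray:
    """Small-Laplacian re-referencing: ``out(ch) = in(ch) - mean(in(neighbors))``.

    Channels without an entry in the neighbor table pass through unchanged;
    a neighbor name absent from ``channels`` raises ``ValueError``.
    """
    eeg = np.asarray(eeg, dtype=float)
    if eeg.ndim != 2 or eeg.shape[0] != len(channels):
        raise ValueError("eeg must be (len(channels), n_samples)")
    index = {name: i for i, name in enumerate(channels)}
    out = eeg.copy()
    for ch, nbrs in neighbors.items():
        if ch not in index:
            continue
        if not nbrs:
            raise ValueError(f"channel {ch} has no neighbors defined")
        try:
            rows = [index[nb] for nb in nbrs]
        except KeyError as exc:
            raise ValueError(f"neighbor {exc.args[0]} of {ch} not in montage") from None
        out[index[ch]] = eeg[index[ch]] - eeg[rows].mean(axis=0)
    return out


def apply_spatial_filter(eeg: np.ndarray, name: str,
                         channels: tuple[str, ...] = EEG_CHANNELS) -> np.ndarray:
    """Dispatch by filter name in {'none', 'car', 'laplacian'}."""
    if name == "none":
        return np.asarray(eeg, dtype=float)
    if name == "car":
        return apply_car(eeg)
    if name == "laplacian":
        return apply_small_laplacian(eeg, channels)
    raise ValueError(f"unknown spatial filter {name!r}; choose from {SPATIAL_FILTERS}")
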