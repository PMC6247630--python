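"""Channel montage, electrode sets, spatial-filter neighbor table and band layout.

The recording montage is a 16-channel modified 10/20 EEG layout plus 8
bipolar EMG derivations (4 muscle groups per arm).  Electrode subsets used
for decoding are expressed relative to the lesioned hemisphere: odd-numbered
channels (C3, CP3, P3) sit over the left hemisphere, even-numbered ones over
the right.
"""

from __future__ import annotations

EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "Fz", "F4", "T7", "C3", "Cz",
    "C4", "T8", "CP3", "CP4", "P3", "Pz", "P4", "Oz",
)

#: Muscle groups carrying one bipolar EMG derivation each, distal to proximal.
EMG_MUSCLES: tuple[str, ...] = ("ecu", "ed", "biceps", "triceps")

#: EMG channels, paretic arm first.  "ecu" = extensor carpi ulnaris,
#: "ed" = extensor digitorum.
EMG_CHANNELS: tuple[str, ...] = tuple(
    f"{arm}_{m}" for arm in ("paretic", "healthy") for m in EMG_MUSCLES
)

LEFT_MOTOR = ("C3", "CP3", "P3")
RIGHT_MOTOR = ("C4", "CP4", "P4")
MOTOR_CHANNELS = ("C3", "C4", "CP3", "CP4", "P3", "P4")

ELECTRODE_SETS = ("ipsilesional", "contralesional", "bihemispheric")

#: Neighbor table for the small-Laplacian spatial filter.  Only the channels
#: listed here are re-referenced; each output channel is the input minus the
#: mean over its neighbors.  The table is symmetric across the midline.
LAPLACIAN_NEIGHBORS: dict[str, tuple[str, ...]] = {
    "Fp1": ("F3", "Fz"),
    "Fp2": ("F4", "Fz"),
    "F3": ("Fp1", "Fz", "C3"),
    "Fz": ("Fp1", "Fp2", "F3", "F4", "Cz"),
    "F4": ("Fp2", "Fz", "C4"),
    "T7": ("C3", "P3"),
    "C3": ("F3", "T7", "Cz", "CP3"),
    "Cz": ("Fz", "C3", "C4", "Pz"),
    "C4": ("F4", "T8", "Cz", "CP4"),
    "T8": ("C4", "P4"),
    "CP3": ("C3", "P3"),
    "CP4": ("C4", "P4"),
    "P3": ("CP3", "Pz"),
    "P4": ("CP4", "Pz"),
    "Pz": ("Cz", "P3", "P4", "Oz"),
    "Oz": ("Pz", "P3", "P4"),
}

#: Spectral bins: 20 bins covering 1-40 Hz at 2 Hz resolution, identified by
#: their center frequency.
BIN_CENTERS_HZ: tuple[float, ...] = tuple(float(f) for f in range(2, 41, 2))

#: Band membership by bin center.  15 Hz is not a bin center, so the beta
#: band (15-30 Hz) resolves to centers 16..30.
BANDS: dict[str, tuple[float, float]] = {
    "alpha": (8.0, 12.0),
    "beta": (15.0, 30.0),
    "alpha_beta": (8.0, 30.0),
}


def resolve_electrode_set(name: str, lesion_side: str) -> tuple[str, ...]:
    """Resolve an electrode-set name to concrete channels.

    Parameters
    ----------
    name : {'ipsilesional', 'contralesional', 'bihemispheric'}
    lesion_side : {'L', 'R'}
        Hemisphere containing the stroke lesion.

    Returns
    -------
    tuple of str
        Channel names over motor cortex.
    """
    if lesion_side not in ("L", "R"):
        raise ValueError(f"lesion_side must be 'L' or 'R', got {lesion_side!r}")
    if name == "bihemispheric":
        return MOTOR_CHANNELS
    lesioned = LEFT_MOTOR if lesion_side == "L" else RIGHT_MOTOR
    healthy = RIGHT_MOTOR if lesion_side == "L" else LEFT_MOTOR
    if name == "ipsilesional":
        return lesioned
    if name == "contralesional":
        return healthy
    raise ValueError(f"unknown electrode set {name!r}")


def resolve_band(name: str) -> tuple[float, ...]:
    """Return the spectral bin centers belonging to a named band."""
    try:
        lo, hi = BANDS[name]
    except KeyError:
        raise ValueError(f"unknown band {name!r}; choose from {sorted(BANDS)}") from None
    return tuple(f for f in BIN_CENTERS_HZ if lo <= f <= hi)


def band_indices(name: str) -> list[int]:
    """Indices into ``BIN_CENTERS_HZ`` for a named band."""
    centers = resolve_band(name)
    return [BIN_CENTERS_HZ.index(f) for f in centers]


def resolve_task_muscles(arm_set: str, muscle_set: str, task_phase: str) -> tuple[str, ...]:
    """Resolve EMG subset names to concrete channels.

    Parameters
    ----------
    arm_set : {'paretic', 'healthy', 'both'}
    muscle_set : {'task_muscles', 'all_four'}
        ``task_muscles`` keeps the two electrodes involved in the current
        task phase: the distal pair (wrist/finger extensors) for the hand
        task, the proximal pair (biceps/triceps) for the reaching task.
    task_phase : {'hand', 'arm'}
    """
    if arm_set not in ("paretic", "healthy", "both"):
        raise ValueError(f"unknown arm set {arm_set!r}")
    if muscle_set not in ("task_muscles", "all_four"):
        raise ValueError(f"unknown muscle set {muscle_set!r}")
    if task_phase not in ("hand", "arm"):
        raise ValueError(f"unknown task phase {task_phase!r}")
    arms = ("paretic", "healthy") if arm_set == "both" else (arm_set,)
    if muscle_set == "all_four":
        muscles = EMG_MUSCLES
    else:
        muscles = ("ecu", "ed") if task_phase == "hand" else ("biceps", "triceps")
    return tuple(f"{a}_{m}" for a in arms for m in muscles)
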