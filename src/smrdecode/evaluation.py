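"""Pseudo-online evaluation: the TP-FP metric and the factorial design grid.

A decoder configuration is one cell of the factorial design compared in the
study: for EEG, electrode set x spatial filter x frequency band x
classifier (3 x 3 x 3 x 2 = 54 cells); for EMG, arm set x muscle set x
classifier (3 x 2 x 2 = 12 cells).  Each session is replayed causally
through the configured pipeline and scored with TP - FP, where TP is the
fraction of movement-period frames classified as movement and FP the
fraction of rest-period frames classified as movement.  The metric is
invariant to a coupled output bias (a classifier that says "move" always
scores 0, like one that says "rest" always) — 1 is perfect, 0 is chance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import windows
from .decoders import AdaptiveSvmDecoder, SmrThresholdDecoder, gated_states
from .emg import extract_emg_features
from .montage import BANDS, ELECTRODE_SETS, resolve_electrode_set, resolve_task_muscles
from .spatial import SPATIAL_FILTERS
from .spectral import extract_eeg_features, motor_feature_tensor
from .windows import BOUNDARY, MOVE, REST

CLASSIFIERS = ("threshold", "asvm")
ARM_SETS = ("paretic", "healthy", "both")
MUSCLE_SETS = ("task_muscles", "all_four")

EEG_FACTORS = ("electrode_set", "spatial_filter", "band", "classifier")
EMG_FACTORS = ("arm_set", "muscle_set", "classifier")


@dataclass(frozen=True)
class DecoderConfig:
    """One cell of the factorial design."""

    modality: str = "eeg"
    electrode_set: str | None = "bihemispheric"
    spatial_filter: str | None = "car"
    band: str | None = "beta"
    arm_set: str | None = None
    muscle_set: str | None = None
    classifier: str = "asvm"

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        if self.modality == "eeg":
            if self.electrode_set not in ELECTRODE_SETS:
                raise ValueError(f"electrode_set must be one of {ELECTRODE_SETS}")
            if self.spatial_filter not in SPATIAL_FILTERS:
                raise ValueError(f"spatial_filter must be one of {SPATIAL_FILTERS}")
            if self.band not in BANDS:
                raise ValueError(f"band must be one of {sorted(BANDS)}")
            if self.arm_set is not None or self.muscle_set is not None:
                raise ValueError("EMG fields must be unset for modality 'eeg'")
        elif self.modality == "emg":
            if self.arm_set not in ARM_SETS:
                raise ValueError(f"arm_set must be one of {ARM_SETS}")
            if self.muscle_set not in MUSCLE_SETS:
                raise ValueError(f"muscle_set must be one of {MUSCLE_SETS}")
            if not (self.electrode_set is None and self.spatial_filter is None
                    and self.band is None):
                raise ValueError("EEG fields must be unset for modality 'emg'")
        else:
            raise ValueError("modality must be 'eeg' or 'emg'")

    def label(self) -> str:
        if self.modality == "eeg":
            return (f"eeg/{self.electrode_set}/{self.spatial_filter}/"
                    f"{self.band}/{self.classifier}")
        return f"emg/{self.arm_set}/{self.muscle_set}/{self.classifier}"


def eeg_grid() -> list[DecoderConfig]:
    """All 54 EEG design cells."""
    return [
        DecoderConfig(modality="eeg", electrode_set=e, spatial_filter=f,
                      band=b, classifier=c)
        for e, f, b, c in itertools.product(
            ELECTRODE_SETS, SPATIAL_FILTERS, sorted(BANDS), CLASSIFIERS)
    ]


def emg_grid() -> list[DecoderConfig]:
    """All 12 EMG design cells."""
    return [
        DecoderConfig(modality="emg", electrode_set=None, spatial_filter=None,
                      band=None, arm_set=a, muscle_set=m, classifier=c)
        for a, m, c in itertools.product(ARM_SETS, MUSCLE_SETS, CLASSIFIERS)
    ]


def full_grid() -> list[DecoderConfig]:
    return eeg_grid() + emg_grid()


@dataclass
class SessionResult:
    """TP, FP and TP-FP of one session under one configuration."""

    tp: float
    fp: float
    score: float = field(init=False)
    config: DecoderConfig | None = None
    patient: int | None = None
    session: int | None = None

    def __post_init__(self) -> None:
        self.score = self.tp - self.fp


def label_periods(session) -> np.ndarray:
    """Rest/move/boundary label of every sliding window of a session.

    Frames whose full 500 ms support lies inside a movement-attempt period
    are ``MOVE``; frames inside an inter-trial interval are ``REST``; all
    others — instruction gaps and cue-straddling windows — are ``BOUNDARY``
    and excluded from TP/FP counting.
    """
    return session.frame_labels()


def compute_tp_fp(predictions, labels) -> tuple[float, float, float]:
    """TP, FP and TP-FP score over non-boundary frames.

    ``predictions`` are classifier outputs in {REST, MOVE}; ``labels`` the
    ground-truth period labels.  Raises if either class is absent.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have the same length")
    move = labels == MOVE
    rest = labels == REST
    if not move.any() or not rest.any():
        raise ValueError("TP-FP needs at least one move and one rest frame")
    tp = float(np.mean(predictions[move] == MOVE))
    fp = float(np.mean(predictions[rest] == MOVE))
    return tp, fp, tp - fp


def _make_decoder(config: DecoderConfig, group: str):
    if config.classifier == "asvm":
        return AdaptiveSvmDecoder()
    if config.modality == "emg":
        # waveform length rises with activation -> high side maps to move
        return SmrThresholdDecoder(modulation="ers")
    return SmrThresholdDecoder(modulation="ers" if group == "C-" else "erd")


def _score_stream(X, labels, config: DecoderConfig, group: str,
                  metric: str) -> tuple[float, float]:
    decoder = _make_decoder(config, group)
    pred = decoder.stream(X, labels)
    if metric == "gated":
        pred = gated_states(pred)
    elif metric != "output":
        raise ValueError("metric must be 'output' or 'gated'")
    tp, fp, _ = compute_tp_fp(pred, labels)
    return tp, fp


def run_pseudo_online(session, config: DecoderConfig,
                      metric: str = "output") -> SessionResult:
    """Replay one session through one design cell.

    Deterministic given the session and configuration.  ``metric='gated'``
    scores the debounced orthosis state instead of the raw 40 ms outputs.
    """
    if config.modality == "eeg":
        frames = extract_eeg_features(
            session, spatial_filter=config.spatial_filter,
            electrode_set=config.electrode_set, band=config.band)
    else:
        frames = extract_emg_features(
            session, arm_set=config.arm_set, muscle_set=config.muscle_set)
    tp, fp = _score_stream(frames.matrix(), frames.labels, config,
                           session.group, metric)
    return SessionResult(tp=tp, fp=fp, config=config,
                         patient=session.patient, session=session.session)


def run_design_grid(sessions, configs: list[DecoderConfig] | None = None,
                    metric: str = "output", progress: bool = False) -> pd.DataFrame:
    """Evaluate every (session x configuration) cell.

    Feature extraction is shared across cells: per session, one full
    motor-channel spectral tensor per spatial filter and one 8-channel
    waveform-length frame set serve all matching cells as slices.

    Returns a long-format table with one row per cell and all factor
    columns needed by the ANOVA stage.
    """
    configs = full_grid() if configs is None else list(configs)
    rows = []
    for session in sessions:
        labels = session.frame_labels()
        eeg_cfgs = [c for c in configs if c.modality == "eeg"]
        emg_cfgs = [c for c in configs if c.modality == "emg"]
        spectral_cache = {
            f: motor_feature_tensor(session, f)
            for f in sorted({c.spatial_filter for c in eeg_cfgs})
        }
        emg_cache = (
            extract_emg_features(session, arm_set="both", muscle_set="all_four")
            if emg_cfgs else None
        )
        for config in configs:
            if config.modality == "eeg":
                frames = spectral_cache[config.spatial_filter].select(
                    channels=resolve_electrode_set(
                        config.electrode_set, session.lesion_side),
                    band=config.band,
                )
            else:
                frames = emg_cache.select(resolve_task_muscles(
                    config.arm_set, config.muscle_set, session.task_phase))
            tp, fp = _score_stream(frames.matrix(), labels, config,
                                   session.group, metric)
            rows.append({
                "patient": session.patient, "session": session.session,
                "group": session.group, "modality": config.modality,
                "electrode_set": config.electrode_set,
                "spatial_filter": config.spatial_filter, "band": config.band,
                "arm_set": config.arm_set, "muscle_set": config.muscle_set,
                "classifier": config.classifier,
                "tp": tp, "fp": fp, "score": tp - fp,
            })
            if progress:
                print(f"patient {session.patient} session {session.session} "
                      f"{config.label()}: {tp - fp:+.3f}", flush=True)
    return pd.DataFrame(rows)


def cell_means(results: pd.DataFrame, factors=EEG_FACTORS) -> pd.DataFrame:
    """Mean score per design cell, best first."""
    factors = [f for f in factors if f in results.columns]
    return (results.groupby(list(factors), dropna=False)["score"]
            .mean().sort_values(ascending=False).reset_index())
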