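"""Session container I/O and run configuration.

Sessions are stored one per HDF5 file with a documented layout:

* ``/eeg``: (16, n_samples) float64 dataset, µV, attribute ``channels``;
* ``/emg``: (8, n_samples) float64 dataset, µV, attribute ``channels``;
* ``/events/times``: seconds; ``/events/kinds``: fixed-length UTF-8 codes;
* root attributes: ``fs``, ``lesion_side``, ``group``, ``seed``,
  ``task_phase``, ``format_version`` and optional ``patient``/``session``.

Round-trips are bitwise lossless.  Run configurations are YAML mappings
validated against the generator dataclasses; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import yaml

from .synthetic import EmgModel, SessionRecording, SmrModel, TrialProtocol

FORMAT_VERSION = 1


class SessionFormatError(Exception):
    """Raised for corrupt or incompatible session containers."""


def write_session(session: SessionRecording, path: str | Path) -> None:
    """Write a session to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["fs"] = session.fs
        f.attrs["lesion_side"] = session.lesion_side
        f.attrs["group"] = session.group
        f.attrs["seed"] = session.seed
        f.attrs["task_phase"] = session.task_phase
        if session.patient is not None:
            f.attrs["patient"] = session.patient
        if session.session is not None:
            f.attrs["session"] = session.session
        eeg = f.create_dataset("eeg", data=session.eeg)
        eeg.attrs["channels"] = list(session.eeg_channels)
        emg = f.create_dataset("emg", data=session.emg)
        emg.attrs["channels"] = list(session.emg_channels)
        ev = f.create_group("events")
        ev.create_dataset("times", data=np.asarray(session.event_times, float))
        ev.create_dataset(
            "kinds",
            data=np.array([k.encode() for k in session.event_kinds], dtype="S16"),
        )


def read_session(path: str | Path,
                 eeg_channels: list[str] | None = None) -> SessionRecording:
    """Read a session container; optionally only a subset of EEG channels.

    Raises :class:`SessionFormatError` on missing groups or an unknown
    container version.
    """
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise SessionFormatError(
                f"unsupported container version {version!r} in {path}")
        for key in ("eeg", "emg", "events"):
            if key not in f:
                raise SessionFormatError(f"container {path} is missing /{key}")
        if "times" not in f["events"] or "kinds" not in f["events"]:
            raise SessionFormatError(f"container {path} has a malformed events group")
        all_eeg = tuple(str(c) for c in f["eeg"].attrs["channels"])
        if eeg_channels is None:
            eeg = f["eeg"][()]
            kept = all_eeg
        else:
            idx = [all_eeg.index(c) for c in eeg_channels]
            eeg = f["eeg"][sorted(idx)]
            kept = tuple(all_eeg[i] for i in sorted(idx))
        return SessionRecording(
            eeg=eeg,
            emg=f["emg"][()],
            fs=float(f.attrs["fs"]),
            eeg_channels=kept,
            emg_channels=tuple(str(c) for c in f["emg"].attrs["channels"]),
            event_times=f["events"]["times"][()],
            event_kinds=np.array([k.decode() for k in f["events"]["kinds"][()]]),
            lesion_side=str(f.attrs["lesion_side"]),
            group=str(f.attrs["group"]),
            seed=int(f.attrs["seed"]),
            task_phase=str(f.attrs["task_phase"]),
            patient=int(f.attrs["patient"]) if "patient" in f.attrs else None,
            session=int(f.attrs["session"]) if "session" in f.attrs else None,
        )


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a generate/decode/grid run."""

    seed: int = 0
    n_patients: int = 2
    n_sessions: int = 1
    group: str = "C+"
    protocol: TrialProtocol = TrialProtocol()
    smr: SmrModel = SmrModel()
    emg: EmgModel = EmgModel()


def _build(cls, mapping, context: str):
    if mapping is None:
        return cls()
    if not isinstance(mapping, dict):
        raise ValueError(f"{context} must be a mapping")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in mapping.items()
    }
    return cls(**coerced)


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as f:
        raw = yaml.safe_load(f)
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ValueError("run config must be a YAML mapping")
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown keys in run config: {sorted(unknown)}")
    kwargs = {k: v for k, v in raw.items()
              if k in ("seed", "n_patients", "n_sessions", "group")}
    for name, cls in (("protocol", TrialProtocol), ("smr", SmrModel),
                      ("emg", EmgModel)):
        if name in raw:
            kwargs[name] = _build(cls, raw[name], name)
    cfg = RunConfig(**kwargs)
    if cfg.n_patients < 1 or cfg.n_sessions < 1:
        raise ValueError("n_patients and n_sessions must be >= 1")
    return cfg


def write_results(results, path: str | Path) -> None:
    """Write a grid results table as TSV."""
    results.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")


def save_decoder_state(decoder, path: str | Path) -> None:
    """Checkpoint a fitted decoder to an HDF5 container."""
    from .decoders import AdaptiveSvmDecoder, SmrThresholdDecoder

    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        if isinstance(decoder, SmrThresholdDecoder):
            f.attrs["kind"] = "threshold"
            f.attrs["modulation"] = decoder.modulation
            f.attrs["history_window"] = decoder.history_window or 0
            f.create_dataset("rest_history", data=np.asarray(decoder.rest_history_))
            f.create_dataset("move_history", data=np.asarray(decoder.move_history_))
            if decoder.threshold_ is not None:
                f.attrs["threshold"] = decoder.threshold_
        elif isinstance(decoder, AdaptiveSvmDecoder):
            if not decoder.is_ready:
                raise ValueError("cannot checkpoint an untrained adaptive SVM")
            f.attrs["kind"] = "asvm"
            for name in ("C", "buffer_frames", "update_stride", "min_fill",
                         "standardize", "kkt_tol"):
                f.attrs[name] = getattr(decoder, name)
            f.attrs["intercept"] = decoder.intercept_
            f.attrs["n_updates"] = decoder.n_updates_
            f.create_dataset("coef", data=decoder.coef_)
            f.create_dataset("mean", data=decoder.mean_)
            f.create_dataset("scale", data=decoder.scale_)
        else:
            raise TypeError(f"unsupported decoder type {type(decoder).__name__}")


def load_decoder_state(path: str | Path):
    """Restore a checkpointed decoder; its predict() matches the original."""
    from .decoders import AdaptiveSvmDecoder, SmrThresholdDecoder

    with h5py.File(path, "r") as f:
        kind = f.attrs["kind"]
        if kind == "threshold":
            hw = int(f.attrs["history_window"])
            dec = SmrThresholdDecoder(modulation=str(f.attrs["modulation"]),
                                      history_window=hw or None)
            dec._reset()
            dec.rest_history_ = list(f["rest_history"][()])
            dec.move_history_ = list(f["move_history"][()])
            dec.threshold_ = float(f.attrs["threshold"]) if "threshold" in f.attrs else None
            return dec
        if kind == "asvm":
            dec = AdaptiveSvmDecoder(
                C=float(f.attrs["C"]), buffer_frames=int(f.attrs["buffer_frames"]),
                update_stride=int(f.attrs["update_stride"]),
                min_fill=int(f.attrs["min_fill"]),
                standardize=bool(f.attrs["standardize"]),
                kkt_tol=float(f.attrs["kkt_tol"]))
            dec._reset(f["coef"].shape[0])
            dec.coef_ = f["coef"][()]
            dec.intercept_ = float(f.attrs["intercept"])
            dec.mean_ = f["mean"][()]
            dec.scale_ = f["scale"][()]
            dec.n_updates_ = int(f.attrs["n_updates"])
            return dec
        raise SessionFormatError(f"unknown decoder kind {kind!r} in {path}")


def write_gate_log(times, outputs, commands, path: str | Path) -> None:
    """Gate command log as TSV with columns (t, output, command)."""
    import pandas as pd

    pd.DataFrame({"t": times, "output": outputs, "command": commands}).to_csv(
        path, sep="\t", index=False)
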