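"""Synthetic cued motor-attempt sessions.

The generator emulates the statistical structure that sensorimotor-rhythm
(SMR) decoding assumes, without attempting to reproduce any real patient's
spectra:

* per-hemisphere mu (~10 Hz) and beta (~20 Hz) rhythms built from
  band-limited filtered-noise carriers, spatially weighted onto the motor
  electrode rows (C3/CP3/P3 and C4/CP4/P4) with small leakage to the midline;
* event-related desynchronization (ERD): during the 5 s movement-attempt
  period the rhythm amplitude is scaled by ``(1 - d)``, so band power drops
  by ``(1 - d)**2`` in expectation; ``d < 0`` models event-related
  synchronization (ERS), as in the contingent-negative intervention group;
* 1/f background noise per channel plus a shared common-mode component;
* slow within-session non-stationarity as a reflected random walk on the
  log-amplitude of each rhythm — the signal drift that motivates adaptive
  classifiers;
* optional ocular and muscular artifact bursts;
* residual paretic-arm EMG bursts during movement attempts, scaled by an
  impairment-linked gain, and weaker mirror activity on the healthy arm.

Trial timing follows the cued protocol: a 3 s inter-trial interval, an
auditory instruction, a go cue 2 s later, and an end cue 5 s after the go
cue.  Sessions are organised in blocks of trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .montage import EEG_CHANNELS, EMG_CHANNELS
from . import windows

FS = 500.0

#: Spatial projection of each hemisphere's rhythm onto the scalp montage.
DEFAULT_TOPOGRAPHY: dict[str, dict[str, float]] = {
    "L": {"C3": 1.0, "CP3": 0.8, "P3": 0.6, "Cz": 0.2, "Pz": 0.15},
    "R": {"C4": 1.0, "CP4": 0.8, "P4": 0.6, "Cz": 0.2, "Pz": 0.15},
}

GROUPS = ("C+", "C-", "sham")


@dataclass(frozen=True)
class TrialProtocol:
    """Timing of the cued-trial protocol (all durations in seconds)."""

    iti_duration: float = 3.0
    instruction_to_go: float = 2.0
    task_duration: float = 5.0
    trials_per_block: int = 17
    blocks_per_session: int = 15

    def __post_init__(self) -> None:
        for name in ("iti_duration", "instruction_to_go", "task_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.trials_per_block < 1 or self.blocks_per_session < 1:
            raise ValueError("trial/block counts must be >= 1")

    @property
    def n_trials(self) -> int:
        return self.trials_per_block * self.blocks_per_session

    def trial_samples(self, fs: float = FS) -> tuple[int, int, int, int]:
        """Samples of (iti, instruction gap, task, total-per-trial).

        One 40 ms analysis step of padding separates the end cue from the
        next trial's ITI onset: the event stream stays strictly increasing
        and every trial starts on the sliding-window grid, so per-trial
        frame counts are identical across trials.
        """
        iti = int(round(self.iti_duration * fs))
        ins = int(round(self.instruction_to_go * fs))
        task = int(round(self.task_duration * fs))
        pad = int(round(windows.STEP_S * fs))
        return iti, ins, task, iti + ins + task + pad

    def n_samples(self, fs: float = FS) -> int:
        return self.n_trials * self.trial_samples(fs)[3]

    def events(self, fs: float = FS) -> tuple[np.ndarray, np.ndarray]:
        """Event stream ``(times_s, kinds)`` for the whole session."""
        iti, ins, task, total = self.trial_samples(fs)
        t0 = np.arange(self.n_trials, dtype=np.int64) * total
        times = np.stack([t0, t0 + iti, t0 + iti + ins, t0 + iti + ins + task], axis=1)
        kinds = np.array(["iti_start", "instruction", "go", "end"])
        return times.ravel() / fs, np.tile(kinds, self.n_trials)


def _pair(v) -> tuple[float, float]:
    if np.isscalar(v):
        return float(v), float(v)
    a, b = v
    return float(a), float(b)


@dataclass(frozen=True)
class SmrModel:
    """Generative model of the EEG rhythms and background.

    Amplitudes are rhythm RMS in µV at the primary electrode of each
    hemisphere (C3 for left, C4 for right); two-element tuples give
    (left, right) hemisphere values, a scalar applies to both.  Modulation
    depths ``d`` scale the rhythm amplitude by ``(1 - d)`` during the
    movement-attempt period: ``d > 0`` is ERD, ``d < 0`` is ERS.
    """

    mu_center_hz: float = 10.0
    beta_center_hz: float = 20.0
    mu_amplitude: tuple[float, float] | float = 7.0
    beta_amplitude: tuple[float, float] | float = 4.0
    mu_depth: tuple[float, float] | float = 0.3
    beta_depth: tuple[float, float] | float = 0.6
    carrier_halfwidth_hz: float = 1.5
    #: 1/f background: one-sided PSD is ``noise_scale**2 * (f/10)**-noise_exponent``
    #: µV²/Hz, so ``noise_scale`` is the µV/√Hz amplitude density at 10 Hz.
    noise_exponent: float = 1.0
    noise_scale: float = 0.3
    common_mode_scale: float = 0.3
    #: Per-second SD of the reflected log-amplitude random walk and its
    #: reflecting bound.
    drift_scale: float = 0.05
    drift_bound: float = 0.4
    erd_ramp_s: float = 0.1
    artifact_rate: float = 0.0
    topography: dict[str, dict[str, float]] = field(
        default_factory=lambda: DEFAULT_TOPOGRAPHY
    )

    def __post_init__(self) -> None:
        for name in ("mu_amplitude", "beta_amplitude"):
            if min(_pair(getattr(self, name))) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("mu_depth", "beta_depth"):
            if max(abs(x) for x in _pair(getattr(self, name))) > 1:
                raise ValueError(f"|{name}| must be <= 1")
        if self.noise_scale < 0 or self.common_mode_scale < 0:
            raise ValueError("noise scales must be >= 0")
        if self.drift_scale < 0 or self.drift_bound <= 0:
            raise ValueError("drift_scale >= 0 and drift_bound > 0 required")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")


@dataclass(frozen=True)
class EmgModel:
    """Generative model of the bipolar surface EMG.

    ``residual_gain`` scales the paretic-arm burst amplitude during movement
    attempts (a monotone proxy for residual motor function / cFMA);
    ``mirror_gain`` scales involuntary co-activation of the healthy arm.
    """

    residual_gain: float = 0.1
    mirror_gain: float = 0.05
    burst_band: tuple[float, float] = (20.0, 150.0)
    baseline_noise: float = 2.0
    burst_amplitude: float = 8.0
    offtask_coactivation: float = 0.3
    ramp_s: float = 0.15

    def __post_init__(self) -> None:
        for name in ("residual_gain", "mirror_gain"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.burst_band
        if not 0 < lo < hi:
            raise ValueError("burst_band must be an increasing positive pair")
        if self.baseline_noise < 0 or self.burst_amplitude < 0:
            raise ValueError("noise/burst amplitudes must be >= 0")


@dataclass
class SessionRecording:
    """One recorded (here: simulated) training session."""

    eeg: np.ndarray  # (16, n_samples) µV
    emg: np.ndarray  # (8, n_samples) µV
    fs: float
    eeg_channels: tuple[str, ...]
    emg_channels: tuple[str, ...]
    event_times: np.ndarray  # seconds
    event_kinds: np.ndarray
    lesion_side: str  # {'L', 'R'}
    group: str  # {'C+', 'C-', 'sham'}
    seed: int
    task_phase: str = "hand"
    patient: int | None = None
    session: int | None = None

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def events(self) -> list[tuple[float, str]]:
        return [(float(t), str(k)) for t, k in zip(self.event_times, self.event_kinds)]

    def frame_labels(self) -> np.ndarray:
        """Rest/move/boundary label of every sliding decoding window."""
        return windows.label_frames(
            self.event_times, self.event_kinds, self.n_samples, self.fs
        )

    def task_spans(self) -> list[tuple[float, float]]:
        """(go, end) times of every movement-attempt period."""
        spans, go = [], None
        for t, k in self.events:
            if k == "go":
                go = t
            elif k == "end" and go is not None:
                spans.append((go, t))
                go = None
        return spans


def _one_over_f(rng: np.random.Generator, n: int, fs: float, scale: float,
                exponent: float) -> np.ndarray:
    """Gaussian noise with one-sided PSD ``scale**2 * (f/10)**-exponent`` µV²/Hz."""
    if scale == 0.0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f_eff = np.maximum(f, 0.5)  # flatten below 0.5 Hz instead of diverging
    gain = scale * np.sqrt(fs / 2.0) * (f_eff / 10.0) ** (-exponent / 2.0)
    gain[0] = 0.0
    return np.fft.irfft(spec * gain, n)


def _carrier(rng: np.random.Generator, n: int, fs: float, center: float,
             halfwidth: float) -> np.ndarray:
    """Unit-RMS band-limited noise carrier."""
    lo = max(center - halfwidth, 0.5)
    hi = min(center + halfwidth, fs / 2 - 1.0)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n + int(2 * fs)))[int(2 * fs):]
    return x / x.std()


def _reflected_walk(rng: np.random.Generator, n: int, fs: float, scale: float,
                    bound: float) -> np.ndarray:
    """Log-amplitude random walk reflected into [-bound, bound], per sample."""
    if scale == 0.0:
        return np.zeros(n)
    n_sec = int(np.ceil(n / fs)) + 1
    steps = rng.normal(0.0, scale, n_sec)
    steps[0] = rng.uniform(-bound, bound)
    walk = np.cumsum(steps)
    walk = np.abs(np.mod(walk + bound, 4.0 * bound) - 2.0 * bound) - bound
    t = np.arange(n) / fs
    return np.interp(t, np.arange(n_sec, dtype=float), walk)


def _task_ramp(protocol: TrialProtocol, n: int, fs: float, ramp_s: float) -> np.ndarray:
    """0/1 envelope of the movement-attempt period with short cosine ramps."""
    iti, ins, task, total = protocol.trial_samples(fs)
    env = np.zeros(n)
    nr = max(int(round(ramp_s * fs)), 1)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(nr) / nr))
    for i in range(protocol.n_trials):
        go = i * total + iti + ins
        end = go + task
        env[go:go + nr] = ramp
        env[go + nr:end - nr] = 1.0
        env[end - nr:end] = ramp[::-1]
    return env


def generate_session(
    protocol: TrialProtocol,
    smr: SmrModel,
    emg: EmgModel,
    lesion_side: str = "R",
    group: str = "C+",
    seed: int = 0,
    task_phase: str = "hand",
    patient: int | None = None,
    session: int | None = None,
    fs: float = FS,
) -> SessionRecording:
    """Simulate one cued motor-attempt session.

    Deterministic for a fixed ``seed``.  The expected task/rest band-power
    ratio at a modulated electrode is ``(1 - d)**2``.
    """
    if lesion_side not in ("L", "R"):
        raise ValueError("lesion_side must be 'L' or 'R'")
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    if task_phase not in ("hand", "arm"):
        raise ValueError("task_phase must be 'hand' or 'arm'")
    rng = np.random.default_rng(seed)
    n = protocol.n_samples(fs)
    ev_t, ev_k = protocol.events(fs)

    eeg = np.empty((len(EEG_CHANNELS), n))
    for c in range(len(EEG_CHANNELS)):
        eeg[c] = _one_over_f(rng, n, fs, smr.noise_scale, smr.noise_exponent)
    eeg += _one_over_f(rng, n, fs, smr.common_mode_scale, smr.noise_exponent)

    task_env = _task_ramp(protocol, n, fs, smr.erd_ramp_s)
    bands = {
        "mu": (smr.mu_center_hz, _pair(smr.mu_amplitude), _pair(smr.mu_depth)),
        "beta": (smr.beta_center_hz, _pair(smr.beta_amplitude), _pair(smr.beta_depth)),
    }
    for center, amps, depths in bands.values():
        for hi, hemi in enumerate("LR"):
            amp, d = amps[hi], depths[hi]
            if amp == 0.0:
                continue
            carrier = _carrier(rng, n, fs, center, smr.carrier_halfwidth_hz)
            drift = np.exp(_reflected_walk(rng, n, fs, smr.drift_scale, smr.drift_bound))
            rhythm = carrier * (amp * drift * (1.0 - d * task_env))
            for ch, w in smr.topography[hemi].items():
                eeg[EEG_CHANNELS.index(ch)] += w * rhythm

    if smr.artifact_rate > 0:
        _add_artifacts(rng, eeg, fs, smr.artifact_rate)

    emg_arr = _generate_emg(rng, protocol, emg, n, fs, task_phase)

    return SessionRecording(
        eeg=eeg,
        emg=emg_arr,
        fs=fs,
        eeg_channels=EEG_CHANNELS,
        emg_channels=EMG_CHANNELS,
        event_times=ev_t,
        event_kinds=ev_k,
        lesion_side=lesion_side,
        group=group,
        seed=int(seed),
        task_phase=task_phase,
        patient=patient,
        session=session,
    )


def _add_artifacts(rng: np.random.Generator, eeg: np.ndarray, fs: float,
                   rate_per_min: float) -> None:
    """Ocular and muscular artifact bursts at Poisson times (half/half)."""
    n = eeg.shape[1]
    n_events = rng.poisson(rate_per_min * n / fs / 60.0)
    frontal = {"Fp1": 1.0, "Fp2": 1.0, "F3": 0.4, "Fz": 0.4, "F4": 0.4}
    for _ in range(n_events):
        start = rng.integers(0, max(n - int(0.5 * fs), 1))
        if rng.random() < 0.5:  # ocular: smooth large deflection, frontal
            dur = int(0.4 * fs)
            shape = 40.0 * rng.uniform(0.5, 1.5) * np.hanning(dur)
            for ch, w in frontal.items():
                eeg[EEG_CHANNELS.index(ch), start:start + dur] += w * shape
            eeg[:, start:start + dur] += 0.05 * shape  # far-field spread
        else:  # muscular: broadband burst at a temporal site
            dur = int(0.3 * fs)
            sos = sps.butter(4, [20.0, 100.0], btype="bandpass", fs=fs, output="sos")
            burst = sps.sosfilt(sos, rng.standard_normal(dur + 200))[200:]
            burst *= 15.0 * np.hanning(dur) / max(burst.std(), 1e-12)
            site = "T7" if rng.random() < 0.5 else "T8"
            eeg[EEG_CHANNELS.index(site), start:start + dur] += burst


def _generate_emg(rng: np.random.Generator, protocol: TrialProtocol,
                  emg: EmgModel, n: int, fs: float, task_phase: str) -> np.ndarray:
    iti, ins, task, total = protocol.trial_samples(fs)
    nr = max(int(round(emg.ramp_s * fs)), 1)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(nr) / nr))
    primary = ("ecu", "ed") if task_phase == "hand" else ("biceps", "triceps")
    sos = sps.butter(4, list(emg.burst_band), btype="bandpass", fs=fs, output="sos")

    out = rng.normal(0.0, emg.baseline_noise, (len(EMG_CHANNELS), n))
    arm_gain = {"paretic": emg.residual_gain, "healthy": emg.mirror_gain}
    # per-trial amplitude jitter shared across channels of a trial
    trial_jit = np.exp(rng.normal(0.0, 0.2, protocol.n_trials))
    for c, name in enumerate(EMG_CHANNELS):
        arm, muscle = name.split("_", 1)
        gain = arm_gain[arm] * emg.burst_amplitude
        if gain == 0.0:
            continue
        muscle_w = 1.0 if muscle in primary else emg.offtask_coactivation
        carrier = sps.sosfilt(sos, rng.standard_normal(n + 200))[200:]
        carrier /= carrier.std()
        env = np.zeros(n)
        for i in range(protocol.n_trials):
            go = i * total + iti + ins
            end = go + task
            a = gain * muscle_w * trial_jit[i]
            env[go:go + nr] = a * ramp
            env[go + nr:end - nr] = a
            env[end - nr:end] = a * ramp[::-1]
        out[c] += carrier * env
    return out


@dataclass
class ShamSchedule:
    """Per-trial orthosis on/off timeline for the sham feedback group.

    Moving-time fractions are drawn uniformly from [0.55, 0.80] of the task
    period — the range enforced for the sham condition — and placed as
    alternating move/stop segments, independent of any EEG.
    """

    task_duration: float
    fractions: np.ndarray  # (n_trials,)
    intervals: list[np.ndarray]  # per trial: (k, 2) moving [start, stop) in s

    @property
    def moving_time(self) -> np.ndarray:
        return self.fractions * self.task_duration


def generate_sham_schedule(
    protocol: TrialProtocol,
    seed: int = 0,
    n_trials: int | None = None,
    fraction_range: tuple[float, float] = (0.55, 0.80),
) -> ShamSchedule:
    """Random orthosis schedule with per-trial moving fraction in the sham range."""
    if protocol.task_duration <= 0:
        raise ValueError("task_duration must be > 0")
    rng = np.random.default_rng(seed)
    nt = protocol.n_trials if n_trials is None else int(n_trials)
    lo, hi = fraction_range
    fractions = rng.uniform(lo, hi, nt)
    intervals = []
    task = protocol.task_duration
    for f in fractions:
        k = rng.integers(1, 4)  # number of moving segments
        move_t = f * task
        stop_t = task - move_t
        move_parts = rng.dirichlet(np.ones(k)) * move_t
        stop_parts = rng.dirichlet(np.ones(k + 1)) * stop_t
        t = 0.0
        spans = np.empty((k, 2))
        for i in range(k):
            t += stop_parts[i]
            spans[i, 0] = t
            t += move_parts[i]
            spans[i, 1] = t
        intervals.append(spans)
    return ShamSchedule(task, fractions, intervals)


def synthetic_cohort(
    n_patients: int,
    n_sessions: int,
    protocol: TrialProtocol | None = None,
    smr: SmrModel | None = None,
    emg: EmgModel | None = None,
    seed: int = 0,
    group: str = "C+",
):
    """Yield sessions of a synthetic patient cohort.

    Patients differ by lesion side (alternating) and by mild random scaling
    of rhythm amplitudes and modulation depths; sessions of one patient
    differ only by realization noise and drift.  Deterministic in ``seed``.
    """
    protocol = protocol or TrialProtocol()
    smr = smr or SmrModel()
    emg = emg or EmgModel()
    master = np.random.default_rng(seed)
    for p in range(n_patients):
        side = "L" if p % 2 == 0 else "R"
        amp_f = float(np.exp(master.normal(0.0, 0.15)))
        depth_f = float(master.uniform(0.8, 1.0))
        p_smr = replace(
            smr,
            mu_amplitude=tuple(a * amp_f for a in _pair(smr.mu_amplitude)),
            beta_amplitude=tuple(a * amp_f for a in _pair(smr.beta_amplitude)),
            mu_depth=tuple(d * depth_f for d in _pair(smr.mu_depth)),
            beta_depth=tuple(d * depth_f for d in _pair(smr.beta_depth)),
        )
        for s in range(n_sessions):
            sess_seed = int(master.integers(0, 2**31 - 1))
            yield generate_session(
                protocol, p_smr, emg,
                lesion_side=side, group=group, seed=sess_seed,
                patient=p + 1, session=s + 1,
            )
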