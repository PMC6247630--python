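# Methods

`smrdecode` re-creates, end to end and without any patient data, the
pseudo-online evaluation loop of a sensorimotor-rhythm (SMR) brain-machine
interface for severely paralyzed stroke patients: synthetic cued
motor-attempt sessions, spectral and muscle-activity features on a sliding
window, two adaptive movement-intention classifiers, the bias-invariant
TP−FP performance score, and the factorial comparison of design choices
(electrode set × spatial filter × frequency band × classifier for EEG;
arm × muscle subsets for EMG).  This note documents the models, the
numerical choices, and what the synthetic experiments can and cannot show.

## Trial protocol and labeling

A session is a sequence of cued trials: 3 s inter-trial interval (ITI), an
auditory instruction, a go cue 2 s later, and an end cue 5 s after the go
cue; trials are organised in blocks of 17, with 15–20 blocks in a full
training session.  All decoding runs on 500 ms windows advanced in 40 ms
steps (the online update rate).  A window is labeled *move* when its full
support lies inside a go→end period and *rest* when it lies inside an ITI;
windows straddling a cue or inside the instruction gap are *boundary* and
excluded from both classifier adaptation and scoring.  One 40 ms padding
step separates the end cue from the next ITI so that the event stream is
strictly increasing and every trial starts on the window grid, which makes
per-trial frame counts exact (113 move and 63 rest frames per trial).

The choice to label from the go cue (rather than from first orthosis
motion), and to count TP/FP per 40 ms classifier output (rather than per
gated orthosis command), are the package's conventions; a gated-command
scoring variant is available (`metric="gated"`).

## Synthetic session generator

The generator produces the statistical structure the decoding analysis
assumes, not realistic patient EEG:

* **Rhythms.** Mu (10 Hz) and beta (20 Hz) carriers are band-limited
  Gaussian noise (order-4 Butterworth, ±1.5 Hz, unit RMS), one per
  hemisphere per band, scaled to `mu_amplitude` / `beta_amplitude` µV RMS
  and projected onto the scalp with fixed weights (C row 1.0, CP row 0.8,
  P row 0.6, small leakage to Cz/Pz).  Filtered-noise carriers rather than
  sinusoids give realistic within-band spectra and make the spatial-filter
  comparison meaningful.
* **Event-related (de)synchronization.** During the movement-attempt
  period the carrier amplitude is scaled by `(1 − d)` with a 0.1 s cosine
  ramp, so task-period band power is `(1 − d)²` × rest power in
  expectation (`d > 0` = ERD; `d < 0` = ERS, the contingent-negative
  condition).  Defaults: d = 0.3 (mu) and 0.6 (beta) on both hemispheres —
  a beta-dominant, bihemispheric modulation.
* **Background.** Per-channel 1/f noise with one-sided PSD
  `noise_scale² (f/10 Hz)^-1` µV²/Hz (default 0.09 µV²/Hz at 10 Hz,
  flattened below 0.5 Hz) plus an equally scaled common-mode component
  shared by all electrodes (what CAR removes exactly).  The default
  rhythm-to-background ratio is high enough that the measured band-power
  ratio sits within a few percent of the `(1 − d)²` contract; the exact
  contract is verified in tests on rhythm-only sessions, and a separate
  test documents the small upward bias the additive background introduces.
* **Non-stationarity.** Each rhythm's log-amplitude follows a random walk
  (σ = 0.05 per √s) reflected at ±0.4, i.e. slow power drifts of roughly
  ×0.45–×2.2 over a session with a mixing time of about a minute.  This is
  the drift that motivates adaptive classifiers.
* **Artifacts.** Optional (default rate 0): smooth 40 µV frontal
  deflections emulating blinks and 0.3 s broadband temporal bursts
  emulating muscle artifacts, at Poisson times independent of the cues.
* **EMG.** Eight bipolar channels (paretic/healthy × wrist extensor,
  finger extensor, biceps, triceps): Gaussian baseline noise (2 µV RMS)
  plus 20–150 Hz noise bursts during task periods.  Burst amplitude is
  `residual_gain × 8 µV` on the paretic arm and `mirror_gain × 8 µV` on
  the healthy arm (involuntary mirror activity), with the task-phase
  muscle pair at full weight and the other pair at 0.3.  `residual_gain`
  defaults to 0.1: residual bursts below the noise floor, matching a
  severely paralyzed cohort in which muscle decoding is possible but
  clearly inferior to EEG; gains ≥ 0.3 are nearly perfectly decodable, so
  the monotone link between residual function and EMG decodability is
  preserved.

All randomness flows from one integer seed per session;
`synthetic_cohort` derives per-patient amplitude/depth scalings and
per-session seeds from a master seed, so any cohort run is reproducible
end to end.

The sham feedback schedule is generated independently of any signal: each
trial's orthosis moving-time fraction is drawn uniformly from [0.55, 0.80]
of the task period (the range enforced in the sham condition) and placed
as 1–3 alternating move/stop segments.

What passing tests do **not** show: nothing here validates decoding of
real stroke EEG — there is no volume-conduction head model, no real
artifact statistics, no EOG, and patient-level accuracies are not
comparable to clinical data.  The synthetic cohort supports *relative*
statements about pipeline design under known ground truth, which is what
the factorial comparison needs.

## Features

* **EEG.** The spatial filter (none, common average reference, or small
  Laplacian with a fixed neighbor table) is applied to the full 16-channel
  montage before any channel subsetting.  Each 500 ms window is demeaned
  and fitted with a 16th-order autoregressive model by the Burg lattice
  recursion; the AR power spectral density is evaluated at the 20 bin
  centers 2, 4, …, 40 Hz and natural-log transformed.  Band membership is
  by bin center: alpha {8, 10, 12}, beta {16, …, 30}, alpha+beta
  {8, …, 30} (15 Hz is not a center; the nearest-inclusive rule is a
  documented convention, as is center evaluation rather than integration
  over bin ranges).  Zero-variance windows map to a log-power floor
  (`log` of the smallest positive double) instead of raising.
* **EMG.** Channels are band-passed 5–200 Hz with an order-10 Butterworth
  filter, applied zero-phase by default to avoid group delay relative to
  the cue labels (a causal mode is available), then summarised per window
  by waveform length `WL = Σ|x_k − x_{k−1}|`.
* **Screening.** `rsquare_screening` ranks every (channel, bin) pair by
  the squared point-biserial correlation between the period label and log
  power — the quantitative core of the original feature-selection step,
  with a deterministic tie-break.

The Burg recursion is a batched numba kernel (a grid run needs several
hundred thousand AR fits per session); its coefficients are tested to
machine precision against the reference implementation in statsmodels.

## Classifiers

* **Threshold classifier.** The per-frame feature is the mean log power
  over the selected electrode-frequency pairs.  The classifier keeps one
  history of per-period mean powers per class; the decision threshold is
  the midpoint of the two history means, re-derived after every completed
  period (supervised adaptation from cue labels; whether the original
  online system adapted from cue labels or orthosis state is not
  documented, so the simpler convention is used).  With ERD polarity,
  power below threshold maps to *move*; exact ties map to *rest*; the
  polarity inverts for ERS semantics.  The history is unbounded within a
  session by default (an optional forgetting window exists).
* **Adaptive linear SVM.** Two rolling buffers hold the most recent
  2 minutes of rest-period and movement-period frames (300 frames per
  class at one append per 400 ms).  Every 10th frame with a non-boundary
  label is appended to its class buffer (oldest evicted at capacity) and
  the model is brought to the *exact* C-SVM solution (linear kernel,
  C = 1) of the current buffers.  Features are z-scored with
  buffer-derived mean/SD refreshed at each retrain (switchable off);
  before both buffers hold 10 frames the prediction is rest.
* **Orthosis gate.** The orthosis state flips only after five consecutive
  identical classifier outputs that differ from the current state; a
  single command is emitted at the flip.

### Exact warm-started SVM solver

The retraining contract is *solution equivalence to batch training*.  It
is met by a primal active-set method on the SVM dual QP: with a linear
kernel the free support set is small (at most about n_features + 1 points
generically), so each outer iteration solves the equality-constrained KKT
system on the free set directly (kernel sub-matrix maintained
incrementally, tiny ridge 1e−12 for degenerate sets) and either moves a
multiplier to a bound or verifies global KKT optimality to 1e−10.
Warm-started from the previous buffer's multipliers the solver typically
needs a handful of outer iterations per retrain; a failed warm start falls
back to a cold solve.  Warm-started and from-scratch solves agree to well
below 1e−6 on decision values (tested), and decision functions agree with
libsvm (sklearn `SVC`) to that solver's own tolerance.  The streaming loop
(buffers, z-scoring, solve, prediction) is one compiled kernel; a
per-frame Python API with identical semantics is kept and tested
equivalent.

## Evaluation and statistics

`run_pseudo_online` replays a session causally through one design cell and
scores TP − FP over non-boundary frames (TP = movement-classified fraction
of move frames, FP = of rest frames): 1 is perfect, 0 is chance, and a
coupled output bias cancels by construction.  `run_design_grid` evaluates
every (session × cell) pair, sharing feature extraction across cells (one
motor-channel spectral tensor per spatial filter, one 8-channel
waveform-length set per session); each cell is a pure slice.  One score
per session per cell; classifier state never crosses sessions.

Factor influence is tested with a main-effects OLS ANOVA (type-II sums of
squares via statsmodels — identical to other types on the balanced grids
produced here); pairwise level comparisons use Wilcoxon's rank-sum test
with Bonferroni correction (`min(1, p × n_pairs)`).

## Reduced problem sizes

The acceptance-scale experiment uses 10 synthetic patients × 3 sessions of
5 blocks × 17 trials (≈ 14 min of recording per session) across the full
54-cell EEG and 12-cell EMG grids — large enough for the design contrasts
to be decisive, small enough to run on a laptop core in minutes.  Unit
tests use 1–2 block sessions; the generator's modulation contract is
verified on 50-trial rhythm-only sessions.

## Known limitations

* No head-model forward simulation, no EOG, no artifact-correlated task
  activity; the CAR-vs-none contrast therefore hinges only on the
  common-mode component and is smaller than in real data.
* The threshold classifier's online behavior is simulated with supervised
  trial-wise adaptation; closed-loop feedback effects (operant
  conditioning) are outside the model.
* Absolute TP−FP values on synthetic cohorts are not comparable to
  clinical results; only orderings and factor effects are meaningful.
* The small-Laplacian neighbor table is fixed configuration; other
  neighbor conventions will shift its results.
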