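# Methods

This note documents the models, parameter choices and numerical decisions
behind `eegtw`, in the spirit of a package reference manual.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic corpus

The generator emulates the structure of a three-class film-clip EEG study:
`n_subjects` (default 15) × `n_experiments_per_subject` (default 3)
sessions, each with exactly 15 trials of `trial_duration` (180 s) at
`sampling_rate` (200 Hz) over 62 montage channels.  The emotion labels
follow the fixed presentation order `1, 0, −1, −1, 0, 1, −1, 0, 1, 1, 0,
−1, 0, 1, −1` (5 trials per class per session).

Each trial is a sum of five band-limited Gaussian processes, one per
canonical band.  The default synthesis is spectral: complex-Gaussian rFFT
coefficients are drawn on the band's frequency support
`[low − 0.5, high + 0.5)` Hz and normalized via Parseval so each
component's time-domain variance equals its target power *exactly*.  This
exactness is the point of the generator — class and drift effects enter
the data with no synthesis error, and only band-power *estimation* noise
remains downstream.  A zero-phase 4th-order Butterworth alternative
(`synthesis="filtered"`) is provided and cross-checked in the tests; it is
slower and retains filter roll-off inside the band but produces the same
band structure.

Target power per (channel, band) for a trial with label *y*:

    P = noise_floor · exp(effect[y, band]) · ch_gain[channel] · gain[band]
        + noise_floor · offset,   clipped below at 1e-6 · noise_floor

- **Class effects** (`class_band_effects`): per-band log-power offsets.
  No published effect sizes exist for real inter-class band-power
  differences, so the defaults were chosen once to give clear but
  non-trivial separability: positive = (0, 0, −0.3, 0.5, 0.8), neutral =
  (0, 0, 0.3, 0, 0), negative = (0.2, 0.3, 0.1, −0.2, −0.4) — i.e.
  beta/gamma elevation for positive affect, alpha elevation for neutral,
  slow-band elevation for negative, in line with the qualitative EEG
  affect literature.
- **Session drift**: one log-normal multiplicative power gain *per band*
  (sd `drift_gain_sd`, default 0.5) and one scalar additive power offset
  (sd `drift_offset_sd`, default 0.3), drawn once per session and shared
  by its 15 trials.  The gain is per band rather than scalar because a
  scalar gain is a rank-one nuisance that high-dimensional linear
  classifiers absorb without loss; a per-band gain scrambles the band
  ratios that carry the class signal, while remaining exactly
  multiplicative per (channel, band) — precisely the distortion class that
  session-level min–max normalization removes.
- **Channel heterogeneity**: a fixed log-normal per-channel gain profile
  (sd `channel_gain_sd`, default 0.2) drawn once per subject, so the
  channel axis is non-degenerate without inventing scalp topography.

All randomness is keyed: substreams derive from
`(seed, role, subject, experiment, trial)`, so generation order is
irrelevant and any trial can be regenerated in isolation.

What the generator does **not** model: ocular/muscular artifacts, line
noise, volume conduction and realistic topography, non-stationarity within
a trial, or 1/f background spectra.  Passing tests therefore demonstrate
correctness of the pipeline's arithmetic and the drift/normalization
mechanism, not expected accuracy levels on real recordings — real-data
accuracies depend on effect sizes this corpus does not estimate.

## Features

- Channel selection drops PO5, PO6, CB1, CB2 by name (62 → 58), erroring
  if the names are absent.  Epochs are 0-based half-open 1-s sample
  windows `[k·fs, (k+1)·fs)`; surplus samples beyond 180 s are discarded.
- PSD estimator: single-epoch Hann periodogram, one-sided, density
  scaling.  At 200 Hz a 1-s epoch gives exactly 1 Hz bin spacing, so band
  power is the sum of bins whose center frequency lies in `[low, high]`
  inclusive, times the bin width.  No estimator choice is canonical here;
  the single-epoch periodogram maps 1 Hz bins cleanly onto the integer
  band edges and keeps the epoch the atomic unit.
- DE is computed from band power via the Gaussian closed form
  `½ ln(2πe·P)` in nats rather than from a separately filtered time
  series: deterministic, and consistent with the PSD stage.  Non-positive
  powers (possible only for degenerate all-zero epochs) are clipped to
  machine epsilon with a logged warning.
- LDS smoothing is a fixed-interval Rauch–Tung–Striebel smoother for the
  random-walk-plus-noise model, applied independently per (channel, band)
  across the 180 epochs.  Only the ratio q/r matters; the default 0.01
  smooths aggressively while leaving constants fixed points exactly and
  recovering the identity as q/r → ∞.  Initialization: state = first
  observation, state variance = the sequence's sample variance (falling
  back to r for constant sequences).  Whether smoothing applies to PSD,
  DE or both is configurable; the default applies it to both.

## Time windows and ELBN

Offline windows are non-overlapping and contiguous from epoch 0; only the
11 canonical lengths (all dividing 180) are accepted, keeping the window
arithmetic exact.  Aggregation is the arithmetic mean, so the mean of
window means equals the epoch mean (used as a cross-check by the
sensitivity-map stage).

ELBN pools the min/max per (channel, band) over all 15 × N window values
of a session by default.  The single-window (N = 1) case is the canonical
rule; pooled extrema are the generalization that reduces to it at N = 1.
A `per_window_index` pooling variant is available.  Degenerate ranges
(F_max = F_min) map to 0, keeping outputs in [0, 1] and finite.  The
protocol-faithful mode fits extrema on all 15 trials — including trials a
later split designates as test trials, which leaks their extrema into
normalization; a `causal` mode fits on the split's training trials only
(held-out outputs may then leave [0, 1]).  The leak is inherent to the
published protocol, so the faithful mode is the default and the causal
mode is the documented deviation.

## Offline evaluation

Samples are trial-level flattened vectors in (channel, band, window)
order; the five bands are concatenated into one vector (a per-band mode
is not provided — band-wise evaluation can be had by slicing tensors
before sample construction).  The ten split sets are fixed verbatim,
including set 3's train/test overlap on trial 12, which is preserved for
protocol fidelity and logged.  Classifier configurations: KNN(k=5,
Euclidean); logistic regression (liblinear, seed 10) wrapped in an
explicit one-vs-rest combiner (recent scikit-learn removed liblinear's
implicit multiclass handling; the wrapper reproduces it); RBF SVM (seed
10); Gaussian naive Bayes; MLP (lbfgs, α=1e-5, hidden (100, 3), seed 1,
max_iter 1e5); bagging of 500 liblinear logistic regressions (seed 1).
Accuracy is the overall fraction correct — test folds are class-balanced,
so overall and macro accuracy coincide in expectation.  No feature scaling
is applied beyond ELBN.

## Online recognition

The offline trial-level model (dimension 58·5·N) cannot score a single
2-s window (dimension 290), so the online classifier is trained on
window-level samples: each training trial contributes all of its sliding
windows, labelled with the trial's emotion.  This is the only
dimensionally consistent protocol.  ELBN stats for online features pool
over all sliding windows of the session's 15 trials (faithful mode) or of
the split's training trials (causal mode).  Trace summaries are median /
25th / 75th-percentile probability trajectories per true class, pooled
over test trials and splits.

## Sensitivity maps

Kruskal–Wallis is applied to per-trial mean features pooled across all
sessions (at full scale, 225 trials per emotion group), per (channel,
band), with tie correction and a χ²(2 df) reference.  Per-session group
sizes (5 per emotion) are too small for meaningful p-values, hence the
pooling.  Degenerate cells (all values tied) report H = 0, p = 1 with a
warning.  No multiple-testing correction is applied; the map is
descriptive, and counting cells with p ≤ 0.05 before/after ELBN is a
relative comparison under identical selection rules.  All 58 channels are
computed; any display subset is a rendering choice.

## Problem sizes

Full corpus dimensions (15 × 3 × 15 trials) are used where the check is
structural arithmetic (counts, shapes, split sizes).  Statistical and
mechanism checks use reduced corpora chosen to keep the suite fast while
leaving wide statistical margins: 5 subjects × 1 session for the
drift/normalization mechanism (150 test decisions per grid cell), 3 × 1
for the chance-level control, 4 × 1 for the acceptance script's
recognition block, with Bagging reduced to 25 estimators and the MLP
capped at 300 lbfgs iterations in those scaled grids (the package
defaults are unchanged).  The chance-level tolerance uses three binomial
standard errors computed from the number of *distinct* test trials, since
the ten splits reuse trials and the 90 test decisions per cell are not
independent.

## Known limitations

- The synthetic corpus cannot calibrate absolute accuracies against real
  recordings; only structural and mechanism-level claims are tested.
- The additive power-offset drift interacts multiplicatively with
  band-power estimation noise, so it is affine in expectation only; exact
  ELBN-invariance statements therefore hold for gain-type drift, and
  offset drift is exercised through the sensitivity-map contrast.
- The online stage assumes the full trial's epochs are available for
  normalization in faithful mode; a streaming deployment would need the
  causal mode plus running extrema.
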