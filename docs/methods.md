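# Methods

## Signals and processing chains

Raw sessions are 60 EEG + 4 EOG channels at 200 Hz in microvolts. The
common stage applies a 2nd-order Butterworth 25 Hz anti-alias low-pass
and second-order IIR notches at 50 and 100 Hz (quality factor 35; the
100 Hz notch only matters before decimation), decimates to 100 Hz by
sample picking (the anti-alias filter has already run, and avoiding a
second filter keeps the causal chain's group delay down), interpolates
visually-marked bad channels by inverse-distance weights of their four
nearest good neighbors, and attenuates eye artifacts by multi-channel
least squares on the four EOG channels plus their first derivatives,
fitted on dedicated eyeblock data (rest, saccades, blinks). This
regression is a deliberately simple stand-in for more elaborate eye
subtraction schemes; it removes the linear, instantaneous part of the
contamination, which is exactly what the synthetic generator produces.
The anterior-frontal row (5 channels) is excluded after eye correction
for the movement pipelines (60 → 55 channels); the error-potential
pipeline keeps all 60 channels, matching its stated feature count of
60 × window samples.

The movement branch adds a 1st-order 0.18 Hz high-pass, common average
reference, optional transient suppression, and a 2nd-order 3 Hz
low-pass before decimating to 10 Hz (intention detection) and 20 Hz
(trajectory decoding). Transient suppression is a robust z-score gate:
per-channel median/MAD reference statistics come from calibration rest
data; samples beyond 5 MADs are blended towards an inverse-distance
interpolation of the four nearest channels, with weight ramping from 0
at the bound to 1 at twice the bound, so clean data passes bit-exactly.
The error branch band-passes the common 100 Hz stream at 1–10 Hz
(overall 4th-order Butterworth). Every chain runs causally (single
forward pass, as online) or zero-phase (forward–backward, for offline
analysis); zero-phase mode doubles the stop-band attenuation in dB.

## Synthetic sessions

The generator's job is to produce data in which each decoder's target
structure is genuinely present, so that a pipeline defect — not noise —
is the likely cause of a failed recovery. Defaults, with units and
rationale:

- **Background noise**: spectral-synthesis pink noise (power ∝ 1/f),
  8 µV per channel broadband, with a shared component mixed at 0.3 for
  spatial correlation. In the 0.15–0.45 Hz tracking band this leaves
  ~1 µV RMS; in the 1–10 Hz error band ~3 µV RMS.
- **Snake targets**: pink noise band-passed 0.2–0.4 Hz (4th-order
  Butterworth, zero-phase) at 20 Hz for 23 s (460 samples),
  standardized to unit variance; x/y candidate pairs are redrawn (up to
  1000 times) until all four position/velocity cross-correlations fall
  below 0.1.
- **Reaching templates**, Gaussian in time and on the scalp
  (positions from the standard 10-10 montage): a motor negativity of
  −6 µV at Cz peaking 0.1 s before the saccade (σ_t = 0.30 s, σ_spatial
  = 0.06 m), present only in *movlook* trials, plus an occipital
  saccade-locked visual response of +4 µV at Oz (σ_t = 0.15 s,
  σ_spatial = 0.05 m) in both conditions. The broad spatial spreads
  reflect volume conduction; the focal visual response keeps the Cz
  minimum at −0.1 s rather than dragging it earlier.
- **Error templates**: Pe +10 µV at CPz, 0.44 s after the error onset
  (σ_t = 0.08 s, σ_spatial = 0.08 m — P300-family components are
  broad), and a late ERN of −8 µV at FCz at 0.77 s (σ_spatial =
  0.06 m). These single-trial peaks correspond to roughly unit SNR
  against the 1–10 Hz band noise at the peak channel; grand averages of
  a few µV are consistent with larger single-trial amplitudes.
- **Kinematic forward model**: EEG(t) = Σ_l g_l · P · y(t − l·0.05 s) +
  noise, with lag gains (1.0, 0.6, 0.3), spatial patterns P centered on
  C3/C4/CP1/CP2/Pz/POz with 20% jitter (fixed pattern seed, so the
  forward model is a property of the "experiment", not of the session),
  and y the six kinematic parameters with the distance/speed rows
  centered (the cortex encodes deviations; an uncentered norm would put
  a DC offset on the scalp). The encoded signal is scaled so its band
  RMS on the encoding channels equals `kin_snr` (default 1) times the
  expected noise band RMS, computed analytically from the synthesis
  spectrum.
- **EOG**: saccades are ±150 µV logistic steps (40 ms rise) on the
  horizontal or vertical pair according to the trial's starting
  position, pursuit is a scaled copy of the snake, blinks are 400 µV
  bumps; everything leaks into the EEG through a fixed frontally
  weighted mixing matrix, which is what the regression stage must
  remove. The saccade detector thresholds the maximum absolute EOG
  derivative at 20 baseline MADs with a 0.5 s refractory period; 20
  sits far above the pink-noise derivative tail (~10 MADs) and far
  below the saccade step (~90 MADs).
- **Timing**: 2 s baseline, saccade 2–4 s later (uniform), 1 s to
  tracking onset, 23 s tracking, 2 s gap. Error onsets are uniform on
  [16, 21] s into tracking in round(30%) of movlook trials; start
  positions are counterbalanced (3 of each per 12-trial run).

What the generator does *not* emulate: non-stationary drifts and
impedance changes, non-linear or time-varying neural encoding,
cross-frequency structure, realistic eye-movement dynamics (main
sequence, microsaccades), or any overlap between the motor template and
the tracking encoder. Passing recovery tests therefore shows that the
pipelines extract the structure they were built for — not that real
EEG supports the same effect sizes (decoding correlations near 0.95 on
synthetic sessions versus ~0.2 on real recordings).

## Decoder details and numerical choices

- **Shrinkage LDA**: pooled within-class covariance shrunk towards
  scaled identity with the analytic Ledoit–Wolf intensity; posteriors
  from the Gaussian equal-covariance model (a logistic of the
  discriminant score). Calibrated posteriors matter because every
  online rule thresholds them at fixed values.
- **Feature windows** are half-open: [−0.5, 0.5) s at 10 Hz gives 10
  samples × 55 channels = 550 intention features; a 0.385 s window at
  100 Hz gives 38 samples × 60 channels = 2280 error features.
- **Time-fraction optimization**: 5 × 5-fold CV over trials (movlook,
  onlylook and rest pools split independently); a test trial is correct
  when the simulated asynchronous rule fires inside [−1.5, 1] s around
  the saccade and never earlier. Detections are timestamped at the
  center of the classifier's 1 s feature window. Ties in the grid go to
  the largest time-fraction (a more conservative gate); the M2
  consecutive counter counts consecutive *consulted* samples, and the
  M1 buffer resets after a confirmed detection.
- **PLS**: 10 components by default (a conventional choice for lagged
  EEG features; logged at fit time), no scaling. The UKF uses Merwe scaled sigma
  points (α = 1e-3, β = 2, κ = 0), dt = 0.05 s; the measurement
  covariance R is the training residual covariance of the PLS
  predictions, the process noise Q follows a white-acceleration model
  with the acceleration variance taken from training velocity
  increments, the initial state is zero with the training kinematic
  variances on the diagonal of P0. Covariance losing positive
  definiteness is repaired by a 1e-9 jitter with a warning; a state
  norm above 1e6 raises. Lag matrices drop their first six time points
  instead of zero-padding.
- **Trial rejection** flags tracking segments with any |sample| >
  100 µV or log-variance/kurtosis more than 4 SD above the across-trial
  mean; batch mode auto-confirms.
- **ErrP window selection** replaces visual inspection: the smoothed
  (50 ms) |error − correct| difference at FCz is thresholded at 50% of
  its maximum within [0.2, 0.9] s; the window runs from the first
  suprathreshold local peak to the last suprathreshold sample (duration
  clipped to [0.2, 0.6] s). A strictly contiguous-span rule cannot
  bridge the dip between the Pe and the late ERN, whereas the
  peak-to-offset rule reproduces both a boxcar difference exactly and
  the two-bump default template's expected window (~0.45 s start,
  ~0.4 s duration).
- **Threshold tuning**: 41 thresholds on [0, 1]; per-fold asynchronous
  TPR/TNR averaged, sorted by threshold and smoothed with a 7-sample
  edge-normalized moving average; τ maximizes smoothed TPR × TNR, ties
  to the smallest τ. A detection is any sample whose last three sliding
  posteriors all exceed τ. TN = correct trial with no detection in its
  whole segment; TP = error trial with no pre-onset detection and at
  least one within 1 s of onset.
- **Chance levels**: label shuffles inside a repeated stratified CV
  (5 × 5 × 20 = 500 iterations by default; 95th percentile), the
  hierarchical bound being the product of the M1 and M2 bounds. The
  trajectory bound breaks the trial–trajectory pairing with
  derangements, refits the full PLS+UKF per shuffle and takes the
  97.5th percentile (100 shuffles by default). The ErrP chance pipeline
  refits the classifier per shuffle and re-tunes τ on a held-out 30% of
  the training portion — tuning on the fit trials themselves lets the
  overfit shuffled classifier pick degenerate thresholds.
- **Closed loop**: the cursor during tracking is α·decoded +
  (1 − α)·snake delayed by 0.14 s (the logged average processing
  latency); α applies to positions. Error trials rotate the snake
  velocity by a randomly signed 90°; a detected ErrP snaps the cursor
  back to the snake, otherwise it disappears 1.5 s after the onset.
  Reaching times out 5 s after the trial start.

## Problem sizes used by the test suite

Unit and property tests run on reduced sessions (2 + 2 calibration
runs). The parameter-recovery acceptance tests use full-size
calibration sessions (72 movlook + 60 onlylook trials) over ten seeds
with reduced shuffle counts — 100 shuffle iterations for the classifier
chance bounds, 10 trajectory re-fits, 4-fold trial CV for the decoding
estimate; `scripts/acceptance.py` runs the full counts (500 / 100,
5-fold) on one seed. Wilcoxon maps use the exact distribution where
SciPy provides it and drop zero differences; Benjamini–Hochberg
adjustment runs across all channel × time cells.

## Known limitations

- The eye-artifact and transient-suppression stages are simplified
  equivalents of the published online algorithms; they share the
  interface and intent, not the exact output.
- Chance TPR/TNR bounds for the error detector are computed per CV
  fold, i.e. over ~4–5 error and ~10 correct test trials; such rates
  are heavily quantized, and their 95th percentile can saturate at 1.0.
  With a near-perfect true detector this makes "strictly above chance"
  unattainable by construction on some seeds; the acceptance suite
  reports this comparison as specified rather than weakening it.
- Source-space analysis is out of scope; activation patterns are
  computed and exported in sensor space only.
- The closed-loop simulator replays pre-generated sessions; the
  decoded cursor does not feed back into the synthetic EEG (no
  user-adaptation model).
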