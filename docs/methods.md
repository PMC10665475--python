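# Methods

`respfusion` detects breathing events in multichannel in-cabin recordings:
a piezoelectric pressure sensor in the seat belt, a 3-axis accelerometer on
the seat belt (respiration + vehicle noise) paired with one on the seat
(vehicle noise only), and two video-derived traces (mean green intensity of
fixed rectangles over the belt and the chest).  A chest belt supplies the
ground-truth breathing peaks and is never used as a model input.

## Signal model and per-sensor conditioning

**Piezo.**  The sensor converts chest pressure against the belt directly
into a voltage; it is used raw.

**Accelerometers.**  Each 3-axis sensor is band-pass filtered per axis
(zero-phase Butterworth, defaults 0.1–0.7 Hz ≈ 6–42 breaths/min, order 4)
and reduced to a scalar by projection onto the first principal component of
the mean-centered axis cloud.  The sign of the principal axis is fixed
deterministically (positive loading on the axis of largest variance); a
Euclidean-magnitude combination is available as an alternative
(`combine="norm"`).

The belt sensor is then denoised against the seat sensor by per-bin
spectral suppression.  With `X1(k)`, `X2(k)` the transforms of the two
combined signals:

    SF(k)     = exp(−|X2(k)| / μ(|X1|)),   μ(|X1|) = mean over bins of |X1|
    X_supp(k) = SF(k) · X1(k)

and the denoised signal is the inverse transform.  Because `SF` is built
from magnitudes, it is conjugate-symmetric for real input, so the inverse
transform is real up to round-off (asserted < 1e−9 of signal scale).

*Numerical conditioning.*  The exponential gain is scale-sensitive:
whatever raises `|X2|` at the breathing bins relative to `μ(|X1|)` drives
`SF → 0` exactly where the signal lives.  Applying one transform to a long
band-limited record does precisely that — `μ(|X1|)` collapses because most
bins are empty, and rectangular-window leakage from strong narrowband or
out-of-band components floods the breathing bins.  The pipeline therefore
applies the suppression per segment (Blackman window, 50 % overlap-add,
reflect-padded ends, default 30 s; `suppress_window_s` in the config).
Setting `suppress_window_s=None` restores the single-transform variant,
which is also the form checked against a brute-force O(N²) DFT oracle in
the tests.  A per-bin canceller of this type cannot remove noise that
shares a bin with the breathing fundamental; it removes spectrally
structured interference (e.g. low-frequency body sway) and attenuates the
rest smoothly.

**Video.**  A frame's respiration sample is the arithmetic mean of the
green channel over a fixed ROI, `color_avg = (1/(w·h)) Σ Pixel`, one sample
per frame at the camera's 10 fps.  Default ROIs (0-based pixel coordinates)
are belt `(x 701, y 550, w 10, h 190)` and chest `(x 401, y 550, w 400,
h 190)` for the 1280×720 cabin geometry, fully configurable.  `verify_roi`
checks the nominal position on the first frame by maximizing local contrast
(intensity variance) over integer shifts within a search radius, falling
back to the nominal ROI with a warning when no contrast structure exists.

## Unified pre-processing, windowing, labels

All channels are polyphase-resampled to 200 Hz, median filtered (default
kernel 5 samples; scipy's reflected edges), and amplitude-normalized to
[−1, 1] per recording (a constant trace maps to zeros).  Snippets are
201-sample windows over the four model channels in the fixed order
(piezo, acc, video_belt, video_chest); training windows overlap by 190
samples (step 11), test windows by 200 (step 1).

Breathing peaks are detected on the chest-belt reference after zero-phase
1 Hz low-pass smoothing: local maxima at least 1.5 s apart (≤ 40
breaths/min) with prominence ≥ 0.1 × the interquartile range of the raw
trace, each refined to the raw local maximum within ±0.25 s.  A snippet is
labeled 1 when a peak lies within ±`label_tolerance` samples (default 50,
i.e. 0.25 s) of the window center.  With breathing periods of 3–5 s this
yields roughly 10–17 % positive windows; training uses inverse-frequency
class weighting by default so the sigmoid head cannot collapse to the
majority class.

## Fusion models

Every convolutional branch is `conv1d(4 filters × 20 samples, valid) →
ReLU → dropout(0.5) → max-pool(4) → flatten`; the concatenated branch
features feed one sigmoid unit thresholded at 0.5.

* early fusion — one branch convolving all selected channels jointly;
* signal-based late fusion — one branch per signal;
* sensor-based late fusion — two independently initialized branches per
  signal (a larger extracted feature set);
* hybrid — elementwise 2-of-3 majority vote over the predictions of the
  other three (no parameters of its own; members share data and follow a
  fixed seed-offset schedule so the ensemble is reproducible).

Training is mini-batch Adam (default lr 1e−3, batch 64, binary
cross-entropy).  The engine is a small numpy implementation with all
randomness (init, shuffling, dropout masks) drawn from one seeded
generator, so CPU runs are bit-reproducible.  The ReLU after the
convolution and the pooling type/size are this package's choices; the
activation between conv and dense is not otherwise constrained by the
architecture being reproduced.

## Evaluation

For predictions against reference labels, `P = 100·(PPV + S)/2` with
`PPV = TP/(TP+FP)` and `S = TP/(TP+FN)`.  A zero denominator sets the
affected term to 0 (logged) — the conservative choice.  The experiment grid
is leave-one-subject-out: for each scenario, train on the other subjects'
recordings of that scenario at training overlap, test on the held-out
subject at test overlap; per-fold `P` values are averaged within scenario,
and the overall `Mean_P` is the mean of the scenario means (an average of
fold-level P, not of pooled confusion counts; a pooled variant is a flag).
Report rounding is 2 decimals, half away from zero.  The "usable driving
time" figure restates the best strategy's `Mean_P` as a percentage of
driving time; the report labels this equation as an interpretation rather
than a separately measured duty cycle.

## Synthetic study

The simulator generates the study conditions at desk scale.  Respiration is
`sin(φ) − h·cos(2φ)` with a slowly wandering instantaneous rate (subject
base rates 12–20 breaths/min, wander 3–8 %, second harmonic h ≤ 0.24); for
h < 1/4 the waveform's maxima sit exactly at φ = π/2 (mod 2π), so the
ground-truth peak train is derived from the phase, not from numerical peak
picking.

The shared vehicle-noise process seen by both accelerometers is: broadband
road/engine vibration (0.8–20 Hz), body-sway/load-shift noise in
0.45–0.7 Hz with steep (order-8) band edges — inside the respiration band
but above the simulated breathing fundamentals, since co-located content is
unrecoverable for a per-bin canceller — Poisson road transients modeled as
Gaussian-envelope suspension bursts (3–8 Hz carriers, τ 0.25–0.5 s), and a
slow drift (< 0.05 Hz).  Scenario profiles order the gains by road
roughness: highway < city < countryside, with city adding the most
stop-and-go transients.  Channels are produced at native rates (100 Hz hub
sensors, 10 fps video traces) to exercise the resampling path, and video
traces carry per-subject lags plus illumination drift.  `simulate_frames`
renders a chessboard belt band whose visible extent inside the ROI follows
the belt trace, so the full frames→ROI→trace path can be tested end to end.

What the simulator does *not* emulate: real road-noise spectra beyond the
three-component model, posture changes and talking artifacts, illumination
changes beyond a slow sinusoid, subject-specific waveform morphology beyond
one harmonic, or any coupling between breathing and vehicle motion.
Passing tests therefore demonstrate that the pipeline recovers events under
the stated noise model, not performance on the deposited driving data.

## Scales and budgets

The end-to-end checks run a 6-subject × 3-scenario × 3-minute study with
signal-based late fusion at 5 epochs — the problem size the package uses
for its own verification runs — and require mean LOSO P ≥ 70, against a
balanced-label chance level of about 50.  Denoising efficacy is measured as
the mean gain, over 10 seeded subjects, of |corr(denoised, clean)| −
|corr(raw PC1, clean)| with a > 0.05 bar; in practice the gain is far
larger (≈ 0.6–0.7) because the raw first principal component is dominated
by vehicle noise.

## Known limitations

* The exponential suppression factor has no dimensionless normalization;
  its behavior depends on the spectral occupancy of the inputs.  The
  windowed default keeps it in its well-conditioned regime but cannot
  recover breathing content that shares bins with interference.
* The 0.5 decision threshold transfers imperfectly across subjects in
  leave-one-subject-out evaluation; with few training subjects the
  sensitivity of individual folds varies widely.
* `P` ignores true negatives entirely; an all-positive predictor scores
  `P ≈ 50 + prevalence/2`, which is why the chance level quoted above is
  ~50 rather than prevalence-dependent.
* Respiratory rate in breaths/min is deliberately not derived from
  predicted labels; the pipeline's output is snippet-level event
  classification (a rate utility would need peak grouping on top of it).
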