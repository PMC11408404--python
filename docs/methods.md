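# Methods

## The detection problem

Sleep spindles are sigma-band (11–16 Hz) EEG oscillations with a fusiform
(waxing–waning) envelope lasting roughly 0.5–3 s, the hallmark of NREM
stage-2 sleep. `spindilometer` frames their detection as binary
classification of 10-s frames: each 30-s polysomnography scoring epoch is
divided into three 10-s frames, and a frame is labeled spindle-positive
when a spindle overlaps it. A per-frame feature vector feeds a
filter-selected classifier; evaluation is frame-level (confusion matrix,
ROC–AUC) plus per-record count agreement (intraclass correlation).

## Synthetic recordings

Expert-scored overnight EEG is rarely shareable, so the package ships a
simulator whose output has the statistical structure the detector relies
on, and nothing more:

- **Background** — 1/f^α Gaussian noise (α = 1 by default, RMS 10 µV),
  produced by Fourier-domain shaping of white noise. This reproduces the
  broadband spectral slope of NREM EEG; it contains no K-complexes, slow
  oscillations, artifacts, or stage structure.
- **Spindles** — a cosine carrier under a symmetric Hann envelope, peak
  amplitude `amp_sigma_ratio` × background RMS (default 2.0). Durations are
  uniform on [0.5, 3] s. Frontal channels (F3-M2, F4-M1) draw carrier
  frequencies from the slow band (12–13 Hz); centroparietal and occipital
  channels from the fast band (14–15 Hz), mirroring the topography of slow
  and fast spindles.
- **Placement** — a homogeneous Poisson process at `spindle_rate_per_min`
  (default 3/min/channel); candidates overlapping an already placed event
  on the same channel are dropped, thinning the realized rate slightly. A
  rate so high that under 10 % of candidates survive raises a saturation
  error. Channels are independent; real spindles co-occur across channels,
  so the simulator's channel-union frame counts run higher than clinical
  per-night counts at the same per-channel rate.

Everything is deterministic given the seed: per-channel noise and event
streams derive from a single `SimConfig.seed` through spawned substreams.
The default sampling rate is 128 Hz (configurable); all operations take
`fs` explicitly.

Because the background is Gaussian and stationary, passing benchmarks here
demonstrates the pipeline's mechanics and its sensitivity to sigma-band
bursts — not robustness to artifacts, arousals, or inter-subject
variability in real recordings.

## Frame labeling

Frames are half-open intervals [k·10 s, (k+1)·10 s). A frame is positive
when an event on that channel overlaps it by at least `min_overlap_s`
(default 0.25 s). The threshold keeps a spindle that barely grazes a frame
boundary from labeling two frames; 0.25 s is below the minimum spindle
duration, so every spindle labels at least one frame.

## Preprocessing

Missing samples are imputed with the channel mean; amplitudes are then
min–max normalized to [0, 1] per channel per recording (not per frame, so
frame-to-frame amplitude contrast survives; a constant channel maps to
zeros by the 0/0 → 0 convention). Trailing partial epochs are dropped.
The 70/30 train/test split is stratified at segment level by default,
mirroring a frame-level evaluation protocol; `group_by_recording`-style
splitting to prevent recording leakage is intentionally not the default,
as the benchmark evaluates frames, not subjects.

## Features (12 per frame)

All features are computed on the mean-removed frame, so each is invariant
to constant offsets.

- **PSD family (7)** — Welch estimate (2-s Hann windows, 50 % overlap);
  absolute band powers for delta (0.5–4), theta (4–8), alpha (8–11), sigma
  (11–16) and beta (16–30 Hz) by rectangular integration over half-open
  bands; relative sigma power against 0.5–30 Hz; spectral peak frequency
  within 9–18 Hz. The raw periodogram and the autocorrelation route (DFT of
  the biased autocorrelation sequence) are retained because they are
  bin-for-bin identical by the Wiener–Khinchin theorem — an exactness check
  the test suite enforces at 1e-8 relative; Welch trades that exactness for
  variance reduction on 10-s frames.
- **CWT family (3)** — complex Morlet (ω₀ = 6) scalogram over 32 log-spaced
  scales spanning 2–30 Hz equivalents; mean and max |coefficient| over
  sigma-equivalent scales, and sigma-scale energy as a fraction of total
  scalogram energy.
- **NGS (1)** — the normal-probability-plot score
  1 − Σ(q_j − p_j)² / Σ(q_j − q̄)², with q the sorted standardized sample
  and p the normal quantiles at Blom plotting positions
  ((j − 0.375)/(N + 0.25)). The score is 1 for Gaussian-ordered data and
  falls as the amplitude distribution departs from Gaussian — a spindle
  burst riding on Gaussian background lowers it. (Despite the
  "non-Gaussianity" naming convention, larger values mean *more* Gaussian;
  the classifier is indifferent to the sign convention.)
- **BGS (1)** — the bispectrum diagonal-slice band ratio. The direct
  estimator splits the frame into 8 Hann-windowed blocks (160 samples at
  128 Hz), averages B(ω,ω) = X(ω)² X̄(2ω) across blocks, and integrates
  P(ω) = |B(ω,ω)| over sigma (11–16 Hz) against 0.5–30 Hz. The diagonal is
  limited to fs/4 so that 2ω stays on the DFT grid. As a third-order
  statistic it retains Fourier phase and responds to quadratic phase
  coupling, which the amplitude-modulated spindle waveform induces between
  carrier and envelope sidebands. Note the diagonal only sees (ω, ω, 2ω)
  coupling; coupling between two distinct frequencies lives off-diagonal
  and is out of scope.

Feature extraction operates on the normalized [0, 1] signal by default
(`--no-normalize` computes on raw µV); relative and distributional features
are scale-free either way.

## Feature selection and classifiers

Selection is a univariate filter: one-way ANOVA F per feature (constant
features score 0), keeping the top k = 10 of 12 by default, ties broken
toward the lower index; mutual information is available as an alternative.
The classifier bank is KNN (k = 5, Euclidean), SVM (RBF, C = 1,
γ = "scale"), a Gini decision tree, Gaussian naive Bayes, and 100
extremely randomized trees. None of these hyperparameters is tuned; they
are the conventional defaults, exposed in config, chosen for
reproducibility over guesswork. Features are z-scored with statistics from
the training rows only; the stored mean/std are reapplied at prediction, so
no test information leaks into scaling. Scores are mapped to [0, 1]
(positive-neighbor fraction for KNN, logistic of the decision value for
SVM, class probability for the rest) and thresholded at 0.5. One pooled
model is trained across all six channels.

## Evaluation

Confusion counts partition the evaluated frames; derived metrics use the
standard formulas with a 0/0 → 0 convention, flagged in the report's
`undefined` list. ROC is swept over all score thresholds with trapezoidal
AUC. Per-record spindle count is the number of frames positive on at least
one channel (frame-union rule — the frame is the counting unit); density is
count per hour. Count agreement uses the two-way mixed, consistency ICC:
single measures (MSR − MSE)/(MSR + (k−1)·MSE) and average measures
(MSR − MSE)/MSR; the form is configurable in principle but consistency is
the default because count comparisons between a fixed pair of scorers are a
two-way mixed design. Degenerate count tables (zero total variance, as in
very short runs where every record saturates) make the ICC undefined; the
pipeline reports null rather than a number.

## Benchmark problem sizes

The default benchmark simulates 12 recordings of 20 minutes, six channels
at 128 Hz — 8 640 frames, of which 30 % are held out — and completes in
about a minute on one core. Twenty-minute records keep per-record counts
(~115 of 120 frames) high enough to expose count disagreement while
remaining quick to simulate; the determinism check uses 3 records of 2
minutes, since bit-identity does not depend on problem size.

## Known limitations

- The simulator omits artifacts, K-complexes, arousals and sleep-stage
  architecture; benchmark numbers are upper bounds on real-data behavior.
- Independent per-channel spindle placement inflates channel-union counts
  relative to clinical scoring, where one thalamocortical event appears on
  several channels at once.
- The EDF codec writes 16-bit continuous EDF with 1-s records and integer
  sampling rates only; EDF+ annotation streams are skipped on read (events
  travel as CSV).
- Segment-level splitting lets frames of one simulated recording appear in
  both train and test; for subject-level claims, split by recording.
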