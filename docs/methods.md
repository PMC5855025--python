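# Methods

## Signal model and decomposition

Skin conductance (µS) is modelled as sudomotor driver activity (µS/s)
convolved with a biexponential Bateman impulse response
`IRF(t) ∝ exp(−t/τ₂) − exp(−t/τ₁)`, `0 < τ₁ < τ₂`, superposed on a
slowly drifting tonic level.  The discrete kernel is normalized to unit
time-area (`Σ k[n] / fs = 1`) so the decomposition has unit DC gain: a
constant conductance maps to a constant driver of the same value, and a
driver impulse of area *a* µS·s produces an SCR of area *a*.  The kernel
is truncated at 8·τ₂ (well past five decay constants) and `k[0] = 0`.

Deconvolution is Tikhonov-regularized FFT division,
`D = conj(H)·S / (|H|² + reg·max|H|²)`, with `reg = 1e-4` relative to
the kernel's peak spectral power.  Deconvolution amplifies measurement
noise at frequencies where `|H|` is small; `reg` bounds the
amplification (effective driver bandwidth ≈ 0.8 Hz at the defaults) and
the recovered driver is additionally Gaussian-smoothed with σ = 0.2 s.
Edges are reflect-padded by one kernel length before the FFT so the
driver does not ring at the recording boundaries; a zero-padding mode is
the exact algebraic inverse of the forward convolution and is what
round-trip checks use (`reg → 0` recovers a sparse driver to ~1e-12).

### Tonic-driver estimation

The tonic driver is interpolated through impulse-free intervals:

1. smooth the total driver (σ = 0.2 s — the light smoothing matters:
   in the driver domain impulses are narrow, so inter-impulse samples
   return to the tonic level; heavier smoothing fills the valleys and
   absorbs phasic mass into the tonic estimate in dense recordings);
2. mark *quiet* samples lying within 0.05 µS/s of a rolling-median
   baseline (20 s window).  The baseline is a median, not a low
   percentile: deconvolution-amplified noise exceeds the threshold, and
   a low-percentile baseline would keep only the lower noise tail,
   biasing the tonic estimate down by a sizable fraction of the noise
   amplitude;
3. per 10 s interval, place one support point at the centroid of its
   quiet samples, valued at their *median* — robust both to residual
   SCR tails above and to deconvolution undershoot below the tonic;
4. interpolate supports with a natural cubic spline, held flat beyond
   the outermost supports.  If no quiet sample exists anywhere the
   estimate falls back to a constant global 10th percentile with a
   warning.

The phasic driver is the remainder; negative excursions are kept so
reconstruction error stays diagnosable.  On noiseless synthetic
recordings the phasic driver correlates ≈ 0.95 with the smoothed true
impulse train and the tonic component is recovered to ≈ 1% relative RMS
(both recomputed by `scripts/acceptance.py`).

## Preprocessing

10th-order Butterworth low-pass below 20 Hz, applied zero-phase
(forward–backward, second-order sections) so SCR onset latencies used by
the peak features are not delayed; then polyphase resampling to the
50 Hz working rate (rational-ratio approximation, line-extension padding
so constants stay constant).  The working band is therefore 0–25 Hz.

## Synthetic-data generator

The generator emulates 10 subjects × 3 driving conditions × 120 s of
wrist GSR at 200 Hz.  Per condition, primary SCR impulses arrive as a
Poisson process — normal 0.05/s, phone 0.25/s, text 0.35/s — and each
primary impulse spawns, with probability 0.1 / 0.4 / 0.5 respectively,
a burst of 1–3 extra impulses at Uniform(0.5, 1.5) s spacing, creating
the overlapping-SCR regime deconvolution exists to untangle.  Impulse
areas are Gamma(shape 2, scale 0.3) µS·s, giving SCR peak amplitudes of
roughly 0.03–0.3 µS.  The tonic level is a per-subject base
Uniform(2, 8) µS plus a drift built from six sinusoids with frequencies
in [0.002, 0.02] Hz and total RMS 0.15 µS — band-limited far below
0.05 Hz by construction, with maximum derivative < 0.1 µS/s.  White
measurement noise has σ = 0.01 µS; optional band-limited (>20 Hz)
EMG-like artifact bursts exercise the preprocessing filter and are off
by default.  Per-subject variability scales all condition impulse rates
by a common Uniform(0.8, 1.2) factor, preserving the within-subject
condition ordering.  Everything is a pure function of the configuration
seed.

What the generator does **not** emulate: motion-artifact physics,
electrode-contact drift, respiration or cardiac coupling, and — most
importantly — any condition effect beyond impulse density and
burstiness.  Amplitude distributions, IRF shape and tonic statistics are
identical across conditions.  Passing tests therefore demonstrate that
the pipeline recovers and exploits rate/burst structure; they do not
certify performance on real roadside recordings, where condition effects
are richer but confounds are too.

## Features

Windows are 5 s with 4 s overlap (1 s hop); a 120 s recording yields 116
windows.  The accumulated-GSR feature divides the window sum by the
*full task duration* (120 s), which is what distinguishes it from the
mean.  The peak scan weights slope and curvature magnitudes (1.3/1.1)
and counts each maximal run of the scan statistic at/above threshold as
one peak; the run marks an SCR's steep rise, so the peak amplitude is
taken through the crest that follows the run.  The scan threshold is
scale-dependent; the printed default is 1.0, and the pipeline
configuration uses 0.001 on the synthetic µS scale — above the
deconvolution noise floor (~4e-4) and below the scan response of the
smallest generated SCRs (~2e-3).  STFT features average magnitude-
squared spectra of 1 s / 0.5 s-overlap sub-windows over time and then
over four equal bands spanning [0, fs/2] (6.25 Hz bands at 50 Hz; four
equal bands over the working bandwidth keep the definition physically
realizable at any rate).  Higuchi uses kmax = 8; Katz returns exactly 1
for monotone lines and 1 by convention for flat windows.  AR
coefficients come from the Burg method (statsmodels) on the demeaned
window — better short-window bias behaviour than Yule–Walker — in the
convention where an AR(1) process with parameter 0.5 yields a(1) ≈ +0.5.

The smoothed pseudo Wigner–Ville distribution is a diagnostic only: the
analytic signal's instantaneous autocorrelation is Hamming-windowed in
lag (2 s) against frequency cross-terms, Fourier-transformed over lag,
and smoothed along time (0.2 s); the map is normalized to sum to the
analytic-signal energy, and a pure tone appears at normalized frequency
2·f₀/fs.

## Feature selection and consensus

SVM-RFE standardizes features once per run (the squared-weight criterion
presumes comparable scales), trains a linear SVM with C = 1, removes the
single feature with minimal ω², and repeats; constant features have zero
weight and are eliminated first among ties (ties break toward the lower
index).  The cross-subject consensus takes the modal feature at each
rank position (ties toward the smaller feature id) and scans the
consensus row left-to-right for the first k distinct features.  This
rule — rather than plain frequency counting — uniquely reproduces both
published "frequent feature" rows and their shared seven-feature subset,
with the printed tie at position 9 resolved toward the smaller id.
The pipeline computes rankings for both binary scenarios and pools the
twenty per-subject lists into a single consensus call to produce one
unified subset, mirroring the published observation that both scenarios
share a subset.

The consensus rule presumes strong cross-subject concordance of rank
*order*, which the reference tables indeed show.  The planted-feature
validation therefore builds cohorts whose subjects are perturbed copies
of a common population sample (mixing weight 0.05) with graded effect
sizes (2.0 down to 1.0 SD) on the seven informative features; with fully
independent subject draws the per-position mode of uncorrelated orders
is noise even when every subject ranks the right set on top, and no
consensus of this form could recover it.

## Classification protocol

Per subject, stratified 10-fold cross-validation with shuffled fold
assignment (a contiguous-block mode is provided for pessimistic
estimates, since 4 s-overlapping windows shared across folds make
shuffled CV optimistic).  Standardization is fitted on training folds
only; the fitted scaler statistics and fold indices are exposed so tests
can verify no validation data leaks into scaling or training.  Kernels:
linear, polynomial d = 2 (coef0 = 1), RBF; C = 1 everywhere and
γ = 1/(n_features·variance); all exposed in the configuration.
Precision/recall are macro-averaged in the 3-class task (a binary mode
with the distracted class as positive is available), and the F-score is
the harmonic mean of the reported precision and recall.

## Known limitations

- Under the default condition profiles, a 5 s window contains on average
  ≈ 0.3 / 2.3 / 3.5 impulses (normal / phone / text).  Phone and text
  windows therefore overlap heavily in count and amplitude statistics,
  which caps attainable window-level 3-class accuracy well below the
  near-ceiling figures reported for real on-road data, where condition
  effects are not confined to impulse density.  The measured accuracies
  on the synthetic cohort are recomputed by `scripts/acceptance.py`.
- The tonic estimator assumes quiet intervals exist within every ~10 s
  span at the analysis timescale; sustained tens-of-seconds saturated
  phasic activity would inflate the tonic estimate.
- The deconvolution treats the IRF time constants as known and shared
  across subjects (τ₁ = 1 s, τ₂ = 3.75 s, the canonical values);
  per-subject refinement by reconstruction-error minimization is
  deliberately not performed by default, keeping runs deterministic.
- Eq-style peak counting merges SCRs closer than the scan's recovery
  time and counts a long burst as few peaks; counts remain monotone in
  the true impulse rate, which is what the classifier uses.
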