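# Methods

This note documents the models, numerical choices, and limitations of
the package. The README states the index definition; here we record how
each stage is computed and why.

## Signal model and preprocessing

A recording is a set of simultaneously sampled channels at a common
rate (the emulated study setup: 500 Hz, 60 scalp electrodes in 10-10
positions, 2–3 minutes of eyes-open rest). The fixed per-recording
pipeline is deliberately minimal, matching how the index is meant to be
deployed without manual cleaning:

1. **Energy normalization.** Each channel is divided by the square root
   of its total energy (sum of squared samples), making amplitude
   scaling uniform across electrodes and subjects. The index is built
   from spectral *shape*, so absolute amplitude is a nuisance variable.
2. **Line-noise removal.** Real-FFT bins within ±0.5 Hz of 60, 180 and
   200 Hz are zeroed and the signal inverse-transformed. Operating on
   the one-sided spectrum keeps the output exactly real and
   length-preserving. Normalization precedes the notch; the order is a
   fixed, documented convention (the energy removed by the notch is
   tiny, so the choice is immaterial in practice).
3. **Per-configuration bandpass** (scoring time, not preprocessing): a
   6th-order Butterworth filter applied forward and backward
   (`sosfiltfilt`), giving zero net phase shift and the squared
   magnitude response. Reflective edge padding of length
   3 × (order + 1) suppresses startup transients; signals must exceed
   the pad length. The band edges are tunable training parameters
   within 2–34 Hz.

No re-referencing, artifact rejection, epoching, or resampling is
performed.

## LPC encoding

Coefficients follow the convention `x(n) = ε(n) − Σ a_i x(n−i)`, i.e.
the whitening polynomial is `A(z) = 1 + Σ a_i z^{−i}`, and the stored
vector is used verbatim by all downstream geometry. Estimation is the
autocorrelation method solved by Levinson-Durbin on biased sample
autocorrelations (computed by FFT): the canonical LPC estimator, which
guarantees a stable all-pole model and yields every lower order as a
byproduct of one O(K²) recursion — the training grid search exploits
this to evaluate all orders from a single pass per filtered signal. The
residual variance is the final prediction-error power. One model is
fitted per channel over the whole continuous recording; there is no
windowing or segment averaging. Fits require N ≥ 10 K samples and a
non-degenerate (non-constant) signal.

The model spectrum is `σ² / |A(e^{j2πf/fs})|²`. Oscillatory modes are
the roots of `A(z)`: each conjugate pair is reported once at frequency
`angle · fs / 2π`, with the pole radius as a sharpness measure and, as
the mode's "amplitude", the model spectral density evaluated at the
pole frequency. That amplitude definition is one consistent reading
(monotone in both residue size and pole sharpness), not a canonical
standard; mode lists are sorted by it. Note the spectral *maximum* of a
resonance sits slightly below the pole angle unless the pole is sharp
(radius ≳ 0.98) — relevant when interpreting broad, noisy peaks.

## Subspace geometry

Group subspaces are fitted by SVD of the centered coefficient matrix
scaled by `1/√(S−1)`; the scaling affects singular values only, never
the basis or distances, and is applied for fidelity to the definition.
Singular values below 1e−12 of the largest are treated as numerical
zeros; a requested dimension above the numeric rank is truncated with a
warning. Distances are plain Euclidean residuals after orthogonal
projection; since the basis is orthonormal, the normalization factors
`p_cᵀp_c` in the projection are 1 and are not recomputed.

Index orientation: `ρ = D_imp / (D_imp + D_norm)`, so high values are
normal-like and the fixed classification rule is "ρ < 0.5 predicts
impairment" (exactly 0.5 predicts normal). The degenerate case of a
point lying in both subspaces returns 0.5 with a warning. Unequal group
sizes are supported; each subspace is fitted from its own group, with
dimension capped at group size − 1.

## Training protocol

* **Groups.** MoCA: impaired = score < 26, normal = score ≥ 26 (fixed
  clinical cutoff). NIH-Toolbox scores: cohort median as the cutoff,
  with the median subject assigned to the high group. Subjects missing
  the score are excluded.
* **Cross-validation.** A single round of subject-level k-fold CV
  (default 10) with folds stratified by group, shuffled by a Philox
  counter-based generator under an explicit seed. The partition is
  drawn once and shared by every grid configuration. The round-robin
  deal continues across groups, so `k = n` reduces exactly to
  leave-one-out.
* **Search grid.** Integer-Hz band endpoints in 2–34 Hz with ≥ 2 Hz
  width (496 bands), orders 2–10, dimensions 1..K−1 capped by fold
  group sizes and numeric rank. The cost is the Spearman rho between
  out-of-fold single-electrode indices and the continuous score. Ties
  break deterministically toward the narrower band, then smaller K,
  smaller n, lower band edge — making the result independent of grid
  enumeration order.
* **Electrode selection** ranks electrodes by their best CV rho (stable
  sort, so ties keep channel-list order) and keeps the top k
  (default 8). The final model refits subspace pairs on *all* training
  subjects with the selected configurations and serializes to a single
  JSON document (configs, bases, preprocessing provenance, seed);
  reloading reproduces indices bit for bit.

## Evaluation

All schemes hold configurations fixed and refit only the subspace
pairs per training split; for the median cutoff rule the cutoff is
recomputed on each training split to avoid leaking the held-out score.
Metrics:

* **Correlation** — partial Spearman rho between out-of-fold combined
  indices and the score, adjusted for age when available: all variables
  are rank-transformed (average ranks on ties), x and y ranks are
  residualized on the covariate ranks with an intercept, and the
  Pearson correlation of residuals is reported with a two-sided t
  approximation at df = n − 2 − #covariates. Age adjustment applies to
  correlations only, never to classification.
* **Classification** — impaired is the positive class; AUC is the
  Mann-Whitney rank statistic with impaired as the low-index class
  (identical to ROC trapezoid integration); rates are percentages; a
  zero confusion cell triggers the Haldane-Anscombe 0.5 correction for
  the odds ratio, flagged in the output.
* **Regression** — OLS of score on index, linear and quadratic. AIC
  uses the Gaussian profile form `n ln(RSS/n) + 2(p+1)`; the quadratic
  vs linear likelihood-ratio statistic is `n ln(RSS_lin/RSS_quad)`
  against χ²(1). RMSE is reported on the raw score scale and, because
  the scaling convention behind published index-RMSE magnitudes is not
  unique, also with both variables min-max scaled to [0, 1]
  (`rmse_scaled`).
* **Randomization test** — scores are permuted once per run (seeded
  Philox bijection of the score multiset) and the full LOOCV pipeline
  reruns with groups re-split from the shuffled scores. An
  `identity=True` hook forces the identity permutation, which must
  reproduce the plain LOOCV report.
* **Robustness** — the electrode sweep re-evaluates LOOCV while
  combining the top-c ranked electrodes; the truncation sweep keeps the
  leading `ceil(fraction · N)` samples of each raw recording (the end
  is discarded), re-runs the fixed preprocessing, and repeats LOOCV per
  retained fraction (10–100% in 5% steps by default).

## Spectral comparators

Band power is the integral of a power spectral density over
`[f_lo, f_hi)` with half-open bins so adjacent bands never double-count
an edge. The default PSD is the full-length boxcar periodogram rather
than a Welch average: integrating over a band already averages many
independent bins, and the unsegmented estimate partitions total signal
power exactly (Parseval), whereas segment averaging loses the tail
samples and tapers the ends, misallocating up to ~2% on signals of a
few thousand samples. Welch averaging (2-s Hann segments, 50% overlap)
remains available via `seg_seconds` for callers who want smoothed
spectra. The alpha/theta ratio uses log base 10 (configurable).
Topographies report per-electrode age-adjusted partial Spearman
correlations flagged at p < 0.05 without multiple-testing correction
(deliberately, as a raw comparator map).

## Synthetic cohorts

The generator emulates exactly the structure the index assumes. Each
subject draws an integer latent score uniformly on 9–30 (stored as
MoCA; the emulated patient score range) and an age from N(68, 8²)
truncated to [40, 95]. On informative electrodes the signal is a sum
of:

* a theta-alpha AR(2) resonance at
  `7 + (6/21)(score − 9)` Hz (pole radius 0.97, unit RMS) — the
  frequency spans 7–13 Hz across the score range;
* a beta AR(2) resonance at 19 Hz (pole radius 0.95) with RMS
  `0.4 + 0.04 (score − 9)` — amplitude roughly triples across the
  range;
* 1/f pink noise (spectrally shaped white noise, exponent 1.0,
  unit RMS), a 60 Hz mains sinusoid (RMS 0.5, random phase), and white
  noise (sd 0.5).

Uninformative electrodes carry only background, mains and white noise.
The component levels were chosen once as a plausible resting-EEG mix in
which oscillations and the 1/f background are comparable; the
score-to-frequency and score-to-amplitude links are linear in the
generative direction, with slopes set so the theta-alpha peak spans the
theta-alpha range end to end. Defaults (149 subjects, 60 channels,
160 s at 500 Hz) mirror the emulated study conditions; tests and the
acceptance script run reduced sizes (typically 120 subjects, 4–6
channels, 10–20 s) chosen so the multi-seed sweeps stay desk-scale —
the effect structure, not the problem size, is what those checks probe.
All randomness flows from a Philox counter-based generator keyed by the
cohort seed, so cohorts are bit-reproducible across platforms.

What the generator does **not** emulate: artifacts (blinks, movement,
electrode pops), nonstationarity, inter-channel correlation from volume
conduction, realistic score distributions, or any nonlinear
score-physiology coupling. Passing recovery tests on these cohorts
shows the pipeline correctly extracts score-linked spectral structure
under its own assumptions; it does not certify performance on clinical
EEG, where the published protocol's numbers require the original
cohort.

## Numerical conventions and degenerate inputs

* Seeds: every stochastic step (fold shuffling, permutations, cohort
  generation) takes an explicit integer seed; derived seeds stay below
  2³¹. Repeated k-fold derives round r's fold seed as
  `(seed + 7919 r) mod 2³¹`.
* Ties: average ranks in all rank transforms; grid and electrode
  ranking tie-breaks as above.
* Degenerate inputs rejected with diagnostics: all-zero channels,
  constant signals, bands at/above Nyquist, too-short signals for the
  filter pad or for N ≥ 10 K, single-class label vectors (AUC
  undefined), constant regression predictors, empty groups after a
  split, truncations below 10 K samples.
* `n_max` capping: inside CV, subspace dimensions are silently capped
  by training group size − 1 and numeric rank (the standalone fitting
  API warns instead), so a configuration remains comparable across
  folds with slightly different group sizes.

## Known limitations

* The exhaustive default grid (496 bands × 9 orders × dims) is
  expensive on long recordings; the coarse factory grids
  (`GridSpec.small()`, or `GridSpec.default(step=...)`) trade
  resolution for speed.
* Only the autocorrelation/Levinson-Durbin LPC estimator is provided
  (no Burg or covariance methods), and only two-class subspace pairs.
* Parameter search and evaluation may share a cohort, as in the
  emulated protocol (selection CV is a single round; evaluation CV
  refits subspaces only). The out-of-sample path — scoring a held-out
  cohort with a frozen model — is available via `LEAPDModel.load` /
  `score_recording` and the CLI `score` command.
* EDF/BrainVision ingestion goes through MNE; unusual vendor variants
  untested beyond ASCII/int16 fixtures.
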