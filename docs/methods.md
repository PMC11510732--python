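# Methods

## Signal model and pipeline

A resting-state EEG recording is a channels × samples matrix at sampling
rate `fs` (the reference geometry is 19 channels of the 10-20 system at
250 Hz).  The pipeline assumes the observed channels are (i) linear mixtures
of statistically independent cortical and artefactual sources, (ii) locally
stationary over 20-second windows, and (iii) informative about class through
the *shape* of their spectral envelope rather than absolute amplitude —
which is why every epoch is z-scored per channel before analysis and the
features are built on the cepstrum, where overall gain moves only
quefrency 0.

Stages, in order: FastICA cleanup → segmentation into non-overlapping 20 s
epochs → per-channel, per-epoch z-scoring (population SD) → log-energy
empirical wavelet reconstruction → real-cepstrum Hjorth descriptors →
one-way ANOVA F ranking → KNN under repeated stratified 10-fold CV.

## FastICA artefact removal

Symmetric fixed-point FastICA with the log-cosh contrast (via
scikit-learn), unit-variance sources.  Artefact components are flagged by a
robust outlier rule on excess kurtosis: a component is removed when
`(kurt − median) / (1.4826 · MAD) > kurtosis_z` (default 3.0).  The rule is
explicit, configurable and disableable because no principled universal
criterion exists; it never flags all components.  Cleaning runs per
recording by default (artefact statistics are better estimated on long
stretches); per-epoch operation is a configuration switch.

Numerical choices: the fixed-point iteration frequently does not reach
`tol = 1e-6` on long EEG-like data whose background sources are
near-Gaussian — the model is still returned, flagged `converged=False`.
For 15-minute recordings the pipeline estimates the unmixing matrix on
every 4th sample (`ica_fit_stride=4`, `tol=1e-4`, `max_iter=200`) and
applies it to the full signal; mixing statistics are stable under this
decimation and the flagged components are unchanged, while the runtime
drops roughly eightfold.  The high-kurtosis blink component is found within
the first few iterations regardless.

## Empirical wavelet reconstruction (ALEEWR)

Per channel: the one-sided FFT magnitude is smoothed by a 5-bin moving
average (width 1 disables it) and its `n_peaks` largest interior local
maxima are kept (default 5, range 1–16; ties keep the lower frequency;
maxima below 1e-8 of the peak magnitude are treated as numerical leakage
and ignored).  Boundaries are midpoints of consecutive maxima.  A
Meyer-type bank is built with transition polynomial
`β(x) = x⁴(35 − 84x + 70x² − 20x³)` and a single transition-width parameter
γ that must satisfy the strict no-overlap bound
`γ < min_i (φ_{i+1} − φ_i)/(φ_{i+1} + φ_i)`; `auto` uses 0.9 × the bound.
Two deliberate conventions:

* The bound additionally includes the Nyquist headroom term
  `(fs/2 − φ_last)/(fs/2 + φ_last)` so the last transition stays on the
  sampled grid; the last wavelet is then flat (=1) up to Nyquist.  Without
  this, the partition-of-unity identity cannot hold on the grid.
* **Self-adjoint application**: the squared responses satisfy
  `ρ₁² + Σ Ψᵢ² = 1` at every grid point, and each mode is
  `irfft(rfft(x) · response²)`.  Plain summation of modes then reconstructs
  the input exactly (relative L2 < 1e-6 on random signals, < 1e-15 in
  practice), which is exactly what the downstream mode-sum reconstruction
  assumes.

Mode selection scores each mode by `LE = ln Σ w²` (energies floored at
1e-300).  Scores are min-max normalised; modes with normalised score
≥ threshold (default 0.10) are summed, and the argmax is always kept.  The
log compresses dynamic range so weak but structured modes survive — the
point of scoring on a log scale.  An all-equal score vector selects
everything.  The alternative `energy-share` basis normalises linear
energies by their total.  One structural caveat: under min-max the weakest
mode is normalised to exactly 0, so it stays excluded for every positive
threshold; the "threshold → 0 recovers the input" completeness limit
therefore holds exactly on the energy-share basis and up to the weakest
mode's energy on min-max.  The threshold is static; adaptive thresholding
is out of scope.

## Cepstral Hjorth features

`c = Re ℱ⁻¹ log max(|ℱ x|, ε)` with ε = 1e-12 × the peak spectral magnitude
(relative, because inputs are z-scored).  On `c`:

* activity `A = (1/N) Σ (cᵢ − μ)²` — population variance, the cepstral
  analogue of signal power;
* mobility `M = √(A(Δc)/A(c))` — rate of change; the square-root convention
  is standard for Hjorth mobility and makes `C = 1` the pure-sinusoid
  reference case (a printed definition without the radical is available as
  `sqrt_mobility=False`);
* complexity `C = M(Δc)/M(c)` — deviation from sinusoidal regularity.

Δ is the unit-spacing first difference; any constant quefrency step cancels
in the ratios.  Features are computed on the full-band reconstructed
channel, not on rhythm sub-bands.  A 19-channel epoch yields 57 features
named `A/M/C + channel` in channel-major order.  M and C are exactly
invariant to scaling of the cepstrum; invariance to *input* gain is exact
end-to-end only because z-scoring runs upstream (raw gain shifts quefrency
0 by ln a, which enters the variances at O(ln²a/N)).

## Feature ranking and classification

One-way ANOVA F per feature: `F = (SSR/(k−1))/(SSE/(n−k))` from the
sum-of-squares partition SST = SSR + SSE.  A perfectly separating feature
(SSE = 0, SSR > 0) gets a +∞ sentinel and outranks everything; SSR = 0
scores 0.  Sorting is stable (ties keep the lower column index).  By
default the harness re-ranks inside each training fold — ranking once on
the full table before CV leaks selection information; that paper-faithful
global mode remains available as `selection_scope="global"`.

KNN presets: FKNN (k=1, Euclidean, uniform), WKNN (k=100, Euclidean, 1/d²
votes), CKNN (k=10, Minkowski order 3, uniform — the neighbour count for
the "cubic" variant is unstated upstream; 10 is this package's default and
configurable).  Voting contracts: uniform ties resolve to the
smallest-index (nearest) winning neighbour; a zero-distance neighbour
decides outright under inverse-square weighting; k is clipped with a
warning when the training fold is smaller.  Evaluation: stratified 10-fold
CV, a fresh seeded shuffle per repeat (repeat r uses seed + r), fold
confusions aggregated per repeat, metrics averaged over repeats
(default 20).  Schizophrenia is the positive class.  Epoch-level folding
reproduces the upstream protocol; `subject_cv=True` gives leakage-free
grouped folds instead.

## Synthetic data: the stated world

Defaults mirror the reference dataset's geometry: 14 subjects per class,
36 × 20 s epochs each (504 epochs per class), 19 channels, 250 Hz.  Each
channel is the sum of:

* a class-dependent resonance — an AR(2) oscillation with pole at 10 Hz,
  radius 0.98 (healthy); the schizophrenia class shifts the pole by
  `2·class_effect` Hz, broadens it (radius `0.98 − 0.015·class_effect`) and
  adds a harmonic ripple at twice the pole frequency with gain
  `0.4·min(class_effect, 1)`.  All differences scale with `class_effect`,
  so at 0 the classes are exchangeable by construction;
* 1/f^slope background noise (SD 0.5 relative to the unit-variance AR
  part), high-passed at 0.5 Hz — the standard acquisition high-pass.  This
  matters: without it the realised variance of 1/f noise is dominated by a
  few near-DC modes, normalisation makes the in-band noise level a
  per-recording random quantity, and epochs become subject-identifiable
  (epoch-level CV then reads ~0.8 under the null purely from subject
  leakage);
* blink artefacts — a shared train of ~0.4 s smooth bumps at a Poisson rate
  (default 4/min), projected on the frontal channels (Fp1, Fp2, F7, F3, Fz,
  F4, F8) with fixed topography and amplitude 5; ground truth (times,
  train, topography) is retained per recording;
* per-channel gains drawn uniformly from [0.5, 2], exercising the gain
  normalisation.

What a green test establishes: that the implementation separates classes
whose cepstral structure differs by construction, at the stated geometry,
and sits at chance when it does not.  What it does not establish: anything
about physiological EEG — no head model, no microstates, no non-stationarity,
no inter-subject variability in rhythm frequency; published accuracies on
clinical data are not reproducible from this generator and are not claimed.

## Degenerate inputs and tie-breaks

Constant channels are rejected by name at normalisation; all-zero channels
pass through ALEEWR as zeros with a warning; all-zero signals have no
spectrum/cepstrum and raise; spectra with no interior maximum fall back to
the largest interior bin with a warning; equal-magnitude peaks keep the
lower frequency; equal F-weights keep the lower feature index; zero
confusion denominators yield NaN sentinels.

## Known limitations

Epoch-level CV overstates generalisation whenever epochs of one subject
share structure (use `subject_cv=True` for honest subject-level claims).
The ALEEWR threshold is static.  The EDF reader handles continuous 16-bit
EDF only.  Instantaneous frequency/amplitude extraction from the wavelet
modes is not implemented (nothing downstream consumes it).
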