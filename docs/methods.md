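# Methods

This note documents the models and procedures implemented in `pacsoz`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Band decomposition

The analysis grid pairs 16 low-frequency (phase) bands with 16
high-frequency (amplitude) bands:

* phase bands tile 0.5–24 Hz with bandwidths 0.5 Hz (0.5–1), 1 Hz (1–8) and
  2 Hz (8–24), resolving the δ band finely while keeping the grid square;
* amplitude bands tile 80–560 Hz in 30 Hz steps, spanning the ripple
  (80–260 Hz) and fast-ripple (260–560 Hz) ranges of high-frequency
  oscillations.

Filters are FIR band-passes designed with a Kaiser window targeting ≥ 60 dB
stopband attenuation and a transition width of half the band's bandwidth.
The tap count implied by the Kaiser formula is forced odd (a zero at Nyquist
is thereby avoided and the filter is exactly linear-phase of integer group
delay) and clamped to [101, 20001] taps.  The clamp only binds for the
narrowest bands at 2 kHz sampling (the 0.5-Hz-wide band would want ~29 000
taps; at 20 001 its transition widens to ≈ 0.36 Hz, which still resolves the
band's centre at unit gain).  A transition width tied to the bandwidth —
rather than to the band's low edge — is what keeps a mid-band tone at unit
gain for *every* grid band; a cycles-of-low-edge rule makes the transition
wider than the band itself for the narrow low-frequency bands and attenuates
in-band content.

Filtering is applied zero-phase.  The modular operation `fir_bandpass` uses
a centred linear convolution (`fftconvolve(..., 'same')`, exact zero phase
for odd symmetric taps).  The pipeline path `channel_analytic` performs the
equivalent operation in the frequency domain — one FFT per channel, a
multiplication by the taps' real (zero-phase-shifted) frequency response
combined with the analytic-signal mask, and one inverse FFT per band — which
is ~2–3× faster over 32 bands and equals `hilbert(fir_bandpass(x))` up to
periodic-versus-linear edge effects confined to half a filter length at the
record boundaries (tested to ~1e-3 rad / 0.1 % amplitude mid-record; the
residual exists because the Hilbert transform is itself a global FFT
operation).  Phase is the angle of the analytic signal in (−π, π];
amplitude its magnitude.  Records are decomposed whole, then cut into
non-overlapping 20-s segments in chronological order (a 1-h record gives
exactly 180 segments; a trailing partial segment is discarded).  Record
edges are retained, not trimmed, so the segment count of a 1-h record is
exact; only the first and last half-filter-length samples carry transients.

## Surrogate-normalized MVL modulation index

For one (phase band, amplitude band, segment) triple, with φ(t) the phase
series and A(t) the amplitude series,

* raw index: MI_raw = |mean_t A(t)·e^{iφ(t)}|;
* surrogates: the phase series is circularly shifted by n_surrogates = 100
  random lags drawn uniformly from [min_shift, N − min_shift] with
  min_shift = 2000 samples (1 s at 2 kHz), which preserves both marginals
  and their autocorrelation while destroying phase–amplitude alignment;
* z-scored index: MI = (MI_raw − μ)/σ with μ, σ the surrogate mean and
  sample (ddof = 1) standard deviation.

Implementation detail: MI_raw at *every* circular lag is obtained at once
from one FFT cross-correlation, |IFFT(FFT(e^{iφ})·conj(FFT(A)))|/N, which is
numerically identical (≤ 1e-12) to explicit rolling and makes the surrogate
loop O(N log N) per cell instead of O(n_surrogates·N).  Surrogate draws are
seeded per (channel, segment, cell), so results are independent of
evaluation order and safely parallelisable.  Degenerate segments with zero
surrogate spread return MI = 0 with a warning.  Negative z values are
retained.  A 16×16 comodulogram stores MI with amplitude bands as rows and
phase bands as columns.

Calibration: under independent phase and amplitude the z-scores are
approximately standard normal — across 200 white-noise segments the mean is
within ±0.1 and the standard deviation within (0.8, 1.2).  The standard
deviation sits slightly above 1 (typically 1.05–1.12) because the ~1 s
phase-coherence time of a narrow low-frequency band leaves only a few dozen
effectively independent lags in a 20-s segment, which makes the surrogate σ
estimate noisy; this is intrinsic to time-shift surrogates at these
parameters, not an implementation artefact.

## Synthetic recordings

Each channel is

    x(t) = sin(θ(t)) + 0.5·(1 + κ·sin(θ(t)))·sin(2π f_a t) + ε(t)
    θ(t) = 2π f_p t + φ_w(t)

with κ the coupling depth (forced to 0 on NSOZ channels), f_p = 3 Hz,
f_a = 120 Hz, ε white Gaussian noise with σ = 1, and φ_w a Wiener phase
drift with diffusion 4 rad²/s.  The drift is load-bearing: a strictly
periodic modulator is invisible to circular time-shift surrogates (shifting
a perfect sinusoid's phase only rotates the mean coupling vector, leaving
|MI_raw| unchanged), whereas physiological slow rhythms hold phase for only
a few cycles.  The chosen diffusion gives a Lorentzian linewidth of
≈ 0.64 Hz — the periodogram still peaks within 1 Hz of f_p — and
decorrelates surrogates shifted by ≥ 1 s.  Setting `phase_drift=0` recovers
the strictly periodic construction for exact envelope checks.

Defaults mirror the clinical recording conditions: 2 kHz sampling, 1 h
duration, and electrode imbalance inside the observed 1:3.75–1:19 range
(the seven-patient reference cohort table with its per-patient SOZ/NSOZ
electrode counts ships in `synthgen.COHORT`; its extremes — ratios 3.75 and
19, electrode totals 36–76 — set the generator's realistic operating
range).  κ defaults to 0.8: with σ = 1 noise this yields per-segment z
values of ~5–8 at the injected cell, comparable to a clearly coupled
electrode rather than a noise-free idealisation.  Optional extras: a 1/f
background and brief high-amplitude spike transients (~70 ms Gaussian
bumps at Poisson times), both off by default.  Channels draw from
independent seed substreams, so adding channels never changes earlier ones.

Not emulated: spatial correlation between electrodes, non-stationary
coupling strength, line noise, artefacts, multiple simultaneous coupling
band pairs, and pathology-specific waveform morphology.  Passing tests on
these recordings therefore demonstrates correct *recovery of injected
structure under realistic noise and imbalance*, not clinical performance.

## Electrode statistics

Per electrode, comodulograms are averaged elementwise over segments.  Eight
band pairs — δ (0.5–4), θ (4–8), α (8–12), β (12–24 Hz) crossed with ripple
(80–260) and fast ripple (260–560 Hz) — are each reduced by the unweighted
mean over their grid cells (δ×ripple covers 4×6 = 24 cells); θ is taken as
4–8 Hz so that every range is an exact union of grid cells.  SOZ and NSOZ
electrode values are compared per pair with a two-sided Mann-Whitney U test
at α = 0.001, with no correction across the eight pairs (each pair is
reported on its own, as is conventional for this analysis).  The p value
uses the exact U distribution whenever there are no ties and both groups
have ≤ 25 electrodes, and the tie-corrected normal approximation otherwise.
The exact branch matters: at 4-vs-16 electrodes the normal approximation
cannot fall below p ≈ 0.0025 even under perfect separation, while the exact
two-sided p reaches 2/C(20,4) ≈ 4.1×10⁻⁴.

## Classifiers

All five models consume per-segment features and expose `fit` /
`predict_score` (monotone SOZ score) / `predict_proba` uniformly.

* **Class-weighted SVM (linear, RBF).**  Features are the flattened 256
  cells, standardised per column with training-split statistics only.  The
  per-class penalty is C_i = C·ω_i with ω_i = N/(2·n_i) (so Σ n_i ω_i = N).
  AUC uses the decision function; probabilities come from a Platt-style
  logistic sigmoid fitted on the training decision scores.  The sigmoid is
  deliberately fitted without inner cross-validation: with only a handful of
  positive segments per fold, cross-validated Platt scaling is unstable and
  was observed to anti-correlate with the decision function.  Default search
  grids: C ∈ {0.1, 1, 10, 100}, RBF γ ∈ {10⁻³, 10⁻², 10⁻¹, 1, 'scale'}
  (overridable).
* **LightGBM** with the same ω_i class weights and the four-parameter tuning
  grid num_leaves ∈ {35..65 step 5}, max_depth ∈ {4, 6, 8, 10},
  learning_rate ∈ {0.01, 0.05, 0.1, 0.15}, min_data_in_leaf ∈
  {20, 40, 60, 100} (448 configurations).
* **2-D CNN** on the 16×16 comodulogram: conv(32, 3×3) → BN → ReLU →
  conv(64, 3×3) → BN → ReLU → maxpool 2×2 → conv(128, 3×3) → BN → ReLU →
  maxpool 2×2 → dense(128, ReLU) → dropout 0.5 → dense(1, sigmoid), same
  padding and stride 1 throughout, He-uniform initialisation, Adam
  (lr 10⁻³), batch 128, up to 100 epochs with early stopping (patience 10 on
  validation loss, best weights restored).  The dense width (128) and 'same'
  padding are our choices where the architecture was under-specified; the
  shape chain is 16×16×1 → 8×8×64 → 4×4×128 → 2048.  The network is
  implemented directly on numpy (im2col convolutions, batch-norm, pooling
  with tie-splitting, inverted dropout); backpropagation is verified against
  finite differences to ≤ 1e-4 relative error, and conv biases — made
  redundant by the following batch-norm — receive exactly-zero gradients.

Losses for the CNN (natural log, p clamped to [10⁻⁷, 1−10⁻⁷]):

* focal: FL(p_t) = −α_t(1−p_t)^γ log p_t, grids α ∈ {0.75, 0.9, 0.99,
  0.999, 0.9999}, γ ∈ {0.5, 1, 2, 5}; γ = 0 recovers α-balanced
  cross-entropy exactly.
* class-balanced focal: the per-sample weight is 1/E_n with
  E_n = (1−β^n)/(1−β) and n the sample's class count *within the current
  training subset*; grids β as α above, γ as above.  The loss is implemented
  as the non-negative −(1/E_n)(1−p_t)^γ log p_t (a sign slip in the common
  statement of this loss would otherwise reward misclassification).

## Time-series nested cross-validation

Segments are cut chronologically into K+1 equal folds (default K = 5; the
segment count must be divisible by K+1, otherwise the caller is told to
trim).  Fold assignment is segment-synchronous across electrodes so a time
period never appears in both train and test through different channels.
Split k trains on folds 1..k and tests on fold k+1.  The inner loop is a
single chronological 80/20 split of the training set (not k-fold): the grid
search trains each configuration on the first 80 % and selects by
validation AUC, ties broken by declared grid order; the winner is refit on
the whole training set and scored on the test fold.  The classification
unit is the segment; per-electrode output is the mean predicted SOZ
probability over the electrode's test segments within each split, averaged
across splits.  Splits whose validation or test set is single-class record
a missing AUC and are excluded from the mean with a warning.  The summary
is mean ± std over splits.  AUC is computed as the rank statistic (ties
count ½) and equals the Mann-Whitney U of the positive group over n₁·n₂ —
an identity cross-checked between modules in the tests.

## Problem sizes

The test suite and the acceptance script run desk-scale versions of the
full-scale analysis; these sizes are the package's documented operating
points, chosen to preserve every qualitative property:

* null calibration: 200 twenty-second white-noise segments, one band pair
  ((3–4) Hz × (110–140) Hz), 100 surrogates;
* parameter recovery: 4 SOZ / 16 NSOZ electrodes, 5-minute recordings
  (15 segments), full 16×16 grid, 50 surrogates;
* classification: 2 SOZ / 18 NSOZ electrodes (1:9), 8-minute recordings
  (24 segments → 6 chronological folds of 4), 50 surrogates, RBF SVM with a
  4-point grid, plus a segment-level label-permutation control.

At these sizes the injected coupling is recovered at the correct grid cell,
the δ-ripple group test reaches its exact-distribution floor
(p ≈ 4.1×10⁻⁴ < 0.001), and the nested-CV AUC is ≥ 0.9 with intact labels
and ≈ 0.5 under permutation.  On synthetic recordings with κ = 0.8 the
separation is essentially perfect (AUC ≈ 1); real recordings, with weaker
and non-stationary coupling, sit lower.

## Known limitations

* The surrogate z-score's variance slightly exceeds 1 at 20-s segments (see
  above); thresholds interpreted as exact normal quantiles are mildly
  anti-conservative.
* Comodulogram cells are computed independently; no spatial or spectral
  smoothing and no multiple-comparison control across the 256 cells.
* The CNN is a faithful but compact numpy implementation tuned for 16×16
  inputs; it is not optimised for large batches or GPUs.
* Per-electrode probabilities are Platt-calibrated from training scores and
  are useful for ranking electrodes within a patient, not as calibrated
  cross-patient probabilities.
* The generator's independence across channels means cross-electrode
  leakage — a real confound for chronological CV on clinical data — is not
  exercised.
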