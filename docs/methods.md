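# Methods

## Problem and approach

Epileptiform discharges are transient scalp-EEG waveforms (tens to hundreds
of milliseconds) whose presence supports an epilepsy diagnosis. `epidisc`
implements two interpretable feature pipelines for separating 4 s,
19-channel (10–20 montage), 256 Hz EEG epochs containing such discharges
from normal epochs, plus a network-based scalp localization procedure:

* **Method One.** Two features per epoch: the *Signal Range* — the mean of
  the 10 largest per-channel max−min excursions — and the mean short-scale
  Hurst exponent of the 19 channels, estimated by adaptive fractal analysis
  (AFA).
* **Method Two.** Three features per epoch: the squared largest singular
  value σ₁² of each of three 19×19 *channel-difference networks*, whose
  (i, j) entry is respectively the Signal Range, the relative alpha-band
  (8–13 Hz) energy, or the short-scale Hurst exponent of the difference
  series xᵢ − xⱼ. Differences of channel pairs are reference-free, which
  weakens the dependence on the recording montage.

Both feature sets feed a random-forest classifier evaluated with a
stratified 2/3–1/3 split, confusion-matrix metrics (sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), accuracy = (TP+TN)/total, positive class =
discharge) and a threshold-swept ROC/AUC.

## Adaptive fractal analysis

For a series x, AFA integrates the mean-removed samples into a profile
u(n) = Σ_{k≤n}(x(k) − x̄), then, for each odd window size w, fits order-M
polynomials in windows overlapping by (w+1)/2 samples and crossfades the
overlapped fits — weights 1 − (l−1)/(n−1) and (l−1)/(n−1) across an overlap
of n = (w+1)/2 points, first/last half-windows unweighted — into a single
smooth global trend v. The fluctuation F(w) = √(mean (u−v)²) scales as w^H
for fractal processes; regressing log₂F on log₂w gives H. EEG shows two
scaling regimes, so a two-segment piecewise-linear fit (breakpoint chosen to
minimize total squared error, at least 3 points per segment) yields the
short-scale exponent `h_short` used everywhere downstream.

Numerical choices:

* **Polynomial order** M = 2 by default (1 is exposed). The local
  coordinate is centered and scaled before building the Vandermonde basis.
* **Window grid**: dyadic sizes 2^k+1 plus intermediate odd values
  {25, 49, 97, 193, 385}, truncated to ≤ N/2, **starting at w = 17 by
  default**. Windows of 5–11 samples leave an order-2 fit almost no
  residual degrees of freedom; the detrending then absorbs a
  scale-dependent share of the fluctuation and bends the small-w end of
  the log-log curve (measured local slope ≈ 0.5 at w = 5–7 for a true
  H = 0.3), biasing the short-scale slope. Starting at 17 samples (66 ms
  at 256 Hz) removes this bias while staying well inside the short-scale
  regime. `min_w=5` restores the full curve for inspection.
* **Degenerate inputs**: exactly constant series (they occur only as a
  channel's self-difference) have F(w) = 0 at every scale; their Hurst
  entry is set to 0 by convention. Series shorter than 64 samples are
  rejected; a two-regime fit additionally needs ≥ 6 grid points.
* Measured accuracy on exact fractional Gaussian noise (100 seeds): mean
  |ĥ_short − h| ≈ 0.01–0.015 at N = 8192 and 0.03–0.05 at N = 1024 for
  h ∈ {0.3, 0.6, 0.8}.

## Spectral features

The PSD is an averaged periodogram (Welch: 1 s Hann segments, 50% overlap),
which stabilizes the estimate on a 4 s epoch; band energies are trapezoidal
integrals over the clinical bands (delta 0.5–3, theta 4–7, alpha 8–13, beta
14–30, gamma 30–70 Hz, capped at the 70 Hz analysis bandwidth). Alpha
energy is *relative* by default — divided by the total 0.5–70 Hz power —
with an absolute mode available.

## Networks, SVD and localization

Feature networks are computed on the 171 upper-triangle pairs and mirrored
(all three edge features are invariant under sign flip, so symmetry is
exact); the diagonal is 0. σ₁ of a symmetric matrix equals its largest
absolute eigenvalue; the unit first singular vector u₁ has its sign fixed
so its largest-magnitude entry is positive.

Localization retains channel j when |cos(col_j, u₁)| ≥ 0.5 (the cosine
normalization keeps the threshold unit-free; a raw dot-product mode
exists), intersects the three per-network selections per subject
(2-of-3 majority available), merges multiple epochs of one subject by
union, and keeps channels selected in ≥ 55% of subjects.

**Known limitation.** On cohorts whose background is statistically
identical across channels, all three networks are nonnegative matrices with
homogeneous entries; u₁ is then their Perron vector and *every* column's
cosine with it stays well above 0.5 (≈ 0.87–0.97 measured; even the clean
bipartite focal-structure limit gives 1/√2 ≈ 0.707). Because the cosine is
scale-invariant, raising the planted discharge amplitude does not change
this: the per-subject selection saturates at all 19 channels and the
cohort step cannot prune. Selective localization therefore requires
between-subject or between-channel heterogeneity of the kind real clinical
recordings have and the symmetric synthetic cohort deliberately lacks. The
test suite asserts the sharper focal-recovery property anyway and it fails
on synthetic data; the weaker property — planted focal channels are always
*contained* in the selection — holds.

## Synthetic data

The generator provides ground truth the clinical recordings cannot (they
are not distributed): every epoch is fGn background + alpha rhythm
(+ discharge template). What it emulates and why:

* **Fractal background**: fractional Gaussian noise generated by circulant
  embedding, which is exact — the sample autocovariance matches the fGn
  closed form — so Hurst-recovery tests are meaningful. Class-conditional
  exponents: normal 0.60, discharge 0.75 (transient-laden epochs are more
  persistent), with a between-epoch SD of 0.06 so classes overlap
  realistically rather than being point masses; background scale 15 µV.
* **Alpha rhythm**: one frequency per epoch drawn from 8–13 Hz, random
  phase per channel, amplitude 8 µV (normal) vs 16 µV (discharge), doubled
  on O1/O2 to reproduce the occipital dominance of alpha.
* **Templates**: smooth asymmetric biphasic bumps (fast rise, slower
  fall), negative-going by default (polarity exposed, since clinical sharp
  waves are usually negative); slow waves are half-sines of 200–500 ms.
  Durations and amplitudes respect the clinical boxes (spike 20–70 ms,
  > 50 µV; sharp 70–200 ms, 100–200 µV; polyspike ≥ 2 spikes; spike
  rhythm 10–25 Hz, 100–200 µV, ≥ 1 s); defaults are midpoints with a
  150 µV amplitude. The waveform is rescaled so its peak-to-trough range
  equals the requested amplitude exactly.
* **Spatial structure**: the template is planted at a random onset on the
  focal channels (default F7/T3) and scaled by attenuation^d (default
  0.4^d) at scalp-graph distance d, which is negligible beyond two hops.
* **Class catalog**: 100 normal epochs and 540 discharges split
  69/82/174/72/64/77/2 across the seven types.

What it does **not** emulate: volume-conduction forward physics, eye-blink
and muscle artifacts, inter-subject electrode-impedance variation, or
non-stationarity within an epoch. Passing tests therefore demonstrate that
the pipeline recovers *planted* fractal, spectral and amplitude structure —
not clinical-grade performance; the published clinical accuracies are not
reproducible without the original recordings.

On this synthetic cohort both methods separate the classes almost
perfectly (AUC ≈ 1.0), which mirrors — but deliberately does not claim to
reproduce — the published ordering (network method ≥ range/Hurst method).

## Problem sizes

Default analyses use the full 640-epoch cohort (1024 samples per channel).
Hurst-recovery checks use 100 seeds at N = 8192 and N = 1024; the
end-to-end classification property uses 20 seed replicates of the full
cohort; localization cohorts use 50 single-epoch subjects. The acceptance
script runs one end-to-end replicate per method and 50 seeds per Hurst
condition.

## Other design choices

* Zero-phase filtering (forward-backward 4th-order Butterworth 0.1–70 Hz
  plus a Q = 30 notch at 50 Hz) preserves transient morphology that Signal
  Range depends on; digital re-filtering of ingested data is optional
  (default on).
* Earlobe-referenced input is taken as-is ("raw"); average referencing
  subtracts the instantaneous 19-channel mean. Channel differences are
  unaffected by either.
* Splits use per-class floors: floor(2/3·n) training items per class, the
  remainder test — with 100/540 epochs this gives exactly 66/360 train and
  34/180 test.
* Random forest: 100 trees, Gini splits, unlimited depth. The claim under
  test is feature quality, not classifier tuning, so hyperparameters stay
  at library defaults with a fixed seed.
* Epochs are segmented without overlap; a trailing partial epoch is
  discarded.
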