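# Methods

This note documents the models, parameter choices, and numerical decisions
behind `taskprio`, in the order data flow through the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic paradigm (`taskprio.simulate`)

**Trial schedule.** The design crosses important task (NCT/WMT), retro-cue
side, and classification type. Within every block each factor level appears
equally often and every *pairwise* co-occurrence is exactly balanced; this
requires block lengths divisible by 4. With the canonical 60-trial blocks
the eight triple cells cannot all be equal (60/8 = 7.5), so they alternate
between 7 and 8 trials in an XOR pattern that keeps all pairwise margins
exact, with the pattern flipped on alternating blocks. Response side is
split as evenly as possible within each cell so that the retro-cue ×
response-side cells needed for lateralization balancing are never empty.
Event onsets are fixed: relevance cue 0 ms (500 ms), memory items 3000 ms
(400 ms), classification cue 5600 ms (200 ms), classification digit 6800 ms
(200 ms), retro-cue 9600 ms (200 ms), memory target 10800 ms.

**Behavior.** The paradigm's published condition means/SDs are the defaults
(NCT RT 537.00/114.13 ms important vs. 562.86/119.61 ms unimportant; NCT
error rates 8.56%/8.66%; WMT RT 1292.68/267.38 vs. 1368.91/300.92 ms;
deviation 13.48°/5.23° vs. 11.77°/4.07°). Per-trial distributions are not
published, so a family had to be chosen once: RTs are moment-matched
log-normal (right-skewed, positive, the standard RT choice) truncated to
the registration windows ([200, 1800] ms classification, [200, 4500] ms
reproduction) by resampling; angular deviations are truncated normal on
[0°, 180°]. Truncation bias is negligible at the default parameters (the
windows sit ≥ 3 SD from the means). Feedback follows the two linear score
formulas with maxima 75 (cued) / 25 (un-cued); missing or incorrect
classification answers and deviations ≥ 45° score zero.

**EEG.** Background is 1/f power-law noise (exponent 1.0, per-trace SD
normalized to 10 µV) plus 1 µV white sensor noise, per trial and channel —
the spectral shape the wavelet stage expects of EEG. Data are emitted
"clean" at 200 Hz over −3700…+13700 ms (preprocessing is out of scope; the
extra 700 ms per side exists to be trimmed after convolution). Planted
effects are additive:

- *Band bursts*: a Tukey-windowed (α = 0.25) sinusoid with a random phase
  per trial, applied to a channel subset and optionally only to trials of
  one condition. Defaults emulate the paradigm's observed phenomenology
  (relevance-cue theta and beta bursts and a retention theta burst for
  NCT-important trials; a number-task alpha burst for WMT-important trials).
- *Lateralized alpha*: one carrier per 1 Hz step across 8–15 Hz (random
  phases) on the 17 posterior pairs, with pair members scaled by
  √(1 ± index) according to the retro-cue side. The target quantity is
  therefore the lateralization index itself. Carriers span the whole pooled
  band because the pooled curve averages all band wavelets: a single-carrier
  burst would be diluted by the signal-free wavelets. The default per-carrier
  amplitude (25 µV) makes the burst dominate the band power so the measured
  index approaches the planted one; the residual background contribution
  biases it toward zero by well under 0.01 at defaults. This amplitude is
  deliberately large for recoverability, not a claim about physiological
  alpha SNR.
- *Decoding patterns*: one fixed random unit-norm 64-channel pattern per
  classification type drives a phase-locked broadband component (visible to
  ERP features), and a second pattern modulates 10 Hz amplitude per channel
  (visible to alpha-power features), both inside the number-task window.

Identical seed and effect specification give bit-identical arrays; every
stochastic stage in the pipeline derives its seed as
`(global·1000003 + crc32(stage)) mod 2³¹`.

**What a green test does not establish.** The generator has no eye or muscle
artifacts, no volume-conducted correlation structure between channels
(noise is independent per channel), no trial-to-trial amplitude drift, no
subject-level random effects beyond independent noise, and stationary 1/f
spectra. Recovery tests therefore validate the *estimators* — that each
analysis measures what it claims on data satisfying its assumptions — not
robustness to real-recording pathologies.

## Time–frequency decomposition (`taskprio.tfr`)

Complex Morlet wavelets are parameterized by FWHM. The temporal FWHM is
interpolated linearly in frequency between 1000 ms at 2 Hz and 200 ms at
20 Hz; the spectral FWHM follows from the Gaussian reciprocity
FWHM_t·FWHM_f = 4 ln 2/π ≈ 0.8825 (≈ 0.88 Hz at 2 Hz, ≈ 4.41 Hz at 20 Hz,
measured on amplitude spectra). The two published endpoint pairs are not
exactly co-satisfiable under reciprocity; the temporal endpoints are taken
as exact and the spectral widths derived, which lands within 4% of the
published spectral endpoint at 20 Hz. Kernels are unit-energy normalized
(power ratios, dB values and the lateralization index are invariant to any
consistent choice), span ±4 temporal SDs, and are applied by FFT
multiplication with "same" alignment; one FFT length serves the whole bank.
After convolution the first and last 700 ms are deleted. dB conversion uses
the across-trials (condition-pooled), across-baseline-window mean raw power
per channel and frequency, window −700…−200 ms; the baseline is stored so
the transform inverts exactly. Zero baseline power raises an error naming
the offending channel/frequency pairs.

## Cluster-based permutation tests (`taskprio.cluster`)

Cluster-forming threshold: two-sided per-pixel p < 0.05 on the paired t
(df = n−1). Clusters are connected components of same-sign suprathreshold
pixels; adjacency is montage channels within Euclidean distance 0.55 on the
unit-sphere montage (median ≈ 6 neighbors) × ±1 frequency step × ±1 time
sample, built once as a sparse Kronecker sum. Cluster statistic: sum of t
("mass"). The null is the distribution of the maximal |mass| over random
sign flips of subject-wise difference maps; Monte-Carlo p values use the +1
correction, `p = (1 + #{max ≥ |mass|})/(1 + n_perm)`, with 1000 permutations
by default. `n_permutations="all"` enumerates all 2ⁿ sign patterns
(n ≤ 20), reproducing the exact permutation test — verified against
brute-force enumeration in the suite. Zero-variance pixels get t = 0 with a
warning. Effect sizes per pixel are available as adjusted partial eta
squared via F = t².

The time axis of the 3-D test is bin-averaged to 20 Hz by default in the
pipeline (the test itself is resolution-agnostic); this is a compute-scale
choice, not a statistical one.

## Lateralization (`taskprio.lateralization`)

"Ipsilateral" means the hemisphere on the same side as the retro-cued item,
so a positive index = lower contralateral alpha = attention toward the cued
item. Trials are drawn so each retro-cue × response-side cell is truncated
to the minimum cell count (the only count-preserving reading of "drawn …
equally often"); an empty cell is an error. Raw (linear) power is required —
dB input raises. Averaging over trials precedes the index; the pooled curve
averages the 17 posterior pairs and all wavelet centers in 8–15 Hz
inclusive. The index is bounded in [−1, 1], antisymmetric under cue-side
flips, and invariant to global power scaling (all property-tested).

## Decoding (`taskprio.decoding`)

Features are downsampled to 20 Hz by non-overlapping bin averaging (the
averaging itself denoises and keeps alignment trivial; plain decimation
would be the alternative reading). No per-feature normalization is applied.
Per iteration, each class's trials are randomly assigned to 15 equal
groups, surplus trials randomly excluded, and group averages computed once
for all time points (assignment is constant across time within an
iteration). Each fold trains a linear SVM (C = 1, hinge loss — the binary
special case of the multi-class wrapper the original used) on 14 + 14
averages and classifies the two held-out averages, so each class receives
10 × 15 = 150 predictions per time point; accuracy is correct/made, and
per-class accuracies are the confusion summary. Curves are smoothed by an
edge-truncated 5-point moving average. For speed the package calls
scikit-learn's low-level libsvm binding directly (prediction-identical to
`SVC(kernel="linear")`, verified in the suite; a public-API fallback
engages automatically if the private binding moves).

One scheme-inherent caveat the suite documents: duplicating one class's
trials verbatim into the other drives accuracy far *below* chance, because
held-out group averages share trials with the opposite class's training
averages. The meaningful chance-level null is two classes drawn
independently from one distribution, which calibrates to 50%.

## Inference (`taskprio.inference`)

`d = t/√n` and `eta_adj = (F−1)/(F−1+(df_error+1)/df_effect)` with
F = t², df_effect = 1. These definitions were adopted because they
reproduce every published (t, d, η) triple to two decimals — that
consistency check is part of the acceptance suite. The JZS Bayes factor is
the Cauchy-mixture marginal of the noncentral-t likelihood over the central
one, integrated adaptively (scipy `quad`, relative tolerance 1e−10, the
real line split around the likelihood peak at δ = t/√n so the quadrature
cannot miss a narrow peak). It is validated against two independent routes:
pingouin's implementation and a dense log-grid quadrature of the equivalent
inverse-gamma g-mixture. Log-space evaluation keeps it finite beyond
t = 60 (BF10 ~ 10²⁷).

## Pipeline and configuration (`taskprio.pipeline`)

`RunConfig` defaults are the paradigm's constants (28 subjects, 10 × 60
trials, 19 wavelets, 15 groups × 10 iterations, prior scale 0.707, pooled
band 8–15 Hz); everything is overridable and validated with a collected
error list (bands outside 2–20 Hz need an explicit override flag). The
runner streams the TFR one frequency at a time and reduces immediately to
condition means / pair averages, so paper-scale trial counts fit in memory.
Interval statistics average over the time points of significant
vs-reference clusters when any exist (the union over conditions for the
paired contrast), else over a configured fallback window, and the source is
recorded in the output. Reruns with the same configuration are bit-identical
(JSON with sorted keys; all randomness seed-derived).

## Known limitations

- Montage positions are constructed geometrically on a sphere, not
  digitized; adjacency and mirror pairing are faithful, absolute distances
  are approximate.
- The 3-D cluster test assumes subject-wise exchangeability under the null
  (paired designs only); between-subject designs and TFCE are out of scope.
- Extreme Bayes factors (≳10²⁴) are computed stably but are inherently
  sensitive to rounding in the input t.
- The default run at full paradigm scale (28 × 600 trials, 19 frequencies)
  is compute-heavy by design; tests and the acceptance script use reduced
  but statistically calibrated scales (documented in each test).
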