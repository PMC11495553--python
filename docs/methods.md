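# Methods

This note documents the models implemented in `rsbagging`, the defaults
chosen where the underlying method leaves a decision open, and what the
synthetic-data validation does and does not establish.

## Preprocessing

Recordings are channels × samples in microvolts. Preprocessing runs in a
fixed order: bad-channel interpolation, average re-referencing, zero-phase
band-pass filtering.

* **Bad channels** are flagged by a robust statistic: the deviation of each
  channel's log-variance from the median log-variance of its montage
  neighbours, converted to a robust z-score (median / 1.4826·MAD across
  channels), threshold 5 by default. Flagged channels are replaced by the
  mean of their good neighbours; a channel with no good neighbours is an
  error rather than a silent guess.
* **Average reference** subtracts the instantaneous across-channel mean,
  making the per-sample channel mean exactly zero (to rounding).
* **Band-pass** is a windowed-sinc FIR (Hamming window, 0.5 Hz transition
  width), applied forward–backward so the net filter is zero-phase; the
  default passband is 0.5–45 Hz. Forward–backward application doubles the
  stopband attenuation, so a 0.1 Hz drift or 50/60 Hz mains tone drops by
  well over 20 dB while 10 Hz alpha passes essentially unattenuated.
* **Artifact handling** is an epoch-level amplitude rule: after cutting
  epochs, any epoch whose peak absolute value exceeds 150 µV (configurable)
  is dropped. Continuous-rejection algorithms mark arbitrary spans and
  change downstream shapes; epoch-level rejection keeps the observation
  count well defined.
* **Epochs** are half-open sample windows `[start, start + length)` of 2 s
  by default with no overlap. 2 s gives 0.5 Hz native spectral resolution,
  enough to place the 1 Hz analysis grid while keeping hundreds of
  observations from a 10-minute recording.

## Connectivity

All nonparametric measures share a single substrate: per-epoch
Hann-tapered Fourier coefficients on the integer-Hz grid 1–45 Hz. Each
epoch is one observation; the per-observation cross-spectrum of channels
i, j is S_ij = X_i X_j*. Measures per channel pair and frequency:

* COH = |⟨S₁₂⟩|² / (⟨S₁₁⟩⟨S₂₂⟩)   (magnitude-squared coherence, [0, 1])
* PLV = |⟨S₁₂ / |S₁₂|⟩|   (resultant length of cross-spectral phases)
* PLI = |⟨sign Im S₁₂⟩|
* wPLI = |⟨Im S₁₂⟩| / ⟨|Im S₁₂|⟩
* debiased wPLI = (Σ_{j≠k} Im S₁₂⁽ʲ⁾ Im S₁₂⁽ᵏ⁾) / (Σ_{j≠k} |Im S₁₂⁽ʲ⁾||Im S₁₂⁽ᵏ⁾|)
* PPC = (|Σ e^{iθ}|² − N) / (N(N−1)), θ = arg S₁₂ per observation
* wPPC = (|ΣS₁₂|² − Σ|S₁₂|²) / ((Σ|S₁₂|)² − Σ|S₁₂|²)
* CSD feature = |⟨S₁₂⟩|
* POWCORR: per frequency, the Pearson correlation of log power envelopes
  across observations after pairwise orthogonalization
  (Y⊥X = Im(Y·conj(X)/|X|)), averaged over both orthogonalization
  directions. The envelope comes from the shared epoch-FFT coefficients
  rather than a wavelet transform — one spectral substrate for all
  nonparametric measures.

Conventions: any 0/0 (zero power, purely real cross-spectrum) evaluates to
0. Imaginary parts within 1e−12 of |S₁₂| in relative terms are treated as
exactly zero, so the zero-lag suppression property (wPLI = 0 when every
observation's cross-spectrum is real) holds under floating-point rounding.
PPC is the unbiased population statistic of squared PLV: under independent
uniform phases its expectation is 0, while PLV has the known positive bias
≈ √(π/4N) — both are verified by Monte-Carlo tests.

### Directed measures

An MVAR model y_t = Σ_k A_k y_{t−k} + e_t, e ~ N(0, Σ), is fitted by
multi-epoch least squares (moment matrices pooled across epochs; no
samples cross epoch boundaries). Order selection minimizes AIC over
1..20 on a common sample support; the fitted model must be stable
(companion spectral radius < 1) or fitting fails with advice to lower the
order. In the frequency domain, A(f) = I − Σ_k A_k e^{−2πi f k/fs},
H(f) = A(f)⁻¹, S(f) = H Σ H*. With values[i, j] = influence of source j on
target i:

* DTF_ij = |H_ij|² / Σ_m |H_im|² (rows of H sum to 1),
* PDC_ij = |A_ij|² / Σ_m |A_mj|² (columns of A sum to 1),
* GC_ij = ln( S_ii / (S_ii − (Σ_jj − Σ_ij²/Σ_ii)|H_ij|²) ), the bivariate
  spectral Granger causality with the noise-covariance correction.

GC in the feature pipeline is computed from a separate bivariate model per
channel pair, matching its two-signal derivation; DTF and PDC use one
full-channel model. Applied to a multichannel model directly, the pairwise
GC correction can numerically overshoot S_ii; the denominator is floored
at a tiny positive value and GC clipped at 0.

Per-frequency matrices are averaged over the band (default 1–45 Hz) and
vectorized to the upper triangle (i < j in montage order), 190 features
for 20 channels. Directed matrices are truncated to the same upper
triangle so every measure emits the same feature count; a
`full_directed` / `--directed-full` option emits all 380 ordered pairs
instead.

## Microstates

GFP_t is the root mean square of the average-referenced channel values at
sample t (the spatial standard deviation). Clustering operates on the maps
at local GFP maxima — the standard choice, since topographies are most
stable and best defined at GFP peaks. The modified k-means is
polarity-invariant: assignment maximizes squared spatial correlation, and
each prototype update is the first principal eigenvector of its assigned
maps' scatter matrix. Iteration stops when the relative change in global
explained variance (GEV) falls below 1e−6; 20 seeded restarts are run and
the best-GEV solution kept (the seed is mandatory, so results are exactly
reproducible). An emptied cluster is re-seeded from the currently
worst-explained map.

Backfitting labels every sample with the prototype of maximal absolute
correlation; zero-GFP samples inherit the previous label. Temporal
smoothing (merging runs shorter than a minimum duration into the
better-correlated neighbour) is available but off by default — the
segmentation model makes no smoothness claim, and smoothing biases
duration estimates.

Per-state parameters: mean GFP (µV), duration (mean stable-run length,
ms), occurrence (runs per second), coverage (sample fraction), and
GEV_k = Σ_{t∈k}(GFP_t · corr(v_t, map_k))² / Σ_t GFP_t². With these
definitions coverage = occurrence × mean duration exactly, and coverages
sum to 1. Feature vectors concatenate the 5 parameters over the k states
ordered by descending coverage, which makes vectors comparable across
subjects without cross-subject map alignment. Prototypes can be fitted
per subject (default in `microstate_features`) or supplied pre-fitted —
e.g. fitted on the concatenated peak maps of training subjects only and
backfitted to every subject, which avoids test-set leakage when
microstate features feed a classifier.

## The ensemble

Given a binary dataset with the minority class as positive, training:

1. stratified split (per class, test count = class size × test fraction
   rounded to nearest; seeded shuffle), default test fraction 0.3;
2. N balanced subsets: each keeps the full minority class and draws an
   equal number of majority samples, by default without replacement
   within a subset and independently across subsets (a with-replacement
   flag covers the alternative reading of "random under-sampling with
   replacement": replacement across subsets is always present);
3. per subset, a Gaussian-kernel SVM (C = 1, gamma = 1/(n_features·Var X))
   with Platt-calibrated probabilities; features are z-scored with
   training-set statistics only. N defaults to 11 — odd, so even
   uncalibrated hard votes cannot tie.

Prediction averages the positive-class probabilities; with threshold α,
positive if p⁺ ≥ α, negative if 1 − p⁺ ≥ α, otherwise abstain. At α = 0.5
the tie p⁺ = 0.5 resolves to the positive (minority) class, biasing toward
sensitivity; consequently no binary sample can abstain and the Predict
Rate is exactly 100 %. The Predict Rate is non-increasing in α on a fixed
ensemble and test set by construction. Evaluation excludes abstained
samples from the confusion counts but keeps them in the Predict Rate
denominator; all five metrics are percentages, F1 included.

`run_task` repeats split → subsets → train → evaluate (default 20
repeats with derived seeds) and aggregates counts and mean metrics; tasks
other than consciousness detection first exclude subjects with a disorder
of consciousness, whose EEG would confound lateralization contrasts.

## Synthetic generators

* **Oscillators**: per-segment constant phases; a coupled channel's offset
  is the configured lag plus von Mises jitter whose concentration is
  solved numerically so the *population* phase locking equals the
  requested strength (strength 1 → no jitter, 0 → uniform). One segment =
  one spectral observation downstream.
* **MVAR**: exact recursion with Gaussian innovations, 500-sample burn-in
  discarded; instability is rejected at construction. Sample lag-0/1
  autocovariances are tested against the Yule–Walker values.
* **Microstates**: run lengths are shifted-geometric (minimum run =
  (1 − jitter) × mean, geometric tail; defaults mean 80 ms, jitter 0.5,
  consistent with the 40–150 ms range reported for scalp microstates);
  the active template is amplitude-modulated by a floored, rectified
  10 Hz oscillation (creating GFP peaks), sign-flipped at random per
  segment (exercising polarity invariance), plus white sensor noise.
  Ground-truth labels are returned for recovery tests.
* **Cohorts**: the `table1` preset reproduces the study composition
  exactly — 241 subjects; 97 non-awake (somnolence 52, stupor 25, light
  coma 15, middle coma 2, deep coma 3) vs 144 awake; stroke-location
  sides 60 B / 96 L / 68 R; motor sides 56 B / 56 L / 79 R; 72 female /
  169 male — with within-state attribute pairing randomized by seed.
  Features are standard normal with each clinical attribute shifting its
  own block of 20 features; the default effect size (1.5, i.e. ~3σ
  Mahalanobis separation for lateralized contrasts before the 170
  uninformative dimensions dilute it) makes tasks learnable but not
  trivial. `gen_imbalanced_gaussians` provides the plain two-Gaussian
  benchmark; "moderate overlap" is fixed at Mahalanobis distance 2.0 in
  10 dimensions with 10:1 imbalance.

What passing tests on these generators show: the estimators implement
their definitions (oracle agreement to 1e−8, normalization identities to
1e−10), are calibrated against known population values, and the ensemble's
sensitivity advantage on imbalanced data is real and large (≈ +60 points
at the default conditions). What they do not show: performance on real
EEG, where volume conduction, non-stationarity, artifacts and
between-subject variability are far richer than these generators emulate;
clinical accuracy claims cannot be reproduced without the clinical data.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to keep Monte-Carlo
error well inside the asserted tolerances: 2000 observations for the von
Mises calibration (±0.03 band ≈ 2.3 sampling SDs), 8000 for the zero-lag
wPLI null (expected value ≈ 0.011 against the 0.05 bound), 200 replicates
× 500 observations for the bias contrast, 60 s at 250 Hz for microstate
recovery, and 20 replicates of n = 1000 for the imbalance benefit. MVAR
fits regularize the normal equations with 1e−12 on the diagonal; the AIC
comparison uses a common sample support across candidate orders. All
randomness flows from explicit seeds; identical seeds give byte-identical
feature CSVs.

## Known limitations

* GC is bivariate; conditional (multichannel) Granger causality is out of
  scope, so indirect influences can appear as direct links.
* POWCORR uses epoch-FFT envelopes, not wavelet envelopes; values are
  comparable within the package but not numerically identical to
  wavelet-based implementations.
* The microstate generator's amplitude modulation is a single rectified
  oscillation, not broadband alpha; GFP peak spacing is therefore more
  regular than in real EEG.
* Directed measures truncated to the upper triangle discard the lower
  ordered pairs; use the full-directed option when directionality itself
  is the question.
* EDF support covers standard 16-bit EDF/EDF+ via mne; proprietary vendor
  formats are not read.
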