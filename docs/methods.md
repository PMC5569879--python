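# Methods

This note documents the models and procedures implemented in `mibci`, the
assumptions behind them, the parameters that matter, and the numerical
choices made where the design was genuinely open.

## Problem setting

Four imagined motor states — resting (R), right foot (RF), left hand (LH)
and right shoulder (RS) — are decoded from a 14-channel EEG montage plus one
vertical-EOG (VEOG) channel sampled at 256 Hz. Six electrodes sit over each
hemisphere in mirror-symmetric pairs (T7/T8, P3/P4, P7/P8, CP3/CP4, FC3/FC4,
C3/C4) and two on the midline (FZ, CZ). Trials last 9 s; the imagery period
runs from t = 2 s to t = 7 s, which is the default epoch window (the window
is configurable, half-open `[start, end)` in 0-based samples). The default
experiment size is 60 trials per state per subject, split 50 train / 10
test, with five subjects so that generic learning has a donor pool.

## Temporal filtering

A second-order IIR notch (50 Hz, Q = 30) and an order-4 Butterworth
band-pass (8–30 Hz) are applied forward–backward (zero-phase) to the
continuous record before epoching, so filter transients fall outside the
trial windows and event-related desynchronization timing is not shifted.
The band isolates the mu (≈10 Hz) and beta (≈22 Hz) rhythms carrying
motor-imagery information. A per-epoch filtering path exists for data that
arrive already epoched.

## wCCA artifact removal

Blinks produce large low-frequency potentials that conduct over the whole
scalp and dominate the VEOG sensor. The remover builds two blocks per
trial,

    X = [x1 … x6, z]ᵀ   (left-hemisphere channels + VEOG)
    Y = [y1 … y6, z]ᵀ   (right-hemisphere channels + VEOG),

centers each row, and fits canonical correlation analysis between them:
direction pairs (aᵢ, bᵢ) maximize corr(aᵢᵀX, bᵢᵀY) subject to unit-variance
constraints aᵢᵀCxx aᵢ = bᵢᵀCyy bᵢ = 1. Because the VEOG row is shared by
both blocks, the first canonical pair (u₁, v₁) locks onto the ocular
component (ρ₁ ≈ 1 by construction). Only u₁ and v₁ are denoised; the other
six pairs pass through untouched. The cleaned blocks are rebuilt through
the inverse of the canonical bases, X̂new = (Aᵀ)⁻¹Unew, and the row means
are restored. Since (Aᵀ)⁻¹ = Cxx A under the unit-variance constraint, the
per-channel correction is proportional to each channel's covariance with
VEOG — a data-driven regression of the blink out of every channel at once.

Denoising of u₁/v₁ uses a five-level db4 wavelet decomposition (symmetric
boundary extension; any signal length ≥ 2^levels is supported) with the
VisuShrink universal threshold per subband,

    k_j = sqrt(2 ln N_j) · median(|D_j|) / 0.6745 .

The default rule zeroes coefficients **above** k_j and keeps the small
ones. This is the inverse of classic hard thresholding and is deliberate:
the large coefficients are the blink transients and the small ones the
high-frequency EEG content worth keeping. Classic hard and soft rules are
available by configuration (`WaveletSpec.threshold_rule`), as is a literal
signed-median noise estimate (`mad="signed"`) instead of the standard
median-absolute-value estimator. All five detail subbands plus the
approximation are thresholded by default, because the approximation carries
the low-frequency blink energy. The midline channels FZ and CZ have no
mirror partner; they are cleaned independently with plain soft-threshold
wavelet denoising of the same basis/depth.

Numerical choices: each block's covariance is inverted through a symmetric
inverse square root; a block whose covariance eigenvalue ratio falls below
1e-12 raises a degenerate-covariance error naming the block. The CCA sign
indeterminacy is fixed by flipping each pair (aᵢ, bᵢ) together so that
cov(uᵢ, x̂₁) ≥ 0, with a largest-|weight| fallback when that covariance is
numerically zero — only one block's convention can be pinned because the
pair must flip jointly to keep ρᵢ ≥ 0.

The VEOG rows of the reconstructed blocks are discarded; only the six EEG
rows of each block are written back into the trial.

## R-CSP feature extraction with generic learning

Each trial E (N × T) is summarized by its trace-normalized covariance
S = EEᵀ/tr(EEᵀ). For a class c the subject's M training covariances are
summed into S_c, and the other subjects' training trials (never their test
trials, and never raw concatenated signals) are pooled per class into Ŝ_c
with count M̂ (M̂ = M·(L−1) when all L subjects have equal counts). Two
shrinkage levels produce the regularized class covariance:

    Σ̂_c(β)    = ((1−β) S_c + β Ŝ_c) / ((1−β) M + β M̂)
    Σ̂_c(β,γ)  = (1−γ) Σ̂_c(β) + (γ/N) tr(Σ̂_c(β)) I      (N × N identity)

β pulls toward the inter-subject generic covariance, γ toward a scaled
identity; the γ step preserves the trace. β = γ = 0 recovers classical CSP
exactly, which is the oracle check in the test suite (a direct generalized
eigenproblem solve).

Per unordered class pair, the composite Σ̂₁+Σ̂₂ is eigendecomposed with
eigenvalues sorted descending, whitened by P̂ = Λ̂^(−1/2)Ûᵀ, the whitened Σ̃₁
eigendecomposed (descending) into B̂Λ̂₁B̂ᵀ, and the full projection
Ŵ₀ = B̂ᵀP̂ formed. The first and last α rows of Ŵ₀ (α = 2 by default,
Q = 2α) are kept; the projection Ẑ = ŴᵀE yields Q rows whose normalized
log-variances are the features:

    ŷ_q = log( var(ẑ_q) / Σ_q var(ẑ_q) ) .

Four classes give six pairwise banks in the fixed order
(R,RF), (R,LH), (R,RS), (RF,LH), (RF,RS), (LH,RS), hence 6·Q = 24 features
per trial; the order is part of the serialization contract. Eigenvector
signs are fixed by making each vector's largest-magnitude entry positive,
and exact eigenvalue ties (e.g. Σ₁ = Σ₂, all whitened eigenvalues 0.5) are
resolved by the stable descending sort. Because var(wᵀE) = wᵀCov(E)w, the
grid search computes features from precomputed N × N channel covariances —
algebraically identical to projecting the raw trial, but orders of
magnitude faster.

### β/γ selection

The (β, γ) grid `[0 : 0.1 : 1]²` (121 cells) is scored exhaustively; ties
break toward smaller β, then smaller γ. The default scoring protocol is
stratified 5-fold cross-validation **within the training split**, because
selecting on the held-out test set leaks evaluation data into model choice;
a `mode="paper"` flag scores on the held-out split instead for
comparability with studies that selected that way. A failed cell (e.g.
β = 1 with an empty generic pool, which makes the covariance denominator
degenerate) records accuracy 0 with a logged warning rather than aborting
the grid.

## Hybrid KNN-SVM classifier

Stage 1 computes cosine distances 1 − uᵀv/(‖u‖‖v‖) from the query to all
stored training features and takes the K nearest (K = 5 by default; K is
not dictated by the method and is exposed in configuration). Each class
represented in the neighborhood is weighted by its summed cosine
similarity (a count-based weighting is available — the weighting scheme is
a design choice, not part of the method's definition). The two
largest-weight classes form the shortlist; ties break by weight, then by
canonical class order (R, RF, LH, RS). If a single class holds the whole
neighborhood the sample is classified directly; otherwise the one-against-
one SVM trained on exactly those two classes' training trials decides.

Pair classifiers default to an RBF kernel with C = 1 and
inverse-feature-variance bandwidth; a linear kernel is available. Features
are standardized per dimension with statistics from the training split
only, before both the KNN and SVM stages (whether to standardize is not
fixed by the method; it is the package's choice and configurable —
`preprocess` also offers L2 normalization, under which the whole decision
is invariant to positive scaling of the query, and `none`). KNN-only and
SVM-only (majority vote over all six pair classifiers, ties to canonical
order) decisions are readable from the same fitted model for baseline
comparisons.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
the biophysics of a head model:

* **Background:** 1/f-shaped Gaussian noise (flat below 1 Hz), default
  standard deviation 10 µV per channel — the amplitude scale of ongoing
  EEG.
* **Class signal:** on each class's active channels, amplitude-modulated
  10 Hz + 22 Hz sinusoids with random phases, restricted to the 2–7 s
  imagery window, with 0.25 s raised-cosine onset/offset ramps and a slow
  (0.4 Hz) amplitude modulation. The oscillation amplitude is calibrated
  against the measured background 8–30 Hz band power (Welch estimate on
  low-blink channels) so that active channels exceed inactive ones by the
  configured power factor (default gain 3.0 — a clearly separated regime
  chosen to validate recovery, stronger than typical event-related
  desynchronization in real recordings). Default patterns assign each
  class a distinct two-channel set (R: C3/CP3, RF: C4/CP4, LH: FC4/P4,
  RS: FC3/P3).
* **Blinks:** raised-cosine pulses (width 0.4 s, amplitude 200 µV) at
  Poisson onsets (0.25/s), shared across the scalp through a front-to-back
  attenuation profile peaking at FZ (0.70) and FC3/FC4 (0.60) and falling
  to 0.05 at the temporal/posterior sites. VEOG records the pulse train
  plus 2 µV sensor noise. The raised cosine is band-limited below 8 Hz, so
  band-pass filtering alone removes most but not all of it — preserving
  the premise that time-domain filtering is insufficient and artifact
  removal is needed.
* An optional 50 Hz sinusoid exists solely for notch-filter tests; no
  muscle artifacts, no volume-conduction leadfield, no left-hander
  asymmetry.

Determinism: one seed fans out per subject through `SeedSequence` spawn
keys; identical configuration + seed reproduces every sample bit-for-bit.

What passing tests on this generator do **not** show: performance on real
EEG, where class patterns overlap spatially, covariances drift within a
session, artifacts are more diverse (saccades, EMG, electrode pops) and
inter-subject transfer is weaker. The generator's inter-subject
variability is sampling noise only, which makes generic learning close to
ideally matched; on real data the β that helps is an empirical question —
hence the grid search.

## Problem sizes used in the checks

The packaged checks run the full study-scale condition — 5 subjects,
60 trials per state (50 train / 10 test), 9 s trials at 256 Hz — for the
end-to-end recovery check, repeated over 10 generator seeds (and 10 seeds
of a chance-level control with identical class patterns, pooled to 400
test trials). Solver contracts (CCA, CSP, whitening, wavelet round trips)
use small random problems where the identities must hold to near machine
precision; the grid-search cell count is exercised on a reduced
four-class dataset so the 121-cell sweep completes in seconds. The
acceptance script mirrors these conditions with 3 end-to-end seeds per
arm.

## Known limitations

* The wCCA inverse reconstruction assumes invertible canonical bases; a
  condition number above 1e10 aborts with an explicit error rather than
  producing a silently distorted trial.
* The suppress-above thresholding rule removes *large* coefficients
  wherever they occur; on artifact-free trials whose first canonical pair
  contains genuine high-amplitude EEG bursts, some signal energy can be
  removed (measured in tests as > 0.95 retained correlation on blink-free
  synthetic data).
* Cosine-distance KNN is undefined for an exactly zero feature vector;
  this cannot occur for log-variance features (which are finite and
  nonzero by construction) but is guarded with an explicit error.
* Trials shorter than 2^levels samples cannot be wavelet-decomposed at the
  default depth; the error message says so rather than silently reducing
  the depth.
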