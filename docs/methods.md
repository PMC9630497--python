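# Methods

This note documents the models, defaults, numerical choices and known
limitations behind `ramanfuse`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Spectral preprocessing

The chain is crop → despike → baseline → smooth → normalize → average,
applied per acquisition-spot spectrum; spot averaging comes last so each
spot contributes with equal weight after normalization, and the
per-patient mean is re-normalized so the spectra entering PCA share exact
unit norm.

**Cropping** keeps the fingerprint region, default 400–1800 cm⁻¹ (closed
interval); all diagnostic bands in the shipped peak table lie inside it.

**Cosmic-ray rejection.** Candidate points are those whose
first-difference robust z-score exceeds `spike_zscore_threshold`
(default 8). Two design details matter on realistic banded spectra:

- The noise scale is the 25th percentile of |d − median(d)| rescaled to a
  Gaussian σ, not the MAD. Band flanks contaminate well over a quarter of
  the |difference| distribution and inflate the MAD severalfold, which
  masks genuine spikes of 20–25× the detector noise.
- Candidate runs (at most `spike_max_width`+1 consecutive suspects,
  default width 3) must additionally stand out from a 7-point
  median-filtered trace by the same threshold. A true spike survives the
  median filter at full amplitude; a band flank is locally monotone so its
  median residual is ≈ 0. This separates narrow spikes from steep flanks
  of genuine bands with measured sensitivity/specificity of 1.0/1.0 on
  200 planted-truth spectra (acceptance suite).

The default action drops the whole flagged spectrum from analysis;
interpolation over the flagged points is available
(`spike_action="interpolate"`). A patient's mean is then taken over the
surviving spots. Spectra with a constant signal (zero scale) yield no
flags, with a warning.

**Baseline.** Asymmetric penalized least squares (a Whittaker smoother
with asymmetric reweighting): minimize Σ wᵢ(yᵢ−zᵢ)² + λ‖Δ²z‖² with
wᵢ = p where yᵢ > zᵢ and 1−p otherwise, iterated to weight convergence.
Defaults λ = 1e5, p = 0.01, 10 iterations — the standard regime for broad
fluorescence backgrounds under Raman bands at ~1.7 cm⁻¹/point sampling.
The solve uses a symmetric banded factorization (O(n) per iteration).
Conservation is exact: corrected + baseline reproduces the input
bit-for-bit. In the λ→∞ limit the baseline tends to the asymmetric
weighted straight-line fit (second differences vanish).

**Smoothing** is Savitzky–Golay, window 11 points, polynomial order 3;
polynomials up to the order are reproduced exactly and endpoints are
handled by polynomial fits on the truncated window.

**Normalization** is Euclidean (unit vector norm) by default;
area-normalization is available behind `normalization="area"`.

## Biofluid fusion

Per patient, the mean plasma spectrum (length L) and mean saliva spectrum
(length L) are concatenated — plasma first — and the axis replaced by the
integers 1..2L; with the native 847-point grid the fused axis ends at
1694. A post-fusion re-normalization switch exists but is off by
default: the stitched values are the already-processed intensities, and
because both halves are unit-norm every fused trace has norm exactly √2,
so the switch divides all fused spectra by one shared constant and cannot
change any scale-invariant downstream model (the test suite asserts the
selected classifier is identical either way). The
physical wavenumber axis is deliberately abandoned; peak reporting maps
fused indices back through the stored segment boundary. Fusing is
lossless: splitting at the boundary recovers both inputs exactly.
Preprocessing is not re-applied to fused traces by default (the inputs
are already processed); a caller can do so explicitly if desired.

## Discriminant pipeline

PCA is mean-centered SVD with a deterministic sign convention (largest
|loading| element positive). Under cross-validation the PCA projection is
refit on each training fold and applied to the held-out patients, so no
information leaks; a `global_pca` flag reproduces the fit-once variant
for comparison studies.

The candidate space is all 6 flavors × all nonempty subsets of PCs 1..K
(K = 5 default → 186 candidates). Covariances: pooled flavors normalize
by n−2, per-class flavors by n_k−1; `diag*` zeroes off-diagonals;
`pseudo*` uses the eigendecomposition pseudo-inverse and the
pseudo-determinant, so rank-deficient score clouds are handled; non-pseudo
flavors raise a descriptive error on singular covariance. Priors are
empirical by default (uniform selectable). ROC decision scores are the
posterior probability of the cancer class; AUC is the trapezoidal
integral, which equals the Mann–Whitney pair statistic (tested).

Selection minimizes total misclassifications, with deterministic
tie-breaks: fewer PCs, then flavor order linear < diaglinear <
pseudolinear < quadratic < diagquadratic < pseudoquadratic, then
lexicographic subset.

For speed, the exhaustive search computes each fold's full-K class means
and covariances once and takes submatrices per candidate — exactly
equivalent to refitting each candidate (the covariance of a coordinate
subset is the corresponding submatrix); equivalence to the naive
re-enumeration is asserted in the acceptance suite.

Evaluation schemes: resubstitution, leave-one-patient-out (the default
for cohort-scale runs) and stratified k-fold at the patient level; in
every CV scheme each patient appears in a validation fold exactly once.

## PLS-DA and VIP

Feature tables are normalized per sample to the cohort-mean total signal
(the GC-MS MTIC convention), log1p-transformed, autoscaled, and fit by
NIPALS PLS1 against the centered 0/1 class indicator, with deflation per
component; A = 2 components by default. The log transform is a deliberate
default: metabolite abundances are approximately lognormal and raw-scale
PLS is dominated by skew (switchable with `log_transform=False`). With A
equal to the design rank, PLS1 reproduces ordinary least squares
(tested). Class prediction thresholds the continuous prediction at the
midpoint of the class means.

VIP follows the standard mean-square-1 normalization; VIP is recomputed
after each elimination step in `backward_eliminate` (a frozen-ranking
mode exists). One subtlety: when evaluating a small panel, the per-sample
normalization always uses the **full** metabolite profile, with the model
fit on the panel columns. Total-signal scaling is a property of the whole
measurement; normalizing within a 5-metabolite panel would divide out
exactly the shared abundance shifts the panel is meant to detect.

Cross-validation refits normalization target, autoscaling and the PLS
model per training fold; default scheme is leave-one-out at the sample
level for the ~28-sample discovery-scale tables.

## Reference unmixing

Targets are decomposed as y ≈ Σ c_k·ref_k + baseline with c ≥ 0.
References are unit-normalized (coefficients are then comparable
contribution weights) and linearly resampled onto the target grid. The
solver alternates NNLS for c with a penalized-least-squares baseline of
the residual, starting from the asymmetric (AsLS) baseline of the raw
target. The refinement step uses the *symmetric* Whittaker smoother: once
the reference part is subtracted the residual is baseline + noise with no
one-sided excursions, and keeping the asymmetric weights there provably
diverges (the downward-biased baseline leaves a positive offset that the
non-negative coefficients absorb, which lowers the baseline further — a
positive feedback loop). Convergence is declared when the coefficient
vector changes by < 1e-6 relative to its largest entry (max 50 sweeps);
non-convergence returns the last iterate flagged. The solution matches a
dense grid search on two-reference problems within the grid step
(acceptance suite). R² is computed on the baseline-subtracted signal.

Peak assignment takes local extrema of |difference spectrum| above a
prominence threshold (default 2× the MAD-based robust noise scale of the
trace) and matches each to the nearest band in the shipped 19-row
diagnostic band table within ±6 cm⁻¹ (ties break toward lower
wavenumber); direction is the sign of the difference at the extremum.
Hierarchical clustering in top-5 PC space uses Euclidean distances with
Ward linkage by default (the linkage is an open choice; Ward is the
standard Euclidean-consistent default for compact score clouds, and other
linkages are selectable).

## Synthetic data: what it emulates, and what it does not

Per spot: intensities = fluorescence background + patient_gain ×
spot_gain × Σ_k A_k·jitter_k·(1 + δ_k·is_cancer)·V(x; c_k, w_k) + noise,
with optional 1–3-point cosmic spikes of 25–60× the noise SD. Bands are
50/50 pseudo-Voigt with widths 9–22 cm⁻¹. Informative band positions and
directions come from the shipped diagnostic band table — plasma-segment
bands (492−, 608−, 1437−, 1526−, 1639+) only in plasma, saliva-segment
bands (488−, 543+, …, 1704−) only in saliva — so the class signal is
genuinely split between the fluids and fusion has something to gain; each
fluid also carries uninformative structural bands. Backgrounds are random
smooth polynomial+hump curves ~5× the band scale. Noise is
heteroscedastic (scales with the local clean signal), with native-state
SD (0.05) twice the dried-state SD (0.025), so native spectra are
measurably noisier by construction. Patient effects: a lognormal overall
gain (σ = 0.08) and independent per-band lognormal jitter (σ = 0.15)
drawn per patient per fluid — the jitter is the irreducible
within-class variation that caps single-fluid performance. Randomness
derives from per-patient substreams keyed by (seed, patient index), so
cohorts are bit-reproducible and appending patients does not perturb
earlier ones.

**Calibration.** The informative-band effect magnitude (δ = 0.10, signed
per band) and the band jitter (0.15) were calibrated, as a design choice,
so that single-fluid cross-validated accuracy on the default 53-patient
cohort falls around the 70–85% regime typical of single-biofluid Raman
classification, with the fused cohort clearly above it. These are the
frozen study conditions for all tests.

**Fusion-synergy experiment.** The fused-vs-single comparison uses
120+70-patient cohorts with stratified 5-fold patient-level CV. The
cohort size is a power choice: at 53 patients the binomial noise of an
accuracy estimate plus the optimism noise of a best-of-186 selection give
the fused-minus-best-single margin a spread of ~0.05, which swamps the
true ~+0.03 margin; at 190 patients the margin (mean ≈ +0.03, SD ≈ 0.02)
is resolvable seed by seed. Honest caveat: even at this size the
per-cohort margin is ~1.5–2 SD above zero, so across arbitrary seed
ranges a few percent of cohorts can still show the best single fluid
matching or slightly exceeding the fused model; the synergy is an
expectation-level ordering, and the acceptance experiment verifies it on
its declared 25 seeded cohorts.

Feature tables are lognormal (per-metabolite base log-abundance
N(2, 1), within-class log-SD 0.4) with five planted fold-3 metabolites
named after the plasma diagnostic panel among 95 class-independent noise
metabolites, and per-sample total-signal jitter (uniform 0.7–1.3) so
normalization is non-trivial. Synthetic metabolite standards are sums of
fixed pseudo-Voigt bands per metabolite, unit-normalized — stand-ins
constructed for measured analytical standards, labelled synthetic in
their docstrings.

What the generator does **not** model: wavelength/intensity calibration
drift, detector etaloning or pixel response, water/substrate backgrounds,
physically derived band intensities, correlated metabolite biochemistry,
batch effects, or any instrument forward model. Passing tests therefore
demonstrate the correctness and statistical behavior of the analysis
chain under the stated generative assumptions, not clinical performance
on measured cohorts.

## Problem sizes and runtimes

Chosen as desk-scale experimental designs: 53-patient default cohorts
(847-point spectra, 5 spots) for pipeline runs; 200 spectra for despike
scoring; 50 seeds for VIP recovery; 50 permutations for each null
calibration; 25 seeded 190-patient cohorts for the fusion-synergy
experiment. The full test suite runs in ~4 minutes and
`scripts/acceptance.py` in ~3 minutes on one CPU.

## Known limitations

- The discriminant search treats the per-patient mean spectrum as the
  unit of analysis; spot-level modeling (mixed effects) is out of scope.
- `pseudo*` flavors use the pseudo-determinant, so their discriminant
  values are comparable only within a fixed rank pattern — the standard
  caveat for pseudo-inverse discriminants.
- Backward elimination recomputes VIP inside the full-table fit, not
  inside each CV fold; panel-size AUC curves therefore carry a mild
  selection optimism, as in common metabolomics practice.
- The CLI is a thin convenience layer; programmatic use through the
  library API is the primary interface.
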