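# ramanfuse

Liquid-biopsy Raman diagnostics with biofluid spectral fusion.

`ramanfuse` is a Python library for classifying disease state (cancer vs.
benign control) from Raman spectra of patient plasma and saliva, built
around a simple but effective data-augmentation idea: **stitch each
patient's mean plasma and mean saliva spectra into one fused trace before
modeling**. Each biofluid carries partly complementary chemical
information, so low-level fusion — plain concatenation on an arbitrary
integer axis — gives the downstream classifier access to both at once and
outperforms either fluid alone.

The package covers the full analysis chain for this kind of study:

- **Preprocessing** — fingerprint-region cropping, cosmic-ray rejection,
  asymmetric penalized-least-squares (Whittaker-type) baseline correction,
  Savitzky–Golay smoothing, unit (L2) normalization, and acquisition-spot
  averaging into per-patient mean spectra.
- **Fusion** — per-patient plasma⊕saliva concatenation (plasma first) on
  an integer axis 1..2L, with lossless unfusing and index→wavenumber
  mapping for peak reporting.
- **Diagnostic modeling** — PCA of the spectral matrix, then an exhaustive
  search over every combination of discriminant flavor
  (`linear`, `diaglinear`, `pseudolinear`, `quadratic`, `diagquadratic`,
  `pseudoquadratic`) and every nonempty subset of the first K principal
  components (default K=5, 186 candidates), evaluated by patient-level
  cross-validation; confusion tables, sensitivity/specificity/accuracy and
  ROC/AUC.
- **Metabolomics** — total-signal (MTIC-style) normalization of GC-MS
  feature tables, NIPALS PLS1 discriminant analysis, VIP
  (variable-importance-in-projection) scoring, and backward elimination of
  low-VIP metabolites down to compact diagnostic panels.
- **Reference unmixing** — non-negative decomposition of biofluid spectra
  into metabolite standard spectra plus a smooth baseline (alternating
  NNLS / penalized-least-squares), difference spectra, diagnostic-band
  assignment against a shipped peak table, and hierarchical clustering in
  PC space.
- **Synthetic cohorts** — a fully seeded generator of realistic
  plasma/saliva Raman cohorts (pseudo-Voigt bands on fluorescence
  backgrounds, class-dependent band intensities, patient/spot variance
  components, heteroscedastic noise, cosmic spikes) and lognormal
  metabolite tables with planted fold changes, so the whole pipeline is
  testable without measured data.

## The model in brief

A preprocessed spectrum is a unit-norm intensity vector on a common grid.
For a cohort matrix **X** (patients × wavelengths), PCA yields scores
**T** = (**X** − **x̄**)**V**ᵀ; a Gaussian discriminant on a PC subset *S*
classifies by argmax over classes *k* of

δ_k(t) = −½ log|Σ_k| − ½ (t − μ_k)ᵀ Σ_k⁻¹ (t − μ_k) + log π_k

where linear flavors pool Σ across classes, quadratic flavors estimate it
per class, `diag*` keeps only the diagonal, and `pseudo*` inverts via the
Moore–Penrose pseudoinverse. Model selection minimizes total CV
misclassifications (FP+FN) over all (flavor, subset) pairs.

For metabolite tables, PLS1 on autoscaled log-abundances against the 0/1
class label gives weights **w**_a and per-component explained response
variance SS_a, and each metabolite's importance is

VIP_j = √( p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a ),  mean(VIP²) ≡ 1.

## Worked example

`examples/02_fuse_and_classify.py` simulates a 53-patient cohort
(34 cancer / 19 control, dried state), preprocesses it, fuses the fluids,
and runs the exhaustive search for each cohort:

```
fused axis runs 1..1694 (plasma first, saliva second)

plasma: best = linear on PCs {1,2,3,4} | LOPO-CV acc 0.943 sens 0.971 spec 0.895 AUC 0.988 (186 candidates searched)
saliva: best = linear on PCs {1,2,3} | LOPO-CV acc 0.925 sens 0.971 spec 0.842 AUC 0.915 (186 candidates searched)
 fused: best = linear on PCs {1,2} | LOPO-CV acc 0.981 sens 1.000 spec 0.947 AUC 0.998 (186 candidates searched)
```

Each line reports the selected discriminant flavor and PC subset with its
leave-one-patient-out cross-validated accuracy, sensitivity, specificity
and ROC AUC. The fused model beats both single fluids because the
generator plants half of the class-informative bands only in plasma and
half only in saliva — the fusion effect the package is built around. The
other examples cover preprocessing (`01`), PLS-DA with VIP panels (`03`),
reference unmixing (`04`) and difference-spectrum band assignment (`05`).

A thin CLI mirrors the library (`ramanfuse simulate | preprocess | fuse |
classify | plsda | fit-refs | run`); exit codes are 0 success, 2 config
error, 3 data error, 4 numerical failure.

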