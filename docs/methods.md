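# Methods

## Scientific setting

Ductal carcinoma in situ (DCIS) and invasive breast cancer (IBC) differ in
whether neoplastic cells have breached the ductal basement membrane into the
surrounding stroma. Invasion triggers a desmoplastic reaction in that
stroma, and surface-enhanced Raman spectroscopy (SERS) imaging of frozen
biopsy sections shows a redox-metabolite fingerprint of it: the polysulfide
band near 480 cm⁻¹ is elevated in invasive stroma while the hypotaurine band
near 974 cm⁻¹ is depressed, with further differential bands (382, 1140,
1250 cm⁻¹ and others) distinguishing the two diagnoses. This package
re-implements the computational chain that turns hyperspectral SERS cubes
and pathology annotation masks into (a) per-wavenumber differential
statistics with DCIS-/IBC-dominance calls and (b) a mesh-level supervised
classifier whose per-patient mesh-vote ratio yields the diagnosis.

Because the patient biopsies are not publicly available, a synthetic
tissue-phantom generator provides cohorts with the statistical structure the
analysis assumes. Every downstream stage is exercised against this
generator's known ground truth.

## Synthetic cohort generator

A phantom is a region-labelled pixel grid: cancer-nest blobs biased toward
the image centre, adipose patches toward the margins, a small normal-gland
fraction, the rest stroma. Region fractions are hit exactly (up to rounding)
by quantile-thresholding smooth Gaussian random fields, which also makes the
regions blob-like and connected. Default fractions: nest 0.20, adipose 0.15,
normal 0.05, stroma 0.60.

Each pixel's raw spectrum is

```
baseline(ν) + Σ_k A_k · m_k(patient) · h(pixel) · w_k² / ((ν − c_k)² + w_k²) + ε
```

* **Bands** are Lorentzian (the typical Raman line shape) with half-width at
  half-maximum 4 cm⁻¹ — narrow enough that the closest pair of reported
  marker bands (576 and 592 cm⁻¹) remains resolvable after tail overlap.
  The mean apex amplitude `A_k` depends on (diagnosis, region) context.
* **The shipped library** injects diagnosis-dependent stroma amplitudes at
  all 27 reported marker wavenumbers (19 DCIS-dominant, 8 IBC-dominant;
  480 cm⁻¹ IBC-dominant and 382/974/1140/1250 cm⁻¹ DCIS-dominant match
  their known directions, the remaining assignments are a modelling choice),
  plus the 722 cm⁻¹ purine-nucleotide band equal in both groups as a
  negative control. Defaults: high amplitude 150, low 100, other contexts
  100 (arbitrary units — absolute SERS intensities are not meaningful, only
  relative structure is).
* **Between-patient variability**: each band carries a per-patient unit-mean
  log-normal multiplier `m_k` with coefficient of variation 0.12. The
  resulting design effect per differential band is
  (150−100)/(0.12·125) ≈ 3.3 pooled standard deviations at the
  patient-mean level, comfortably above the ≥ 2 SD detectability target
  (observed apex effects 2.5–3.4 SD after the full pipeline).
* **Hotspot heterogeneity**: a per-pixel unit-mean log-normal factor
  `h` (cv 0.25) multiplies all bands of a pixel, emulating electromagnetic
  hotspot variation of nanoparticle SERS substrates.
* **Baseline**: degree-3 polynomial in the normalized axis coordinate plus
  one broad Gaussian hump (centre 1100 cm⁻¹, σ 220 cm⁻¹); coefficients are
  jittered per patient (cv 0.10) and per pixel (cv 0.05), giving the
  baseline-removal stage something nontrivial and patient-specific to
  remove.
* **Noise** is additive Gaussian, σ = 10 (≈10% of a low-amplitude apex).
* **Calibration**: a narrow silicon phonon line (HWHM 2 cm⁻¹) at
  520 + δ cm⁻¹ accompanies each patient; a nonzero miscalibration δ shifts
  every band by the same amount.

The axis covers 250–1800 cm⁻¹ at 2 cm⁻¹ (the instrument's resolution); the
lower bound is 250 so that the lowest reported marker band (256 cm⁻¹) is
on-axis. Default images are 16×16 pixels before binning — a deliberate
scale-down of the real instrument's large tiles chosen so a 46-patient
cohort simulates in seconds; it yields ≈ 40 stromal mesh cells per patient
after binning.

RNG discipline: one master seed per cohort; `numpy.random.SeedSequence`
child streams per patient and, within a patient, per operation (layout,
baseline, amplitudes, hotspots, noise). Identical config and seed give
bit-identical cohorts.

**What the generator does not emulate:** tile seams and scanning stripes,
cosmic-ray spikes, spatially correlated noise, chemically realistic mixed
spectra at region borders, imbalanced stroma availability across patients,
and any absolute-intensity physics. Passing tests therefore demonstrate
that the pipeline's logic is correct under its stated statistical
assumptions, not that it is robust to every artefact of real instruments.

## Preprocessing

* **Calibration** locates the silicon apex by parabolic interpolation over
  the top three channels (worst-case error ≈ 0.22 cm⁻¹ for a 2 cm⁻¹-wide
  line on a 2 cm⁻¹ grid) and shifts the axis so the apex sits at exactly
  520 cm⁻¹. Re-calibrating with the same record applies a shift of ~0.
* **Binning** averages non-overlapping factor×1 line bins along the scan
  axis (default factor 4). The mean convention keeps intensities comparable
  across factors; trailing rows not filling a bin are cropped with a
  warning. Annotation masks are binned with the same geometry by majority
  vote (ties to the smallest label code).
* **Baseline removal** is asymmetric least squares on a Whittaker smoother:
  minimise Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)² with wᵢ = p for points above the fit
  and 1−p below, iterated to weight stability. Defaults λ = 30, p = 10⁻⁴
  were chosen against the generator-truth contract: a pure noiseless
  baseline is removed to < 1% of its range, a noiseless band apex is
  preserved within 5%, and the median apex error over the marker bands at
  default noise is < 10%. The very small p matters for a subtle reason:
  with p ~ 10⁻² the upward pull that band area exerts on the fit is
  proportional to total band amplitude, which differs between diagnoses
  (DCIS stroma carries 19 high bands, IBC 8), so the baseline error itself
  becomes a group difference smeared across the spectrum. At p = 10⁻⁴ this
  pull is negligible. An alternative "clip" scheme (Whittaker smoothing
  with iterative peak clipping, whose pull saturates independently of band
  amplitude) is available but not default because the clipped plateaus bias
  noisy apex recovery. The asymmetric fit sits slightly below the noise
  mean; this offset is common to all spectra and cancels in every
  between-group comparison.
* **Band accumulation** sums channels whose centres lie in the closed
  interval [c−h, c+h]: ±5 cm⁻¹ for imaging, ±10 cm⁻¹ for features and
  statistics. Summation (not averaging) was chosen; with a fixed grid the
  two differ only by a constant factor. Halfwidth 0 degenerates to the
  nearest-channel slice. Band accumulation is linear and commutes with
  binning.

The processing order is calibrate → bin → baseline-subtract; binning first
reduces per-spectrum noise (helping the baseline fit) and cuts the number of
fits 4-fold. Baselines are smooth, so binning does not change what is being
removed.

## Differential-wavenumber discovery

Tagged spectra are averaged per patient over a chosen annotation class
(default: the stroma labels), then each wavenumber channel is tested DCIS vs
IBC with Welch's unequal-variance t-test (Satterthwaite degrees of freedom)
— the appropriate choice for the unbalanced 14 vs 32 groups. Significance
is the raw per-channel p < α (default 0.05) with no multiple-testing
correction, matching how the reference analysis reports per-wavenumber
significance; Benjamini–Hochberg is available as an option. Zero variance
in both groups with equal means yields p = 1 by convention.

Detected peaks are extracted from the channel-level results as follows:

1. Significant channels form runs; runs separated by gaps < 20 cm⁻¹ are
   merged. Lorentzian tails carry genuine low-grade significance well
   beyond a band, so flickering tail segments are folded into their parent
   band's run rather than standing alone.
2. Runs with fewer than 3 significant channels are discarded: at 2 cm⁻¹
   sampling a real band with ≥ 8 cm⁻¹ full width cannot light up an
   isolated channel.
3. Within each merged run, peak centres are the local maxima of the
   absolute group-mean-difference profile, at least 10 cm⁻¹ apart and with
   prominence ≥ 10% of the run's maximum. The difference profile is used
   for localization instead of |t| because the t statistic saturates
   wherever band-amplitude variability dominates: both the effect and its
   standard error scale with the same Lorentzian tail, leaving |t|
   plateau-shaped across a band while the mean difference stays sharply
   peaked at the centre.
4. An apex must carry a standardized group difference of ≥ 1.5 pooled
   standard deviations (three-quarters of the 2-SD design target). This
   floor separates band-scale signal from the sub-SD structure that
   cumulative same-sign tails and residual baseline error leave between
   and beyond band clusters; a true 2-SD band still clears it with ≈ 90%
   probability, and the shipped ≥ 2.5-SD bands essentially always do.

Dominance is "D" (DCIS > IBC) or "I" (IBC > DCIS) by the sign of the mean
difference at the apex.

The clinical statistics layer provides Fisher's exact test (two-sided
hypergeometric p with the conditional maximum-likelihood odds ratio;
degenerate margins give p = 1 and an undefined OR) and logistic-regression
odds ratios per unit band intensity with Wald 95% intervals, univariable or
covariate-adjusted; perfect separation and collinear covariates are
detected and rejected with advice to penalise.

## Classification and patient aggregation

Mesh cells are single binned stroma pixels; features are the ±10 cm⁻¹ band
accumulations at the 27 marker wavenumbers. Patients are stratified by
class, shuffled and dealt round-robin into 4 patient-disjoint sets whose
class counts differ by at most one (the study's 46 patients do not divide
into four sets of ten, so all patients are placed in four near-equal sets;
the last set is the evaluation set). Folds for the 3-fold cross-validation
are likewise patient-disjoint and class-stratified; folding at mesh level
would leak patient identity between train and test.

Six families are tuned by grid search maximizing mean test-fold Cohen's
kappa: L1-regularized logistic regression, RBF support-vector machine,
random forest, gradient-boosted trees, k-nearest neighbours and Gaussian
naive Bayes. Scale-sensitive families (L1, SVM, KNN) are standardized
inside their pipelines. The shipped grids are small published-default
values (e.g. C ∈ {0.1, 1, 10}; tree depth ∈ {3, 6}); on separable synthetic
data any grid point lands in the same performance regime. Class-weighted
training is intentionally not enabled by default: the reference analysis
trained on the imbalanced mesh counts directly.

Cohen's kappa is (p_o − p_e)/(1 − p_e) with expected agreement from the
marginal products; degenerate marginals (p_e = 1) define kappa = 0 with a
warning. Evaluation refuses any table containing training patients (a hard
error, not a convention) and reports kappa, accuracy and class-support-
weighted F1/precision/recall plus the confusion matrix in (IBC, DCIS)
order. Permutation importance is the mean kappa drop over column
permutations, clipped at zero and normalized to unit sum.

Patient aggregation counts each patient's mesh votes; the IBC ratio is
reported at 3 decimals, and the category is IBC iff the *unrounded* ratio
exceeds 0.5. On the shipped default cohort the held-out patients are all
classified correctly with every per-patient mesh accuracy at 100%.

## Numerical and degenerate-input choices

* Grid coordinates are 0-based, row-major, pixel centres; masks share the
  binned grid.
* The tagged-text export rounds to 6 significant digits; round trips are
  lossless at that precision. Malformed rows fail with their line number.
* Baseline iteration caps at 50 sweeps; non-convergence warns and returns
  the best fit. Zero spectra pass through unchanged.
* The silicon apex estimate falls back to the argmax channel when the
  maximum sits on an axis edge; a flat (sub-SNR) silicon spectrum is a hard
  error.
* HDF5 cube containers disable object timestamps so identical configs
  produce hash-identical output trees.

## Problem sizes

Shipped defaults run a full 46-patient cohort (simulate → preprocess →
per-patient statistics) in roughly 4 s on one core; the 20-seed
differential-recovery study takes ~90 s and the six-family training on
~1800 meshes a few seconds. These sizes were chosen to make the complete
statistical argument reproducible interactively; all of them scale up
linearly through the configuration.

## Known limitations

* The baseline model and its removal are mutually consistent by
  construction; a vendor instrument's background ("weighted mean fitting"
  of the original acquisition software) is not reconstructible and is not
  claimed to be reproduced — the contract is truth recovery on synthetic
  cubes.
* Dominance assignments for the unattributed marker bands are arbitrary
  (only the 19/8 split and the five attributed directions are anchored).
* The detector's 1.5-SD apex floor trades a small power loss at exactly
  2-SD effects for robustness against tail structure; cohorts with much
  weaker injected effects should lower `min_effect` and expect extra
  tail/noise peaks at α = 0.05.
* Patient-level aggregation assumes every patient contributes at least one
  stromal mesh; patients without stroma annotations are excluded upstream
  with a warning.
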