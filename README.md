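# sersstroma

Stroma-focused SERS imaging-metabolomics analysis for the differential
diagnosis of ductal carcinoma in situ (DCIS) versus invasive breast cancer
(IBC).

When breast cancer invades, the stroma around it mounts a desmoplastic
reaction with a measurable redox-metabolite fingerprint: surface-enhanced
Raman spectroscopy (SERS) imaging of frozen biopsy sections shows the
polysulfide band at 480 cm⁻¹ elevated in invasive stroma and the
hypotaurine band at 974 cm⁻¹ depressed, among ~27 differential fingerprint
wavenumbers. This package implements the full computational chain that
exploits that fingerprint, for spectroscopists and computational
pathologists who want a tested, reproducible reference pipeline:

* **synthetic cohorts** — seeded tissue phantoms (cancer nests, stroma,
  adipose, normal gland) rendered into hyperspectral SERS cubes with
  Lorentzian marker bands, per-patient amplitude variation, log-normal
  hotspot heterogeneity, smooth baselines, noise and a silicon calibration
  line (real biopsies are not publicly available);
* **preprocessing** — axis calibration against the 520 cm⁻¹ silicon phonon
  line, asymmetric-least-squares baseline removal, line binning, and band
  images accumulated over ±5 / ±10 cm⁻¹ windows;
* **annotation** — tagging spectra with pathology labels, the flat
  `(x, y, tag, spectrum)` text export, and stromal ROI meshes (one mesh
  cell per binned pixel);
* **differential statistics** — per-patient mean spectra, per-channel
  Welch tests with DCIS-/IBC-dominance calls and peak collapsing, Fisher's
  exact test and logistic-regression odds ratios;
* **classification** — 27-band mesh features, patient-disjoint stratified
  splits, six algorithm families tuned by grid search maximizing Cohen's
  kappa

  κ = (p_o − p_e) / (1 − p_e),

  held-out evaluation, permutation importance, and per-patient aggregation
  of mesh votes (category = IBC iff the fraction of IBC-called meshes
  exceeds 0.5).

## Worked example

```python
from sersstroma.config import CohortConfig, PreprocessConfig
from sersstroma.pipeline import (simulate_cohort, preprocess_patient,
                                 cohort_patient_means, stroma_feature_table)
from sersstroma import (differential_peaks, train_models, evaluate,
                        patient_aggregate, stratified_split)

cohort = simulate_cohort(CohortConfig(seed=7))          # 14 DCIS + 32 IBC
processed = [(p.patient_id, p.diagnosis, *preprocess_patient(p, PreprocessConfig()))
             for p in cohort]

report = differential_peaks(cohort_patient_means(processed, "stroma"))
print(report.n_peaks, "differential peaks:", report.dominance_counts())
print(report.peaks.head(5).round(3).to_string(index=False))

feats = stroma_feature_table(processed)
plan = stratified_split(feats[["patient_id", "diagnosis"]].drop_duplicates(), 4, seed=3)
models = train_models(feats[feats.patient_id.isin(plan.training_patients)],
                      algorithms=["xgb"], seed=5)
print("XGB cross-validated kappa: %.3f" % models.models["xgb"].cv_kappa)

held = feats[feats.patient_id.isin(plan.evaluation_patients)]
agg = patient_aggregate(evaluate(models.models["xgb"], held).predictions)
print("held-out patient accuracy:", (agg.predicted_category == agg.diagnosis).mean())
```

prints

```
27 differential peaks: {'D': 19, 'I': 8}
 wavenumber       t   p dominance
      256.0   8.505 0.0         D
      334.0   7.578 0.0         D
      382.0  11.370 0.0         D
      480.0 -14.682 0.0         I
      532.0  11.611 0.0         D
XGB cross-validated kappa: 0.969
held-out patient accuracy: 1.0
```

The discovery stage recovers exactly the 27 injected marker bands with the
19 DCIS-dominant / 8 IBC-dominant split (negative t at 480 cm⁻¹ means
IBC > DCIS — the polysulfide elevation of invasive stroma); the
gradient-boosted mesh classifier reaches a cross-validated kappa of 0.97
and classifies every held-out patient correctly by mesh-vote ratio.

## Command line

The staged workflow (simulate → preprocess → annotate → diffpeaks →
features → split → train → evaluate → aggregate) also runs from a YAML
config; each subcommand resumes cached upstream stages:

```bash
sers-stroma run --config cfg.yaml            # everything
sers-stroma diffpeaks --config cfg.yaml      # up to the statistics stage
```

Exit codes: 0 ok, 2 configuration error, 3 data error.

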