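# pvskit

Automated perivascular-space (PVS) analysis for T1-weighted 3D brain
volumes, for researchers studying the glymphatic system, small-vessel
disease and dementia.  PVS appear as thin, dark, tubular structures on
T1w MRI; their volume fraction in the centrum semiovale (CSO) and basal
ganglia (BG) is an imaging marker of impaired waste clearance.  The
package covers the full chain:

1. **Segmentation** — non-local-means denoising with Rician noise as
   the reference level, multiscale Frangi vesselness
   `V = (1 - e^{-R_A^2/2\alpha^2}) e^{-R_B^2/2\beta^2} (1 - e^{-S^2/2c^2})`
   over Hessian eigenvalues `|λ1| ≤ |λ2| ≤ |λ3|` (dark-tube condition
   `λ2, λ3 > 0`), and thresholding to a binary PVS mask.
2. **Quantification** — per-ROI PVS volume fraction
   `pvsvf = |PVS ∩ ROI| / |ROI|` with a single-pass 1.5×IQR outlier
   fence (type-7 quantiles).
3. **Modelling** — Gamma GLMs with log link,
   `log E[pvsvf] = b0 + b1·marker + covariates` and interaction forms
   `... + b1·cortisol + b2·marker + b3·(cortisol×marker) + ...`
   (likewise for ACE), with median-centered predictors, z-scaled BMI,
   Wald inference, model-fitted interaction curves with 95% bands, and
   deviance-residual diagnostics.
4. **Synthetic ground truth** — capsule-tube phantoms with exact truth
   masks and simulated cohorts with known Gamma-GLM structure, so the
   whole pipeline is testable without restricted clinical data.

## Worked example

Simulate a cohort of 465 subjects whose CSO PVS volume fraction carries
a negative cortisol×TNF-a interaction, then fit the interaction model
(outliers removed by the IQR fence first):

```python
import numpy as np
from pvskit import CohortSpec, ModelSpec, simulate_cohort, run_model_suite

cohort = simulate_cohort(CohortSpec(n_subjects=465, seed=1))
spec = ModelSpec(outcome="pvsvf_cso", form="cortisol_interaction",
                 biomarker="tnf_a", standardize=True)
table = run_model_suite(cohort, [spec], outlier_k=1.5)
print(table[["term", "std_beta", "se", "p"]].round(4).to_string(index=False))
```

```
              term  std_beta     se      p
         intercept    0.0181 0.0413 0.0000
          cortisol    1.0715 0.0267 0.0096
             tnf_a    0.9787 0.0259 0.4067
    cortisol:tnf_a    0.9049 0.0293 0.0006
          sex_male    1.0771 0.0527 0.1588
               age    1.1933 0.0258 0.0000
             bmi_z    1.0468 0.0258 0.0760
hippocampal_volume    1.0703 0.0260 0.0090
```

`std_beta` is the exponentiated coefficient: the multiplicative change
in mean PVS volume fraction per SD of the predictor.  Here the
intercept says the reference subject's expected CSO fraction is ~1.8%
(435 subjects remain after the outlier fence); the interaction
`0.905 (p = 0.0006)` recovers the generating value 0.93 within its
standard error — higher TNF-a makes the cortisol–PVS association more
negative; and age is the dominant covariate (×1.19 per SD), as
expected for PVS burden.

Segmentation on a synthetic phantom from the shell:

```bash
pvskit simulate-phantom --seed 3 --out phantom/
pvskit segment phantom/phantom.nii.gz --out seg/
pvskit quantify seg/pvs_mask.nii.gz phantom/roi_labels.nii.gz phantom/roi_table.csv
pvskit phantom-eval --seed 1 --n-phantoms 20   # Dice / recovery report
```

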