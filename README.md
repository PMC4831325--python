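# mrgfr

Glomerular filtration rate (GFR) from renal dynamic contrast-enhanced
(DCE) MRI, using a subject-specific two-compartment tracer-kinetic model.

DCE-MRI can measure renal function without ionizing radiation: a
gadolinium tracer is freely filtered at the glomerulus, so the rate at
which it accumulates in the renal parenchyma is proportional to GFR.
Published two-compartment (2C) uptake models, however, typically assume a
fixed uptake interval (90 s or 110 s) and a fixed literature hematocrit
(41%) for every subject — yet uptake intervals vary between roughly 64
and 141 s and hematocrit between 30% and 49% across real cohorts, and
both enter the GFR estimate directly. `mrgfr` implements a pipeline for
researchers cross-calibrating MR-based GFR against reference clearance
methods in which both quantities are subject-specific:

1. aortic and renal signal curves are converted to enhancement curves and
   the aortic curve to plasma concentration via the subject's hematocrit,
   `C_p = ΔS / (1 − Hct)`;
2. a two-gamma-variate arterial input function (AIF) is fitted to the
   aortic plasma curve (first pass + recirculation);
3. the end-of-uptake point is selected automatically on the smoothed
   renal curve, subject by subject;
4. a 2C uptake model with arterial delay and glomerular dispersion,

       C_k(t) = v_p P(t) + (GFR_V/60) ∫₀ᵗ P(τ) dτ,
       dP/dt = (Ao_p(t−δ) − P)/t_disp,

   is fitted from the postaortic rise to the end-of-uptake point by
   Levenberg–Marquardt least squares, and GFR_V (min⁻¹) is converted to
   whole-kidney GFR (mL/min) by the renal parenchymal volume.

Fixed-interval (90 s / 110 s) and 2C inflow–outflow variants, fixed-vs-
subject hematocrit modes, linear-regression and Bland–Altman agreement
statistics, and a seeded synthetic cohort simulator (no patient data is
required anywhere) complete the package. See `docs/methods.md` for the
model details and simulator design.

## Worked example

```python
import numpy as np
from mrgfr import (CohortConfig, simulate_cohort, estimate_subject_gfr,
                   summarize_cohort, format_summary)

# a 29-subject synthetic cohort on the study acquisition grid
# (dt = 1.7 s, 135 time points, 10 precontrast), 2% curve noise
cohort = simulate_cohort(CohortConfig(seed=20160413))

subject = cohort[0]
fit = estimate_subject_gfr(subject, method="ss", hct_mode="subject")
print(f"true GFR {subject.ground_truth.true_gfr_ml_min:.1f} mL/min, "
      f"estimated {fit.gfr_ml_min:.1f} mL/min (R^2 = {fit.r_squared:.3f})")

results = [estimate_subject_gfr(r, m, "subject")
           for r in cohort for m in ("ss", "fixed90", "fixed110")]
ref = [r.reference_gfr for r in cohort]
print(format_summary(summarize_cohort(results, ref), ref))
```

Output:

```
true GFR 119.2 mL/min, estimated 112.4 mL/min (R^2 = 0.996)
GFR method comparison (mL/min)
================================================================
             reference: range   41.8- 159.7  mean   96.4 +/-  24.3
    fixed110/subject  : range   44.5- 154.8  mean   96.0 +/-  25.3  R2 0.944  bias   -0.4 [ -12.4,   11.6]
     fixed90/subject  : range   44.9- 151.8  mean   96.1 +/-  24.9  R2 0.940  bias   -0.3 [ -12.5,   11.9]
          ss/subject  : range   44.9- 154.0  mean   96.2 +/-  24.8  R2 0.947  bias   -0.2 [ -11.6,   11.2]
```

The per-subject line compares the pipeline's estimate with the
generating truth (R² here is the goodness of the kidney-model fit). Each
summary row gives one model's GFR range and mean ± SD, its regression R²
against the reference values, and the Bland–Altman mean bias with ±2 SD
limits of agreement; the subject-specific (ss) model correlates best.

## Command-line interface

    mrgfr simulate --n 29 --seed 20160413 --out cohort/
    mrgfr detect   --cohort cohort/ --out detections.csv
    mrgfr fit      --cohort cohort/ --method ss --hct-mode subject --out results.csv
    mrgfr compare  --cohort cohort/ --results results.csv --out summary.csv

All files are plain CSV (curves as `time_s,aorta_signal,kidney_signal`;
hematocrit stored as a fraction); every output table carries the seed
and a configuration hash. A YAML config (`--config`) exposes detection
thresholds, fitting settings and cohort distributions.

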