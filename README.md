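# hepajac

Analysis and prediction of liver volume-change maps after external-beam
radiotherapy.

Irradiated liver tissue atrophies; spared tissue can regenerate
(hypertrophy).  Mapping *where* the liver will lose or gain volume months
after treatment would let planners trade off high focal dose against the
low-dose bath during optimisation.  `hepajac` implements the full analysis
chain for this question, for researchers in image-guided radiotherapy and
medical image analysis:

1. **Volume-change mapping.**  Pre- and post-RT livers are registered with
   a contour-driven biomechanical model: Demons registration of the liver
   and vessel masks on signed distance transforms supplies Dirichlet
   boundary conditions (liver surface + vessel centerlines) for a
   linear-elastic tetrahedral finite-element model of the pre-RT liver;
   the nodal solution is rasterized into a dense displacement field u on
   the planning grid.  The voxel-wise volume change is the Jacobian
   determinant offset by one, dv = det(I + grad u) - 1, negative where
   tissue contracts, zero outside the liver.
2. **Regional dose response.**  Planned dose is converted to EQD2 with the
   linear-quadratic model (alpha/beta = 3 Gy); mean EQD2 and mean dv are
   compared per region (Couinaud-like segments 1-4, right lobe, left
   lobe, whole liver) across a cohort via Pearson r, the linear fit
   dv% = x * EQD2 + y, and 50 Gy-stratified hypertrophy/atrophy tables.
3. **Prediction from pre-treatment data.**  A 3D U-Net (NumPy
   implementation, CPU-only) regresses the volume-change map from three
   channels -- windowed CT, EQD2/100, and a fused liver-contour/time
   channel EQD2/(100 T) -- under leave-n/k-out cross-validation
   stratified by cancer type.  Its per-case voxel-wise correlation with
   the registration-based map is compared against the dose-only baseline
   (the negated EQD2 correlation) with a paired Wilcoxon test, plus
   regional r / identity-line R^2 and hypertrophy/atrophy ROC AUC.

Patient imaging of this kind is not publicly available, so the package
ships a synthetic phantom cohort generator (`hepajac.phantom`) producing
livers with segments and vessel trees, IMRT-like plans matching the target
population's prescriptions (50-100 Gy in 10-28 fractions, follow-up
147 +- 36 d), and a *planted* spatial dose->volume-change response with
known ground-truth deformation fields -- every stage of the pipeline is
validated by recovering that planted truth.  See `docs/methods.md` for the
models and their assumptions.

## Worked example

Generate a small cohort, fit the regional dose-response, and inspect the
right lobe:

```python
import pandas as pd
from hepajac.phantom import generate_cohort
from hepajac.regional import regional_means, cohort_regression, change_distribution_table

cases = generate_cohort(30, seed=7)
rows = pd.concat(
    regional_means(c.truth_dv, c.eqd2, c.labels, c.case_id, c.t_days) for c in cases
)
fit = cohort_regression(rows, "right_lobe")
print(f"right lobe: r = {fit.pearson_r:.2f}, "
      f"slope = {fit.slope:.3f} %/Gy, intercept = {fit.intercept:.1f} %")
print(change_distribution_table(rows, "right_lobe").to_string(index=False))
```

```
right lobe: r = -0.91, slope = -0.263 %/Gy, intercept = 2.5 %
    region  dv_threshold_pct  pct_low_dose_dv_above  pct_high_dose_dv_below  n_low  n_high
right_lobe               0.0              72.222222              100.000000     18      12
right_lobe              10.0               0.000000               83.333333     18      12
```

Mean volume change in the right lobe falls by ~0.26 percentage points per
Gy EQD2 (r = -0.91 across 30 phantoms); every right lobe whose mean EQD2
exceeded 50 Gy lost volume (83 % by more than 10 %), while low-dose right
lobes often gained a little -- the qualitative pattern the analysis is
designed to expose.
Registration-based maps (instead of planted truth) come from
`hepajac.biomech.register_case` + `volume_change_from_dvf`, and the
U-Net comparison from `hepajac.predictor.run_cv` +
`hepajac.evaluate.paired_comparison`.

The same stages are scriptable from the shell:

```bash
hepajac simulate --n 20 --seed 7 --out cohort/
hepajac register --case cohort/case000 --out dvf.nii.gz
hepajac jacobian --dvf dvf.nii.gz --liver cohort/case000/labels.nii.gz --out dv.nii.gz
hepajac analyze --cohort cohort/ --out stats/
hepajac train --cohort cohort/ --epochs 35 --folds 4 --out runs/
hepajac evaluate --cohort cohort/ --pred runs/ --out eval/
```

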