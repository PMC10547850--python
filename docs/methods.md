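# Methods

`hepajac` re-implements, end to end, a liver radiotherapy volume-response
analysis: voxel-wise volume-change (Jacobian) maps are derived from pre-
and post-treatment images by contour-driven biomechanical registration,
related regionally to the planned dose, and predicted from pre-treatment
data alone by a 3D U-Net.  Because the patient data such analyses are run
on is not public, the package ships a first-class synthetic phantom cohort
with a planted, recoverable ground-truth response; every claim the test
suite makes is a claim about recovering that known truth.

## Dose model

Planned physical dose D delivered in n fractions is converted voxel-wise
to the equivalent dose in 2 Gy fractions with the linear-quadratic model
at alpha/beta = 3 Gy for liver.  Two conversions are shipped.  The
`standard` mode is the conventional EQD2 = D (d + a/b)/(2 + a/b) with
per-voxel fraction dose d = D/n, which maps a 2 Gy/fraction schedule to
itself.  The `as_printed` mode evaluates D (1 + D/(n a/b)), which is the
biologically effective dose (BED); it exceeds the standard EQD2 by the
constant factor 1 + 2/(a/b) = 5/3.  Both appear in the field's reporting
practice, and because the factor is constant all correlations and
stratified frequencies are identical under either; regression slopes and
the 50 Gy stratification threshold simply live on the chosen scale.  The
default is `as_printed`; the mode is explicit everywhere.

## Biomechanical registration

Longitudinal liver CTs cannot be registered on intensities (contrast
phase, tumour response and acquisition protocol all change), so the
pipeline is driven entirely by organ masks:

1. **Rigid alignment** of the liver masks by centroid + principal axes,
   with the four proper-rotation sign choices disambiguated by overlap.
   Synthetic cases are generated in the planning frame, so this stage is
   a near-identity safety net rather than a workhorse.
2. **Demons registration** run separately on the liver and vessel masks,
   with forces computed on signed distance transforms (binary masks have
   no usable gradient; the SDT carries surface geometry into the volume).
   Symmetric forces, Gaussian fluid and diffusion regularisation
   (2 mm each), a step cap of 2-3 mm, and a Dice stopping rule (0.98 for
   liver, 0.90 for the thin vessel tree).  Non-convergence is flagged on
   the result, never silent.  Vessels are registered on a cropped
   bounding box; the field is only ever sampled near the tree.
3. **Tetrahedral model**: the smoothed liver mask is sampled on a cubic
   lattice (7 mm edge) and each occupied cube split into five conforming
   tets (mirrored decomposition by parity).  The structured construction
   guarantees positive volumes, makes mesh volume track mask volume, and
   gives O(1) point location for rasterization.
4. **Boundary conditions**: every surface node takes the liver Demons
   displacement at its position; interior nodes within 12 mm
   (~1.7 mesh edges) of the skeletonized vessel centerline take the
   vessel Demons displacement.  The operation-level default capture
   radius (2 mm) is far below the FE node spacing and captures almost no
   nodes; the pipeline default is therefore tied to the mesh edge so the
   vessel tree actually constrains the interior.  Surface wins conflicts.
5. **Linear-elastic solve** with linear tets and pure Dirichlet data;
   constrained nodes are exact, free nodes solve the reduced SPD system
   (direct sparse solve, relative residual verified <= 1e-8).  Under pure
   Dirichlet conditions the solution is provably independent of Young's
   modulus.  The pipeline uses a *low* Poisson ratio (0.1): the quantity
   of interest is distributed volumetric strain, which a
   near-incompressible model (nu -> 0.5) suppresses between constraints.
   Measured on planted fields, nu = 0.45 recovers roughly half the
   regional volume change that nu = 0.1 does; nu stays in the config.
6. **Rasterization** by barycentric interpolation inside the mesh, zero
   outside.  The volume-change map is then |J| - 1 with J measured by
   central differences; the determinant is evaluated only where its
   stencil is fully inside the mesh support and nearest-filled into the
   staircase boundary band (filling the *scalar* |J| preserves its
   magnitude; extending the displacement field itself flattens gradients
   and corrupts the band).  The map is zero outside the liver by
   convention, and folding voxels (|J| <= 0) are counted, not clamped.

On phantoms with a planted -30 % / +10 % lobar response (96^3 grid,
2-2.5 mm voxels), this stack recovers per-region mean volume change to a
few percentage points (cohort mean), voxel-wise r ~ 0.75-0.80 against the
planted map, and integrates to the warped liver volume within ~1.5 %.
The residual magnitude under-estimation is inherent to contour-driven
registration: distance-transform forces constrain only the motion
component normal to surfaces and tubes (the aperture problem), so some
interior redistribution is invisible to the data the method uses.

## Synthetic cohort

Each phantom case comprises: a perturbed-superellipsoid liver (15-35 % of
the field of view; ~1-2 L at default spacing) partitioned through a hilum
point into a caudate-like segment 1, left-lobe segments 2-4 and the
merged right lobe; a two-trunk recursive vessel tree rasterized inside
the liver (never thinner than one voxel, or coarse lattices lose the
branches); CT-like intensities (liver ~90 +- 10 HU, vessels ~140 HU,
background ~-50 HU with smooth texture); an IMRT-like plan with an
ellipsoidal focus sized to the target region, Gaussian falloff
(sigma 18 mm) and a 5-15 Gy corridor bath, never exceeding 1.1x the
prescription; and plan metadata drawn from the study population the
pipeline targets (cancer types 25/64/11 % HCC/CC/CRC, prescriptions
50-100 Gy in 10-28 fractions from the empirical table, follow-up gap
N(147, 36) d truncated to [79, 257] d).

The planted voxel response combines, per case with log-normal sensitivity
s_i (sigma 0.3) and time modulation (T/147)^0.5:

* a *saturating* dose response: atrophy approaches `max_atrophy` = 0.45
  instead of growing linearly (slope 0.005 /Gy at the origin);
* *vascular sparing*: atrophy attenuated up to 50 % within 15 mm of the
  vessel tree, and compensatory hypertrophy enhanced there;
* *compensatory hypertrophy*: below ~50 Gy (smooth logistic gate), gain
  proportional to the liver fraction receiving > 50 Gy, so regeneration
  scales with the atrophied volume;
* *subcapsular vulnerability*: atrophy enhanced up to 60 % within 12 mm
  of the capsule;
* *baseline remodeling*: a small (amplitude 0.08), zero-mean,
  dose-independent pattern (perivascular regeneration against
  subcapsular thinning);
* smooth spatial noise (sd 0.06) and clipping to [-0.6, +0.4].

The anatomy-coupled terms exist because of what the analysis must
demonstrate: if the response were any monotone function of dose alone,
the dose map itself would be a near-perfect voxel-wise predictor (we
measure r ~ 0.95-0.97) and no image-based model could beat it.  The
sparing/capsule/remodeling terms are predictable from the pre-treatment
channels but invisible to a linear dose baseline -- the premise of the
prediction study.  Switches recover the plain linear dose response
(`max_atrophy=inf`, zeros elsewhere), which is the configuration the
slope-recovery experiments use.

**Ground-truth deformation.**  A displacement field whose Jacobian equals
1 + g is constructed as the gradient of a potential solving
div grad phi = log(1 + g) with a zero-displacement far boundary.  The
discrete solve uses the *wide* (2h) central-difference Laplacian so that
the centrally differenced divergence of the constructed field reproduces
log(1+g) exactly in the interior (the stencil's near-null modes are
projected out; the fields are smooth), followed by three fixed-point
corrections of the prescribed divergence against the *measured*
determinant, which absorb the second-order terms at large |g|.  The
construction is verified, not trusted: the centrally differenced Jacobian
of the field matches 1 + g to well under 0.02 mean absolute error over
the liver (typically ~0.002), the residual concentrating at the jump to
zero response at the liver edge.  Post-treatment images and masks are the
forward warp of the
pre-treatment ones under the field (fixed-point inversion), and the
smoothing applied to make g resolvable is a *normalized* convolution --
plain smoothing of the masked field dilutes the response toward the
outside zeros and visibly biases regional means.

## Regional statistics

Maps are averaged over the whole liver, segments 1-4, the right lobe and
the left lobe (union of 2-4); volume change is reported in percent.
Cohort dose-response is summarised by Pearson r and the OLS fit
dv% = slope * EQD2 + intercept.  The slope's standard error is
heteroscedasticity-robust (HC3): the per-case sensitivity is
multiplicative, so residual variance grows with dose and the classical
error understates the slope's sampling variability.  Frequency tables
stratify at 50 Gy mean EQD2 and count hypertrophy (dv above 0 / +10 %)
below the split and atrophy (dv below 0 / -10 %) above it; event labels
for ROC analysis use the symmetric +-5 % convention with strict
inequalities (the only reading under which hypertrophy and atrophy are
disjoint rare events).

## Predictor

Inputs are three channels on a liver-bounding crop grid (margins 15/15/5
voxels at full scale): CT windowed from [-1000, 500] HU to [0, 1]
(clamped), EQD2/100, and a fused contour/time channel (-1 outside the
liver, EQD2/(100 T) inside).  The network is a two-level 3D U-Net
(8 base channels, LeakyReLU, nearest upsampling, skip concatenation,
dropout on the bottleneck, zero-initialised 1x1 head so the untrained
model predicts "no change") written directly in NumPy: convolutions are
im2col + GEMM with hand-derived backward passes, verified against finite
differences, and Adam optimisation.  Training minimises voxel MSE with
random +-20 degree rotations about all three axes; validation each epoch
uses the mean of the smallest 16/18 (proportionally scaled) per-case
MSEs, checkpointing on improvement.  Testing is leave-n/k-out
cross-validation stratified by cancer type; every prediction comes from
the fold that never saw the case, mapped back to the planning grid and
zeroed outside the liver.

Two profiles exist.  The full-scale profile mirrors the reference
protocol (192x192x64 grid, 10 folds, batch 2, learning rate 2e-4, 1000
epochs).  The desk profile -- used by the test suite and the acceptance
script -- runs 48x48x16 grids, 4 folds and ~35 epochs with learning rate
2e-3, cosine decay and dropout 0.05, because at two orders of magnitude
less compute the reference rate never leaves the transient.  Problem
sizes throughout (phantom grids, cohort sizes, epochs) are the package's
desk-scale defaults chosen so the full pipeline runs on a single CPU in
minutes; the full-scale settings remain available in the configs.

## Evaluation

Per case, the voxel-wise Pearson correlation (liver voxels only --
outside voxels are identically zero in both maps and would inflate r)
between the predicted and the registration-based map is compared with
the *negated* correlation between EQD2 and that map, so both
distributions are oriented positively.  Normality is checked with
Shapiro-Wilk; the paired difference with a two-sided Wilcoxon signed-rank
test (exact for small untied samples, else the normal approximation).
Regional agreement reports Pearson r alongside an identity-line
R^2 = 1 - SS_res/SS_tot about y = x, so systematic magnitude
under-estimation lowers R^2 while leaving r high (the regression-line r^2
is also reported).  ROC AUC uses the tie-aware pair-counting definition.

## What the phantoms do and do not show

Passing tests demonstrate that the pipeline's machinery is correct and
that, when a dose/anatomy-driven response of the assumed family exists,
the registration stack recovers it and the predictor exploits it beyond
a linear dose baseline.  The phantoms do not emulate contrast-phase
differences, breathing motion, tumour mass effect, segmentation error or
inter-patient anatomical variability, and the planted response family is
far simpler than real radiobiology -- absolute correlation levels on
phantoms are therefore optimistic and only the *directional* statements
transfer.  Known limitations: contour-driven registration
under-estimates interior redistribution (aperture problem); the
structured mesh staircases the surface at the cube scale; Demons on
thin vessel trees rarely exceeds Dice ~0.9; and the desk-scale U-Net
sees vessels only as far as the coarse grid resolves them.
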