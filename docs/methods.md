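# Methods

## Signal model and tensor estimation

Each voxel is modelled by a single symmetric diffusion tensor D (mm²/s);
the diffusion-weighted signal follows the Stejskal–Tanner equation
S_i = S0·exp(−b_i·g_iᵀ D g_i). The fit solves the log-linearized system
in the 6 unique tensor elements plus ln S0 by ordinary least squares
(LLS), the estimator used by era-typical scanner and Slicer pipelines; a
weighted refit (WLLS, weights = squared LLS-predicted signals) is
available behind a flag. The b=0 repeats are averaged into a single
volume before fitting so that the unweighted samples do not dominate the
7-unknown system. Signals below 1e−6·S0 are floored before the log and
counted (a warning reports the count). A design whose directions are
coplanar or too few is rejected as rank-deficient rather than silently
pseudo-inverted.

Eigenvalues are sorted descending and clamped at zero *only* for the
derived metrics (FA by the normalized-deviation formula, MD as the
eigenvalue mean; an all-zero tensor maps to FA = 0). The raw tensor
diagonal is kept untouched because the ALPS index is defined on the axis
diffusivities Dxx/Dyy/Dzz, not on eigenvalues. Non-finite tensors mark a
voxel invalid; invalid voxels are excluded (and counted) from ROI means.

Gradient directions are interpreted in the image coordinate frame of the
accompanying NIfTI affine. The FSL bval/bvec text dialect does not pin
the frame, so this convention is stated here and enforced consistently by
the writer and reader; near-unit directions (|‖g‖−1| ≤ 1e−3) are
renormalized with a warning, worse deviations rejected.

## The ALPS index

ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc), computed
from single-slice ROI means. Multi-slice ROIs are rejected by default
(overridable with a warning) because the measurement is defined on one
transverse slice at the lateral-ventricle body. Two observers are merged
by averaging the four diffusivities and re-forming the ratio; the
alternative convention (averaging the two ratios) is exposed separately,
since ratio-of-means and mean-of-ratios differ in general and the
literature rarely states which level is averaged.

Automatic ROI suggestion operates on the FA-weighted directionally
encoded color map: the slice with the largest ventricle cross-section is
chosen, candidate pixels need a DEC intensity of at least 0.1 (an FA
floor that excludes isotropic tissue, whose eigenvectors are numerically
arbitrary), the projection ROI grows 8-connected and nearest-first from
z-dominant pixels bordering the ventricle, and the association ROI from
y-dominant pixels lateral to it. Default target sizes are 9 and 8 voxels
(≈35 and 30 mm² at 2×2 mm pixels, matching reported clinical ROI sizes).
The procedure is deterministic given its inputs; when no qualifying
pixels exist it raises and advises manual ROIs.

## Phantom generator

The phantom emulates only the geometry the measurement relies on — not
anatomy: disjoint axis-aligned blocks for ventricle (isotropic
3.0e−3 mm²/s), projection fibers (λ∥ = 1.4e−3 along z, λ⊥ = 0.4e−3),
association fibers (λ∥ along y) and background (isotropic 0.8e−3),
plausible brain values and all configurable. The perivascular effect is
an additive increment δ to Dxx inside both fiber blocks, giving a
ground-truth ALPS of (λ⊥ + δ)/λ⊥; the default δ = 1.488e−4 sets that
ratio to 1.372, the middle of reported glioma cohorts, and
`delta_for_alps()` inverts the relation for calibration studies.

The acquisition mirrors a clinical single-shell protocol: b = 0 and
1000 s/mm², 20 encoding directions, 2 mm isotropic voxels, no
inter-slice gap. The direction set is a 20-point antipodally-symmetric
electrostatic-repulsion table (minimum angular separation 30.6°) shipped
as a text fixture and recorded in output metadata. The four signal
averages of such protocols are modelled as four b=0 repeats — a stated
simplification. Rician noise is the magnitude of
(S + N(0,σ), N(0,σ)) with σ = S0/snr, applied per channel; snr = ∞
bypasses the noise branch entirely, making noiseless outputs independent
of the seed. The default snr of 30 is a realistic 3-T b0 value. Identical
(spec, seed) pairs are bit-reproducible.

What the phantom does *not* carry over from real data: partial-volume
mixing at block boundaries, spatially varying noise (parallel-imaging
g-factor), eddy/motion artifacts, fiber curvature and crossing. Passing
tests therefore demonstrate the correctness of the estimator and index
arithmetic under the stated model, not robustness to those confounds.

Tumor label volumes are nested axis-aligned boxes (outer edema+tumor
envelope ⊇ whole tumor ⊇ disjoint non-enhancing / necrotic / hemorrhagic
subcompartments), painted innermost-label-last. The representation makes
the subtraction identities exact by construction, and per-slice areas are
analytically computable from the spec for oracle tests.

## Volumetry

Volume = per-slice area (pixel count × in-plane pixel area) × slice
distance (thickness + gap), summed over slices, reported in cm³ — the
planimetric convention of manual ROI studies; masks replace the hand-drawn
polygons as the reproducible equivalent. Lesions are retained only if
strictly larger than 1 cm² in their maximal single-slice cross-section
("larger than" is read as strict, so an exactly-1 cm² lesion is removed).
Lesion connectivity is 8-connected in-plane with face connections across
slices — stated here because the convention is otherwise ambiguous. When
tumor occupies both hemispheres the side with more tumor voxels is
selected; exact ties go to the left with a warning (an arbitrary,
flagged choice).

## Cohort generator

Patients are drawn cell-by-cell over the (grade, IDH1) design, by default
86/52/63 patients in grades II/III/IV with mutant fractions 66/86, 34/52,
7/63, grade-level age means 41.4/45.2/57.5 years (SD 13.3/13.6/15.1,
truncated at 18 by redraw) and per-grade compartment-volume moments from
the reference table in `dtialps.cohort.REFERENCE_GRADE_SUMMARY`. Volumes
are truncated at zero by redraw — volumes cannot be negative — so the
effective generative moments are those of the truncated normal; the
redraw fraction is reported in `df.attrs`. Because each compartment is
drawn independently per grade cell, the additivity identity
(enhancing = whole − parts) holds for *measured* label volumes but not
for these simulated covariates; the cohort table models measurement
outputs as correlated-through-grade covariates, which is what the
statistics layer consumes.

The outcome is alps = 1.372 + 0.202·(0.308·z(IDH1) − 0.353·z(edema)) + ε
with ε ~ N(0, 0.168): standardized coefficients in outcome-SD units
applied to within-sample z-scores, so a regression on z-scored variables
recovers the coefficients in expectation. The residual SD of 0.168
(0.83 outcome-SDs) makes the realized pooled ALPS SD land near 0.202
given the covariate correlation the grade structure induces. No other
covariate carries a direct effect; their marginal associations run
entirely through grade — exactly the confounding structure a stepwise
selector must see through.

## Statistics layer

* **Exclusions** remove any patient flagged under-18, motion artifact,
  infratentorial-only or IDH1-missing, logging counts per reason.
* **Normality**: Kolmogorov–Smirnov with estimated mean/SD is
  anti-conservative, so the Lilliefors-corrected null distribution is
  used (statsmodels implementation; calibration verified by simulation).
* **ICC(2,1)**: absolute-agreement, two-way random-effects, single
  measure, computed from the two-way ANOVA mean squares with the
  F-approximation CI; validated to 1e−10 against hand mean-squares
  arithmetic and against pingouin's ICC(A,1).
* **ANCOVA**: outcome ~ group dummies + age; adjusted means at the
  grand-mean age; all pairwise contrasts Bonferroni-multiplied by the
  number of pairs, with CIs at the matching α/m t-quantile. A constant
  covariate is dropped, reducing exactly to one-way ANOVA.
* **Regressions**: all variables z-scored, so coefficients are
  standardized (for a simple regression, β equals Pearson r — used as an
  oracle). Coding: woman=0/man=1, wild-type=0/mutant=1, grade ordinal
  2/3/4, chosen so a positive IDH1 coefficient reads "mutation →
  higher ALPS". Binary predictors are z-scored too, the common
  statistics-package convention.
* **Stepwise**: forward entry of the smallest partial p ≤ 0.05, backward
  removal of any partial p > 0.10, iterated to stability (classic SPSS
  defaults; configurable). An empty model is a valid outcome. With eight
  null candidates each admitted by a ~5% type-I event, the expected
  probability of a perfectly clean selection is ≈0.95⁸ ≈ 0.66 — measured
  at 0.68 — even though the true predictors are recovered in >99% of
  runs with unbiased coefficients; this operating characteristic is a
  property of stepwise selection itself, not of the implementation.
* **VIF** = 1/(1−R²) from regressing each predictor on the rest; perfect
  collinearity reports infinity with a warning.

## Problem sizes and numerical choices

Default phantom grids are 32×32×12 (ROI-masked fits where only ROI
statistics are needed), Monte-Carlo suites use 200 phantom realizations /
200 cohort replicates / 1000 null simulations — sizes at which every
stochastic check's tolerance is several standard errors wide. Tensor-fit
agreement with an independent per-voxel OLS reference is asserted to
1e−6 relative; closed-form statistical oracles to 1e−10; noiseless
round trips to 1e−9 (limited by the 1e−10 precision of the stored
direction table). Ties in ROI growth are broken lexicographically by
voxel index so automatic placement is deterministic.

## Known limitations

Single-tensor model only (no multi-shell, no non-Gaussianity); no
registration, DICOM ingestion or template anatomy; automatic ROI
placement assumes the block-geometry phantom contrast and is a
convenience on real DEC maps, not a validated segmentation; the cohort
generator reproduces first and second moments and one linear outcome
mechanism, not the full joint distribution of real clinical measurements.
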