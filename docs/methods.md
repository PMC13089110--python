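# Methods

This note documents the models implemented in `comet_bioage`, the synthetic
cohort the tests run on, and the numerical and design choices made where the
underlying procedure left room.

## Cohort definitions

Amyloid status is decided by the nearest eligible measure within ±2 years of
baseline MRI. Modality preference is categorical, not temporal: if any PET
measure (florbetapir or PiB) lies in the window, the PET measure with the
smallest |offset| decides, even when a CSF measure is closer in time; CSF
decides only when no PET exists in the window. Ties at equal |offset| prefer
florbetapir, then the earlier (smaller signed offset) measure. Cutoffs are
applied exactly as printed: PET positive at SUVR ≥ cutoff (florbetapir 1.1,
PiB 1.47, inclusive), CSF positive at Aβ-42 < 980 pg/mL (strict). A
participant with no eligible measure is `unknown`.

Cohorts: CU diagnosis + amyloid-negative → `CU`; MCI/dementia +
amyloid-positive → `symptomatic`; every other combination → `excluded`
(the source cohort definitions say nothing about discordant cases, so
exclusion is assumed). Chronological age groups: younger ≤ 65, older ≥ 80,
else average (both bounds inclusive).

## Epigenetic clocks and the biological age gap

A clock is `m = intercept + Σ_j w_j β_j` over CpG beta values, followed
either by the identity (blood-trained clocks) or by the log-linear adult
anti-transform used by pan-tissue clocks:

    age(m) = (A+1)·exp(m) − 1   if m < 0
           = A + m·(A+1)        otherwise,      A = adult_age = 20 y

with fixed point age(0) = A. Missing clock CpGs raise an error listing the
ids; there is no silent imputation.

Per clock, the biological age gap is the residual of an OLS regression of
predicted age on chronological age over the supplied cohort; residuals are
mean-zero and exactly uncorrelated with chronological age on that cohort.
The BAG used downstream is the arithmetic mean of the per-clock residuals
(averaging three clocks reduces clock-specific noise variance by ~3×). No
covariates enter the BAG calculation; adjustment happens downstream in the
w-scores.

Choices: the regression cohort defaults to *all* participants with
methylation (BAG is computed before any cohort stratification); per-cohort
fitting is available by passing the subset. Biological-age groups use the
cohort sample SD (ddof = 1) with the boundary |z| = k (default k = 0.5)
assigned to the extreme groups — a probability-zero event in continuous
data, fixed for reproducibility. Technical replicates are resolved before
clock application by a uniform, seeded draw within each participant's
replicate group.

## ComBat harmonization

Scanner field strength (1.5T vs 3T) is the batch variable. The model is
standard parametric empirical-Bayes ComBat: per feature, a least-squares fit
of the value on batch indicators plus covariates; standardization by the
batch-size-weighted grand mean, the covariate fit and the pooled residual
variance (1/n denominator); per-batch naive location/scale estimates; a
normal prior on locations and an inverse-gamma prior on scales with
moment-matched hyperparameters across features; and iterative conditional
updates of the shrunken location γ* and scale δ*² until the maximum
absolute relative change falls below 1e-4 (cap 1000 iterations; the
procedure converges in a handful of steps in practice).

The harmonizer is fitted on the CU reference only and stores everything
needed to transform unseen rows (per-batch γ*, δ*, covariate coefficients,
pooled variances), so symptomatic subjects are adjusted with CU-derived
batch parameters and disease effects pass through untouched. Covariate
contributions (age, sex, and diagnosis when it varies) are added back
unchanged; covariate columns that are constant in the reference (diagnosis
in a CU-only fit) are dropped and recorded on the model. γ is parameterized
as a deviation from the weighted grand mean, so the identifiable batch
contrast is γ_b − γ_b′.

Note an EB subtlety: because the *shrunken* γ* is removed rather than the
naive per-batch mean, re-applying the model to its own training data leaves
per-feature batch-mean residuals of the order of shrinkage × sampling noise
(~1e-2 standardized units at reference sizes of a few hundred) — small and
statistically null, but not numerically zero. Tests assert the statistical
null on held-out subjects and >90% gap reduction on the training batches,
plus equivalence (≤1e-6) with an independently coded R oracle on a fixed
8-subject fixture.

## Composites, w-scores and CoMeT

ROIs are averaged bilaterally first (left/right mean per region), then
unweighted across the region set. The cortical composite uses 18
DKT signature regions (thickness); the MTL composite mixes thickness
(entorhinal, parahippocampal) and volume (hippocampus, amygdala) measures.
One naming caveat: the published signature lists "middle frontal" as one
region while FreeSurfer's DKT parcellation splits rostral/caudal middle
frontal; the default ROI set uses a single `middlefrontal` label and is
YAML-overridable for real FreeSurfer exports.

A w-score is a covariate-adjusted z-score against the CU reference:
`w = (observed − predicted) / residual SD`, where the prediction comes from
an OLS fit on the CU cohort — age + sex for thickness composites, age + ICV
for volume composites (taken literally: sex is not added to the volume
model). The residual SD uses the n − p denominator, so reference w-scores
have sample SD sqrt((n−p)/(n−1)), slightly below 1; their mean is exactly 0.
Covariates are internally centred and scaled for conditioning (ICV is ~1e6×
larger than the sex indicator); exposed coefficients are in raw units.

Because the MTL mixes measure kinds with different covariate rules, the MTL
composite w-score is the mean of two separately w-scored sub-composites
(thickness and volume) — this keeps each measure correctly adjusted. Then

    CoMeT = w_cortical − w_MTL,

antisymmetric in its arguments; lower values mean relatively greater
cortical involvement. Composites are computed from harmonized ROI values;
the covariates used for w-scoring are the raw age/sex/ICV.

## Statistical battery

All p-values are two-sided. Pearson correlation uses the t reference with
n − 2 df. The Wilcoxon rank-sum statistic W is the sum of midranks of the
first group; the p-value is exact — full enumeration of the C(n, n_a) rank
assignments — when the pooled sample has ≤ 12 tie-free observations, else a
tie-corrected normal approximation with continuity correction. Exhaustive
enumeration shows the two routes agree within 0.02 for every attainable
outcome at 6-vs-6 and within 0.04 when both groups have ≥ 3 members; the
approximation degrades for very unbalanced small splits (up to ~0.12 at
n_a = 1), where the exact route is authoritative. The rank-biserial effect
size is the mean pairwise dominance (#a>b − #a<b)/(n_a·n_b), equal to
2U/(n_a n_b) − 1 with ties shared. Group order is fixed as (decelerated,
accelerated) and (younger, older), so a negative effect size always means
the first-named group is lower. Chi-squared tests are Pearson's without
continuity correction. No multiple-testing correction is applied, and no
additional covariates enter the group comparisons (the w-scores already
adjust for age, sex and ICV). Groups smaller than 2 are reported as
not-computable rows rather than raising.

## Synthetic cohort generator

The generator emulates the structure of an ADNI-like baseline cross-section;
its defaults are the study conditions the tests run under.

* **Cohort sizes** 163 CU / 170 MCI / 115 dementia — the methylation subset
  sizes, so the symptomatic analysis runs at n = 285.
* **Age** truncated normal, mean 75.3 y, SD 7.3 y on [55, 95] (pooled
  cohort-table scale); **sex** 44.4% female; **ICV** normal
  (1.45e6 ± 1.4e5 mm³); education and CDRSB drawn to match the reported
  medians (CDRSB 0 for CU, ~1.5 MCI, ~5 dementia); APOE4 carrier
  frequencies ~21% CU / ~68.5% symptomatic.
* **ROI model** value = healthy norm + age slope (−0.01 mm/y thickness,
  −15 mm³/y at hippocampus scale) + sex effect (0.05 mm, thickness) + ICV
  slope (volumes) + batch effect + planted deviation + measurement noise
  (0.05 mm per thickness ROI, scaled per volume ROI). The 3T batch adds
  +0.06 mm (scaled per ROI) and multiplies noise SD by 1.3.
* **Planted deviations** are coherent per compartment: each subject carries
  a shared severity S and a cortical-minus-MTL contrast D (in CU-reference
  SD units), with compartment deviations W_cortex = S + D/2,
  W_MTL = S − D/2 and variances budgeted so CU deviations have unit
  variance. In symptomatic subjects D is generated as
  ρ·z_BAG + sqrt(1−ρ²)·ε around the mean contrast, so
  corr(latent BAG, contrast) = coupling_rho *by construction* (default
  0.15, the scale of the reported headline correlation; mean atrophy −1.2
  SD cortex, −1.8 SD MTL, the typical MTL-predominant pattern). Because
  the coupling is planted on the total subject-level contrast, measured
  CoMeT inherits the correlation with only ~4–5% attenuation from
  measurement and clock noise — estimated r ≈ 0.94·ρ at the default noise
  levels.
* **Latent BAG** normal, SD 4 y. **Methylation** betas are constructed per
  clock as an affine map of the target prediction (age + BAG + clock noise,
  default 2 y per clock) along the clock's coefficient direction, centred
  at beta 0.5, plus CpG noise projected orthogonal to the coefficients so
  the planted prediction is exact; generation fails loudly if any beta
  would leave [0, 1]. Three synthetic clocks (two identity, one
  log-linear) use disjoint 60-CpG blocks of a 200-CpG panel. Optional
  technical replicates duplicate rows with fresh orthogonal noise.
* **Amyloid measures** are drawn on the diagnosis-consistent side of each
  cutoff with a safety margin, so classification recovers the generator's
  intent exactly — cohort-assignment tests have a planted truth.
* **Determinism**: one seed feeds fixed per-table sub-streams
  (participants, ROI, amyloid, methylation), so adding a table cannot
  perturb earlier draws and identical seeds give byte-identical outputs.

What the generator does *not* emulate: real CpG biology and probe-level
artifacts, nonlinear covariate effects, longitudinal structure,
site-level (multi-scanner-ID) batches, and correlated ROI noise beyond the
single shared severity factor. Passing tests therefore demonstrate that the
pipeline recovers what it claims from data matching its model assumptions —
not that those assumptions hold in any particular real cohort.

## Problem sizes used in the automated checks

The test battery runs the full pipeline at the study's methylation-subset
scale (n = 448; 200 seeds for the coupling calibration, 100 for the null),
parameter-recovery at n = 500 over 20 seeds, harmonization checks at
~500 subjects per scanner, and the reference-normalization check at
n = 500 CU — sizes at which the Monte-Carlo tolerances quoted above are
several sampling SDs wide.

## Known limitations

* Clock coefficients are synthetic by default; real published coefficient
  files must be supplied by the user in the documented CSV layout.
* The harmonization model assumes every batch present at application time
  was seen in the reference; there is no pooling fallback for novel
  scanners.
* The MTL thickness/volume combination rule (average of two sub-w-scores)
  is one defensible reading of an under-specified construction; switching
  to a single pooled regression would change MTL w-scores slightly.
* Exact Wilcoxon enumeration is limited to pooled n ≤ 12; beyond that the
  tie-corrected normal approximation is used without a permutation
  fallback.
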