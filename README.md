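# comet-bioage

Does *biological* aging — measured from blood DNA methylation — shape **where**
Alzheimer's disease damages the brain, beyond chronological age? Typical,
amnestic AD atrophies the medial temporal lobe (MTL) more than the cortex;
atypical, often younger-onset presentations show the reverse. `comet-bioage`
is a tested, seeded pipeline for quantifying that relationship in
ADNI-style tabular data:

1. **Cohorts** — classify amyloid status from the nearest PET or CSF measure
   within ±2 years of baseline MRI (florbetapir SUVR ≥ 1.1, PiB SUVR ≥ 1.47,
   CSF Aβ-42 < 980 pg/mL; PET preferred over CSF), then split participants
   into amyloid-negative cognitively unimpaired (CU) and amyloid-positive
   symptomatic (MCI/dementia) cohorts.
2. **Clocks** — apply linear epigenetic clocks to CpG beta values
   (identity or Horvath-style log-linear adult age transform), compute each
   clock's **biological age gap** BAG = residual of predicted age regressed
   on chronological age, average the per-clock gaps, and stratify
   accelerated / neutral / decelerated groups at ±0.5 SD.
3. **Harmonization** — remove 1.5T-vs-3T scanner batch effects from regional
   thickness/volume measures with parametric empirical-Bayes **ComBat**,
   fitted on the CU reference and applied to symptomatic subjects, preserving
   age, sex and diagnosis effects.
4. **CoMeT** — build a cortical composite (18 DKT signature regions,
   bilateral thickness) and an MTL composite (entorhinal + parahippocampal
   thickness, hippocampus + amygdala volume), convert both to CU-referenced
   w-scores (thickness adjusted for age + sex, volume for age + ICV), and
   score

   `CoMeT = w_cortical − w_MTL`

   Lower CoMeT ⇔ relatively greater cortical involvement (less typical
   presentation).
5. **Stats** — Pearson correlation of CoMeT vs BAG, Wilcoxon rank-sum with
   rank-biserial effect sizes (exact enumeration for small tie-free samples),
   chi-squared association tests and cohort descriptive tables.

Real methylation/MRI cohorts are access-controlled, so the package ships a
first-class **synthetic cohort generator** that plants a known ground truth —
latent per-subject BAG, a cortical-vs-MTL atrophy contrast coupled to BAG at a
configurable correlation, scanner batch effects, covariate structure, and
methylation betas whose clock predictions equal age + latent gap + noise —
and records every planted parameter for parameter-recovery testing.

## Worked example

```sh
comet-bioage run-all --seed 7 --outdir runs/demo
cat runs/demo/summary.txt
```

```
Primary analysis report
============================================================
comet_vs_bag_pearson [symptomatic]: n=285, stat=0.1812, p=0.002129
comet_by_bio_age_group [symptomatic]: n=(91,96), stat=7213.0000, p=0.0002907, rank-biserial=-0.307
...
comet_vs_bag_pearson [dementia]: n=115, stat=0.2467, p=0.007865
...
cu_mean_cortical_w [CU]: n=163, stat=-0.0000
cu_mean_mtl_w [CU]: n=163, stat=0.0000
cu_mean_comet [CU]: n=163, stat=-0.0000
```

Reading this run (default synthetic cohort: 163 CU + 170 MCI + 115 dementia
subjects with methylation, planted CoMeT–BAG coupling 0.15): the symptomatic
cohort shows a positive CoMeT–BAG correlation (r = 0.18 here; the planted
0.15 plus sampling noise), i.e. biologically *decelerated* subjects sit lower
on CoMeT — relatively more cortical atrophy. The Wilcoxon row compares CoMeT
between the decelerated (n = 91) and accelerated (n = 96) groups; the
negative rank-biserial (−0.31) means the first-listed (decelerated) group
tends lower. The CU rows are the built-in sanity check: CU subjects scored
with their own reference models have mean w-scores of exactly 0.

The run directory also contains every intermediate table (`participants.csv`,
`roi.csv`, `bag.csv`, `roi_harmonized.csv`, `comet.csv`, `table1.csv`), the
planted ground truth (`truth.json`), the fitted ComBat model
(`combat_model.json`) and a provenance manifest with content hashes
(`manifest.json`). Identical config + seed reproduces the directory byte for
byte.

The same analysis is available programmatically:

```python
import comet_bioage as cb

cfg = cb.SyntheticConfig(coupling_rho=0.15, seed=7)
participants, roi, amyloid, truth = cb.generate_cohort(cfg)
betas, clocks = cb.generate_clock_data(participants, truth, cfg)
labels = cb.build_cohort_table(participants, amyloid)
bag = cb.compute_bag_table(cb.select_replicate(betas, seed=8), clocks,
                           participants.set_index("id")["age_at_mri"])
```

Estimator-style classes (`ComBatHarmonizer`, `WScoreModel`,
`AgeResidualizer`) follow scikit-learn conventions (`fit`, `transform`,
`get_params`, fitted attributes with trailing underscores) and compose with
sklearn tooling.

## Data formats

All inputs and outputs are delimited text: participant/amyloid/ROI tables as
CSV, methylation betas as a participants × CpG CSV (with a replicate index
column), clock coefficients as CSV with a small `#` header block declaring
the clock name, transform and adult-age knot (published Horvath / Hannum /
Shireby coefficient files can be dropped into this layout; none are
bundled), and ROI-set definitions as YAML. See `docs/methods.md` for the
model details, parameter meanings and design decisions.
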