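# aneumatch

Multidimensional matched-cohort construction and surgical-outcome comparison
for intracranial aneurysm studies.

## The problem

When a neurosurgical center compares two approaches to clipping anterior
communicating artery (AcomA) aneurysms — here a small anterior
interhemispheric (AIA) series against a larger pterional (PA) series — the
arms differ systematically in case mix: rupture status, severity grades,
aneurysm size and orientation all influence both the choice of approach and
the outcome. `aneumatch` implements the matching procedure such comparisons
need: for each AIA case (the *aneurysm of interest*, AOI) it retrieves the
most similar PA case by k-nearest-neighbor case-based reasoning under a
weighted Euclidean dissimilarity on Z-scored features,

    dist(x, q) = √( Σ_l fw_l (x_l − q_l)² ),    fw_l = 1,  k = 3,

within strata of identical rupture status and frontal base-dome-angle (FDA)
quadrant, with sequential 1:1 assignment and deterministic conflict
adjudication. A downstream comparison engine then produces the
baseline-balance table and the primary (occlusion, mRS at discharge) and
secondary (temporary clipping, intraoperative rupture, postoperative
stroke/hemorrhage, hydrocephalus, shunt dependency, vasospasm) outcome
analysis, routing each variable to chi-square / Fisher exact /
Mann-Whitney U / t-test by the standard expected-cell and
normality/variance-homogeneity rules.

Because clinical source data of this kind are not openly available, the
package ships a synthetic cohort generator that reproduces the study
structure (14 AIA vs 36 PA candidates, ~50% ruptured, the full covariate and
outcome schema) including planted "twins" with known ground truth for
matching-recovery validation. See `docs/methods.md` for the model and all
design choices.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort and write their tables to `results/`:

```
python analysis/01_simulate_cohort.py     # 14 AIA vs 36 PA cases
python analysis/02_derive_morphometrics.py# SR, AR, FDA category
python analysis/03_match_cohort.py        # k-NN matching, conflicts, pairs
python analysis/04_compare_outcomes.py    # baseline table + outcome report
python analysis/05_calibration.py         # twin recovery + engine calibration
```

The matching step prints every adjudicated conflict, e.g. (seed 1):

```
matched 14 of 14 AOIs against 36 references
  conflict over P006: A007 keeps P006; A009 falls back to P015
  conflict over P019: A004 keeps P019; A010 falls back to P023
  conflict over P022: A012 keeps P022; A003 falls back to P033
  conflict over P013: A014 keeps P013; A011 falls back to P034
mean matched distance: 2.130
```

i.e. four references were each the top match of two AOIs; the closer
claimant kept the reference and the other took its next free neighbor —
exactly the situation the two-reviewer adjudication handles in interactive
practice. The comparison step then reports, per variable, the per-arm
summary, the routed test and its p-value:

```
      variable   arm_aoi arm_reference         test  p_value
nicotine_abuse 3 (21.4%)     5 (35.7%) fisher-exact 0.677617
      ruptured   7 (50%)       7 (50%)   chi-square      1.0
 hydrocephalus  1 (7.1%)       7 (50%) fisher-exact  0.03285
      vp_shunt    0 (0%)     8 (57.1%) fisher-exact 0.001932
```

Zero matching covariates are flagged at α = 0.05 (the matching balanced the
arms), while the planted outcome effects — less hydrocephalus and shunt
dependency in the AIA arm — are detected. The calibration script reports
100% planted-twin recovery at zero noise, 99.9% at 5% feature noise, and
the exact null sizes of the discrete test routes (chi-square 0.0375, Fisher
0.018 at n = 14 per arm; see the calibration caveat in `docs/methods.md`).

A `aneumatch` CLI wraps the same stages
(`aneumatch simulate|derive|match|compare|run`, each accepting `--seed` and
`--config`).

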