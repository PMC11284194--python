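# Methods

`aneumatch` builds 1:1 matched cohorts for comparing two microsurgical
approaches to anterior communicating artery (AcomA) aneurysms — a small
anterior interhemispheric (AIA) arm matched against a larger pterional (PA)
reference pool — and then compares the arms with routed statistical tests.
This note records the model, the knobs that matter, and the design choices
made where the procedure was genuinely open.

## Matching model

Each AIA case (the "aneurysm of interest", AOI) is compared to candidate PA
references by a weighted Euclidean dissimilarity on Z-score-standardized
features:

    dist(x, q) = sqrt( Σ_l fw_l (x_l − q_l)² )

with all feature weights `fw_l = 1` by default. Retrieval is k-nearest
neighbor with `k = 3` (small-sample setting). Three weighting variants are
exposed — `plain` (equal weights 1/k), `inverse_distance` (weights ∝ 1/d,
normalized), and `minmax_inverse` (distances min–max scaled over the pool to
[0, 1], then inverse-weighted). All variants rank by the same raw distance,
so the retrieved neighbor *set* is identical; only reported weights differ,
and pair selection uses the plain ranking.

Matching features:

* unruptured stratum — gender, age at surgery, aneurysm shape
  (regular/irregular), aneurysm size (mm);
* ruptured stratum — the same plus Hunt & Hess grade and Fisher grade.

Categorical features enter the distance 0/1-coded (codebook: male = 0,
female = 1; regular = 0, irregular = 1) before standardization; ordinal
grades enter as their integer level. The formula is thereby applicable to
every matching feature, at the cost of treating a one-step grade difference
like any other unit difference on the standardized scale.

**Standardization pool.** Z-scores (sample sd, denominator n−1) are fit on
the union of a stratum's AOIs and candidate references, not globally.
Distances are compared within strata — between an AOI and its own candidate
pool, and between claimants in a conflict — so per-pool scaling keeps those
comparisons on one scale. Constant columns (likely in small strata) are
mapped to all-zero and flagged rather than erroring, contributing nothing to
any distance.

## Stratification and the FDA

The frontal base-dome angle (FDA) is the sagittal angle between the
aneurysm's maximum-height axis and a baseline parallel to the frontal skull
base, measured on the full circle starting ventral to the aneurysm. It is
binned into quadrants with upper-closed intervals: [0, 90] → 1,
(90, 180] → 2, (180, 270] → 3, (270, 360] → 4; 360° is accepted as the top
of category 4 and not wrapped. The boundary policy keeps the classifier
total and monotone on the continuum while matching the one-decimal
granularity of the printed category ranges.

Matching is constrained to strata of identical rupture status × FDA
category. Rupture status is never crossed. When a category holds no
references — or fewer references than AOIs, which makes 1:1 matching
infeasible — fallback categories are merged in along a per-category chain
(angularly adjacent quadrants first, preferring the upward neighbor, e.g.
3 → 4; the opposite quadrant last), and every merge is logged. Because a
merged stratum and its donor category draw on the same references, strata of
equal rupture status with overlapping category sets are unioned before
matching, and union + extension iterate to a fixpoint; in a stress test of
1000 random 14-vs-36 cohorts this leaves exactly one infeasible draw (more
unruptured AOIs than unruptured references in total), which raises an
explicit unmatchable error.

## Sequential assignment and conflicts

AOIs are processed in ascending case id ("next in line" made deterministic).
Each proposes its nearest reference; references are assigned 1:1 without
replacement. When two AOIs claim the same reference, the default adjudicator
gives it to the claimant at the smaller raw distance (ties by ascending case
id) — a deterministic stand-in for the two-neurosurgeon review used in
interactive practice; the adjudicator is a pluggable callable so an expert
policy can replace it. The loser falls back to its second, then third,
not-yet-assigned neighbor. If all k neighbors are taken while free
references remain in the stratum, the walk continues down the full
within-stratum distance ranking and the beyond-k fallback is logged; a
strict "error at k" policy would make the workflow partial on realistic
cohorts even though a valid 1:1 matching exists.

## Synthetic cohorts

The generator emulates the structure the matching and comparison stages
assume: a 14-case AIA arm versus a 36-case PA pool, rupture probability 0.5,
and the full clinical/morphometric/outcome column set. Distributional shapes
are the package's own choices, configurable and documented here:

* age ~ Normal(55, 10) truncated to [18, 95] years;
* aneurysm size (= maximum dome height Hmax) ~ log-normal, median 7 mm,
  log-sd 0.5; neck, parent-vessel diameters and dome height scale from it
  with plausible ratios;
* FDA angle ~ Uniform[0°, 360°);
* binary covariate prevalences default to values in the range typical of
  published AcomA baseline tables (e.g. hypertension 0.40, nicotine abuse
  0.35, multiple aneurysms 0.30, rare comorbidities 0.03–0.08);
* Hunt & Hess mass centred on grades 1–2, Fisher grade on 2–3, populated
  only on ruptured cases;
* per-arm binary outcome probabilities (`outcome_effects`) default to a
  pattern in which the AIA arm has less temporary clipping, hydrocephalus
  and shunt dependency — the direction the matched comparison is meant to
  detect; `with_null_outcomes()` equalizes the arms for calibration work.
  mRS at discharge is drawn from rupture-dependent categorical mass, equal
  in both arms by default.

What the generator does *not* model: inter-rater measurement error, imaging
statistics, correlations between covariates (all independent given rupture
status), and lost-to-follow-up. Passing tests therefore demonstrate the
mechanics of matching and testing, not clinical realism.

Planted twins provide matching ground truth: each AOI gets one perturbed
copy in the reference pool (continuous features jittered by
`noise_scale` × the feature's sd across AOIs, binaries flipped with
`flip_prob`, grades stepped with `flip_prob`; rupture status and FDA
category preserved) plus `n_decoys` = 2 independent draws confined to the
same stratum so they genuinely compete. Recovery is 100% at zero noise by
construction and ≈ 99.9% at 5% noise in the shipped calibration run.

## Statistical comparison

Routing per variable:

* binary/categorical → Pearson chi-square without continuity correction on
  the contingency table; Fisher's exact test (two-sided, point-probability
  method) replaces it when any expected cell is below 5 and the table is
  2×2. All-constant variables are reported as skipped ("—").
* ordinal/metric → per-group normality screen with Lilliefors-corrected
  Kolmogorov–Smirnov at α = 0.05 (plain KS with estimated parameters is
  anti-conservative; groups with n < 4 or zero variance count as
  non-normal); any failure → Mann–Whitney U (exact when the combined sample
  is ≤ 20 without ties, else normal approximation with tie and continuity
  corrections); both pass → Levene (mean-centred) chooses pooled
  (p ≥ 0.05) versus Welch t.

All p-values are two-sided; no multiple-testing correction by default (a
Holm option exists), matching the per-variable presentation style of
baseline tables in this literature. Percentages print with one decimal,
integral values without decimals ("7 (50%)").

### Calibration caveat (known limitation)

At n = 14 per arm the routed tests are discrete and slightly conservative.
By exact enumeration over both arms' binomial counts (reproduced by
`analysis/05_calibration.py`), the chi-square branch has conditional size
0.0375 and the Fisher branch 0.018 at a binary prevalence of 0.3; the
Mann-Whitney normal approximation has exact size 0.0444 at 14/14, pulled to
≈ 0.041 when conditioned on the non-normality route; the pre-tested t branch
sits slightly above 0.05 when skewed samples slip through the normality
screen. A two-sided Monte-Carlo band check centred exactly on α can
therefore flag these routes as "too conservative" depending on the
replicate seed — the acceptance-style calibration test in the suite
documents this honestly rather than recentring the band; the primitive-level
checks (Fisher vs full table enumeration for all N ≤ 40, Mann–Whitney vs
labeling enumeration, t vs a permutation oracle) are exact and green.

## Numerical conventions

* Distance/weight degeneracies: zero-distance neighbors share all inverse
  weight; min–max scaling with d_max = d_min falls back to equal weights
  (and otherwise necessarily gives the nearest neighbor scaled distance 0,
  hence weight 1 — an intrinsic quirk of inverse-weighting min–max-scaled
  distances).
* Neighbor and adjudication ties break by ascending case id; every stage is
  deterministic given config + seed, and report headers embed tool version,
  seed and config hash.
* Problem sizes in the shipped runs: 14 + 36 cases per cohort, 100
  replicates for twin recovery, 1000–2000 replicates for null calibration,
  exact enumeration rather than sampling wherever a closed population is
  small enough (Fisher tables, Mann–Whitney labelings, binomial-count
  grids).
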