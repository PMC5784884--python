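# Methods

This note documents the models the package fits, the generative assumptions
of the synthetic cohorts, the numerical choices that matter, and what the
test suite does and does not establish.

## Data model

Concentrations are absolute values in μM from a targeted assay panel
(amino acids, acylcarnitines, biogenic amines, glycerophospholipids,
sphingolipids, hexose), stored as a samples × metabolites table with a
per-cell below-limit-of-detection (LOD) flag and a per-metabolite LOD.
Everything downstream of imputation operates on natural-log concentrations.

## Preprocessing

* **Met-So exclusion.** Methionine sulfoxide accumulates with serum
  degradation; samples with Met-So strictly greater than 5 μM are excluded.
  The threshold is read literally as a strict inequality and is
  configurable; an alternative mode recomputes it as mean + 3·SD of the
  supplied samples, since 5 μM corresponds to roughly three standard
  deviations above the serum average.
* **LOD dialects.** Three imputation modes reflect three measurement
  contexts: `highest_below_lod` (brain tissue) sets every censored cell of
  a metabolite to the highest recorded sub-LOD value, deliberately erasing
  sub-LOD differences while preserving the above/below contrast that
  classifiers may use; `half_lod` (prodromal serum) is the conventional
  LOD/2 substitution; `none` (preclinical serum) leaves values untouched.
  When `highest_below_lod` finds no recorded raw value it falls back to the
  LOD itself, preserving ordering against above-LOD cells. Above-LOD cells
  are never modified.
* **Duplicates** are averaged arithmetically per metabolite; a cell remains
  censored only if every replicate was.
* **Storage-time matching.** Converter and non-converter samples are paired
  within ±2 years of freezer storage by maximum bipartite matching
  (Hopcroft–Karp), which is deterministic given input order and provably
  maximal — a greedy pass is not.

## Signature discovery

Only AD and CN samples enter discovery; the asymptomatic-pathology group is
reserved for the association battery. Within each LOO fold, features are
standardized by training-fold statistics only. The SVM arm uses a linear
kernel with fixed C = 1 (p ≫ n; no inner tuning loop) and recursive feature
elimination to *m* features per fold (default 20, step 20 % per round); a
metabolite's rank is the number of folds that selected it, with ties broken
by mean absolute margin-model weight, then lexicographically. The RF arm
takes its LOO metrics from per-fold forests and its ranking from one forest
fit on all samples: bagging is implemented directly over CART trees
(√p features per split) so each tree's out-of-bag set is known exactly, and
importance is baseline OOB accuracy minus mean OOB accuracy over
independent permutations of the metabolite's column. Vote ties in the
forest go to the lexicographically first class label.

Region selection maximizes mean LOO accuracy across classifiers (ties: SVM
accuracy, then the fixed order MFG, ITG, CBL). The panel is the union of
the two top-k lists minus assay-availability exclusions, ordered consensus
first, then by best rank.

The published panel-membership table is packaged as a fixture (26 panel
members, 13 consensus, plus the hexose dropped for assay unavailability).
The table does not record which ranking each unique metabolite came from,
so the fixture fixes an arbitrary-but-deterministic assignment; only the
membership counts are asserted against it.

## Cognitive composites

Each raw test is z-scored against the baseline (time = 0) visits of all
subjects — the only population guaranteed observed at baseline — after
negating timed tests (trail-making A/B), where higher raw scores are worse.
A domain composite is the mean of available constituent z-scores; it is
invariant to affine rescaling of any raw test's units. Visits strictly
after estimated symptom onset are dropped for converters; the onset visit
itself is retained, since it may have informed the onset estimate. An onset
recorded before baseline is treated as degenerate: only the baseline visit
survives.

## The association battery

All ten models adjust for age and sex only and report two-sided p-values,
deliberately uncorrected: the panel is a fixed a-priori hypothesis set and
the battery is interpreted through consistency across categories rather
than any single test. A Benjamini–Hochberg switch exists but is off by
default.

* **Group differences (brain).** The log concentration is the outcome of a
  cumulative-logit proportional-odds model with one intercept per distinct
  observed value — the regression generalization of the Wilcoxon and
  Kruskal–Wallis tests. The likelihood is maximized directly (analytic
  gradient, ordered-threshold reparametrization as first threshold plus
  log-increments, warm start at empirical cumulative logits, L-BFGS); this
  is ~100× faster than a generic ordinal fitter when the number of distinct
  values approaches n, and is cross-checked against statsmodels'
  `OrderedModel` in the tests. The global group p-value uses the Rao score
  test at the covariate-adjusted null with expected information and the
  classical (N−1)/N multinomial variance convention, making it exactly the
  asymptotic Wilcoxon/Kruskal–Wallis statistic when no covariates are
  supplied. The likelihood-ratio variant is available but measurably
  anticonservative at the autopsy design size (type-I error 0.073 vs 0.057
  for the score test at n = 44 over 1 500 null replicates), which is why
  the score test is the default. Direction is the sign of the AD-vs-CN
  coefficient from the full maximum-likelihood fit.
* **Pathology correlations.** Adjusted Spearman = midrank-transform x and
  the ordinal score, residualize each rank vector on the covariates by
  least squares, correlate the residuals; t reference with n − 2 − q df,
  Fisher-z confidence interval. With constant covariates this reduces to
  classical Spearman to machine precision.
* **Conversion risk.** Cox proportional hazards (lifelines; Efron tie
  handling), hazard ratio per 1 log-unit of concentration, Wald inference.
  Monotone likelihoods (complete separation) are flagged and reported with
  missing p rather than a spurious estimate.
* **Cognitive trajectories.** Linear mixed models per domain among
  converters only (the trajectory question concerns pre-onset decline in
  those who convert): fixed effects metabolite, age, sex, time and each ×
  time; random intercept and slope per subject with unstructured 2 × 2
  covariance; REML; Wald inference. The reported estimate is the
  metabolite × time coefficient on a per-year scale. Internally time is
  modeled in years (days/365.25) for conditioning. Because the resampling
  suites fit this one small structure thousands of times, the REML
  criterion is profiled directly (per-group sufficient statistics computed
  once; each evaluation is batched 2 × 2 Woodbury algebra; Nelder–Mead over
  the log-Cholesky of the relative random-effect covariance, two
  deterministic starts; exact-interpolation early exit for noiseless data).
  Estimates, standard errors and restricted likelihoods agree with a
  generic mixed-model fitter to optimizer precision — the test suite keeps
  that cross-check — at roughly a tenth of the cost, and without the
  convergence-at-non-stationary-point failures the generic quasi-Newton
  paths exhibited on this surface.
* **Cross-sectional endophenotypes.** OLS of the atrophy index and of ln
  CSF markers on log concentration; designs with condition number above
  1e10 are rejected.

## EASE-AD scoring

The five cognitive-domain results collapse to one category: significant if
any domain is, direction by majority among significant domains, exact ties
resolved by the fixed domain order (memory, attention, executive, language,
visuospatial) with an explicit conflict flag — a deterministic, logged
replacement for an ad-hoc manual choice. Each significant cell is coded
against the category's AD-like polarity (higher concentration AD-like for
group differences, CERAD, Braak, both Cox categories, the atrophy index and
both tau markers; lower concentration AD-like for Aβ1–42 and for cognitive
slopes, where decline is negative). The EASE-AD score counts significant
cells regardless of polarity, matching its definition as a count of
significant associations; a strict AD-like-only variant sits behind a flag.
Rows sort by score, then metabolite class (sphingolipids,
glycerophospholipids, others), then name.

## Synthetic cohorts

One global seed fans out into fixed named substreams (concentrations,
metadata, survival, visits, …), so adding a stream never perturbs another
and identical configurations are byte-identical. Per-metabolite log-scale
means are drawn N(1, 0.8) with log-SDs U(0.25, 0.6) — concentrations
spanning roughly 0.1–50 μM, a realistic range for a targeted panel.
Defaults mirror the three study designs: 15/14/15 AD/CN/ASYMAD autopsy
subjects across three regions; 250 serum samples with converter-skewed
Met-So contamination (expected 43 exclusions: 34 converters, 9
non-converters) and a 4.5-year converter storage-time shift; 216/366/185
CN/MCI/AD prodromal subjects.

Planted effects are the recoverable ground truth: standardized group mean
shifts confined to one region (the asymptomatic group sits a configurable
fraction along the AD−CN difference); exponential proportional-hazards
conversion with linear predictor Σ log-HR × centered log concentration plus
an age term, administratively censored (the baseline hazard is calibrated
to a target conversion fraction — Cox estimation is baseline-free, so this
choice is inert); biennial visits with raw test scores generated from a
latent domain score with subject random intercept (SD 0.5) and slope
(SD 0.05/yr), base slope −0.03 z/yr, test-level noise 0.3 z; and linear
cross-sectional effects with the AD-like sign convention (higher atrophy
index and tau, lower Aβ1–42 in more affected groups). Neuropathology scores
derive from one ordered latent severity monotone in group, discretized to
the 0–3 and 0–6 ranges.

The generator makes no attempt to match real cohorts' marginal
distributions, inter-metabolite correlation structure, APOE genetics, visit
irregularity or dropout. Passing tests therefore demonstrate that the
pipeline recovers known structure under its own model assumptions — not
that those assumptions describe any real cohort.

## Validation strategy and problem sizes

Every estimator is checked against an independent oracle: an explicit
hand-written LOO loop (exact equality), grid-search maximization of the Cox
partial likelihood on 6-subject inputs (1e-4), classical Spearman under
constant covariates (1e-12), exhaustive maximum matching on ≤12-per-side
instances, statsmodels `OrderedModel` for the proportional-odds likelihood,
and pingouin's partial correlation for the rank-residual construction.

Null calibration runs 500 replicates per model with empirical type-I error
required in [0.03, 0.07] at α = 0.05. Cohort sizes for these suites are the
design sizes where they are small (autopsy n = 44; serum n = 207) and
reduced otherwise (prodromal n = 90), with seeds equal to replicate
indices. Parameter recovery uses 100 seeds: a planted hazard ratio of 2 at
n = 500 (mean estimate required in [1.85, 2.15]) and a planted −0.10
z/yr-per-log-unit trajectory interaction at 150 subjects × 4 visits (mean
within ±0.02). The end-to-end check plants AD-like effects on three
sphingolipid analogs across all three cohorts (reduced sizes: 44 autopsy,
90 preclinical, 105 prodromal) and requires the planted set's median
EASE-AD to beat the non-planted panel median in ≥95 of 100 seeds. These
sizes were chosen once as the suite's study conditions and are stated here
so the computational scale of every claim is explicit.

## Known limitations

* The proportional-odds fit assumes proportional odds across all distinct
  outcome values; no formal test of that assumption is run.
* The mixed model assumes Gaussian residuals and linear time trends; the
  generator matches those assumptions, so recovery tests are well-posed but
  say nothing about robustness to misspecification.
* Printed adjusted rank-correlation magnitudes in small published analyses
  of this design are not directly comparable across estimator variants;
  this package's estimator is the standard residualized-rank partial
  correlation and is validated against its own oracles, not against any
  published coefficient table.
* The pipeline consumes the atrophy index and CSF assay values as given
  numbers; their derivation is out of scope, as are batch normalization
  against QC plasma and any pathway-level interpretation.
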