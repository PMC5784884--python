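# easead

Brain metabolite signature discovery and endophenotype association scoring
for early Alzheimer disease (AD).

## The problem

Blood biomarker studies of AD usually compare diagnosed cases with controls,
ignoring the long preclinical window in which pathology accumulates silently.
An alternative design starts in the brain: identify the metabolites whose
*brain tissue* concentrations discriminate neuropathologically confirmed AD
from controls, then ask whether the *blood* concentrations of those same
metabolites track quantitative disease endophenotypes — pathology severity at
autopsy, risk of conversion to incident AD, cognitive trajectories, MRI
atrophy, and CSF markers — in people who are not yet demented.

`easead` implements that framework as a tested, reusable pipeline over
targeted metabolomics concentration tables (absolute μM values with
below-limit-of-detection flags), together with a synthetic cohort generator
that plants known, recoverable effects so every stage can be validated
without access-restricted cohort data.

## Pipeline

1. **Preprocess** (`easead.preprocess`) — serum-quality exclusion on
   methionine sulfoxide (Met-So > 5 μM), per-cohort limit-of-detection
   imputation dialects (`highest_below_lod`, `half_lod`, `none`), duplicate
   averaging, natural-log transform, and ±2-year storage-time matching
   (maximum bipartite matching) for sensitivity analyses.
2. **Discover** (`easead.discovery`) — leave-one-out (LOO) cross-validation
   of a linear-kernel SVM (per-fold recursive feature elimination; rank =
   selection frequency across folds) and a random forest (rank = out-of-bag
   permutation importance, i.e., mean decrease in OOB accuracy); the region
   with the best LOO accuracy defines the signature; the union of the two
   top-*k* lists is the panel.
3. **Composites** (`easead.composites`) — domain cognitive composites
   (memory, attention, executive, language, visuospatial) from baseline-
   standardized test z-scores, with records after symptom onset removed.
4. **Battery** (`easead.battery`) — ten association categories per panel
   metabolite, all age- and sex-adjusted, p-values deliberately uncorrected:
   proportional-odds group differences (AD/ASYMAD/CN; rank-based score test,
   the regression generalization of Wilcoxon/Kruskal–Wallis), adjusted
   Spearman correlations with CERAD and Braak scores, Cox models for
   conversion (hazard ratio per 1 log-unit concentration), linear mixed
   models for metabolite × time effects on cognitive slopes, and OLS for the
   SPARE-AD atrophy index and ln CSF Aβ1–42 / t-tau / p-tau.
5. **Score** (`easead.scoring`) — cognitive domains collapse into one
   category; each significant cell is coded AD-like (red) or protective
   (green) against a per-category polarity map; the **EASE-AD score** is the
   count of significant cells per metabolite (0–10), and the ranked grid is
   exported as TSV/heat map.

A synthetic-cohort module (`easead.synthetic`) emulates all three study
designs — an autopsy cohort with group shifts confined to one brain region,
a preclinical serum cohort with proportional-hazards conversion and biennial
cognitive visits, and a prodromal CN/MCI/AD cohort with linear
metabolite–endophenotype effects — from a single seed with independent
substreams.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on a small
synthetic study (seed 0) with AD-like effects planted on four
sphingolipid-analog metabolites (SM001–SM004):

```bash
cd analysis
python 01_simulate_cohorts.py
python 02_preprocess.py
python 03_discover_signature.py
python 04_endophenotype_battery.py
python 05_ease_ad_score.py
```

Stage 3 prints the LOO metrics and picks the planted region:

```
  ITG svm:  96.55% / 100.00% /  92.86%
  ITG rf :  89.66% / 100.00% /  78.57%
selected region: ITG
panel: 15 metabolites (5 consensus, top-10 of each ranking)
```

Stage 5 prints the final scores — the planted sphingolipid analogs dominate
the grid, exactly the separation the score is designed to surface:

```
EASE-AD scores (significant associations across 10 categories):
  SM002     9 *planted*
  SM001     8 *planted*
  SM004     8 *planted*
  SM003     7 *planted*
  AA005     4
  ...
median EASE-AD — planted sphingolipid analogs: 8.0, other panel members: 1.0
```

Intermediate tables (cohorts, QC summaries, ranked lists, battery results,
the heat-map TSV and PNG) land under `results/`. The same pipeline is
available as one call: `easead.run_full(easead.demo_pipeline_config(seed))`,
which re-runs byte-identically for a fixed seed.

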