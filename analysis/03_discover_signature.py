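#!/usr/bin/env python
"""Discover the brain metabolite signature by dual machine-learning ranking.

Evaluates a linear-margin classifier (with per-fold recursive feature
elimination) and a random forest by leave-one-out cross-validation on
AD vs CN samples in each brain region, picks the best-discriminating
region, ranks metabolites by SVM selection frequency and by RF out-of-bag
permutation importance, and combines the two top-k lists into the
signature panel.
"""

import pandas as pd

from common import CONFIG, RESULTS, load_processed_cohorts

from easead.discovery import (
    ClassifierSpec,
    build_panel,
    loo_evaluate,
    rank_rf,
    rank_svm,
    select_region,
)
from easead.io import write_table

OUT = RESULTS / "03_signature"


def main() -> None:
    brain = load_processed_cohorts()["brain"]
    meta = brain.metadata
    svm_spec = ClassifierSpec("svm", n_selected=CONFIG.svm_n_selected, C=CONFIG.svm_C)
    rf_spec = ClassifierSpec("rf", n_trees=CONFIG.rf_n_trees)

    metrics, cache = {}, {}
    for region, mat in brain.concentrations.items():
        sel = meta[(meta["region"] == region) & meta["group"].isin(["AD", "CN"])]
        X = mat.values.loc[sel["sample_id"]]
        y = sel["group"].to_numpy()
        loo_svm = loo_evaluate(X, y, svm_spec, seed=CONFIG.seed)
        loo_rf = loo_evaluate(X, y, rf_spec, seed=CONFIG.seed)
        metrics[region] = {"svm": loo_svm.metrics, "rf": loo_rf.metrics}
        cache[region] = (loo_svm, X, y)

    print("LOO metrics (accuracy / sensitivity / specificity, AD positive):")
    rows = []
    for region, ms in metrics.items():
        for clf, m in ms.items():
            rows.append({"region": region, "classifier": clf,
                         "accuracy": round(m.accuracy, 2),
                         "sensitivity": round(m.sensitivity, 2),
                         "specificity": round(m.specificity, 2)})
            print(f"  {region} {clf:3s}: {m.accuracy:6.2f}% / "
                  f"{m.sensitivity:6.2f}% / {m.specificity:6.2f}%")
    region = select_region(metrics)
    print(f"selected region: {region}")

    loo_svm, X, y = cache[region]
    svm_list = rank_svm(loo_svm, all_metabolites=X.columns)
    rf_list = rank_rf(X, y, n_trees=CONFIG.rf_n_trees,
                      n_permutations=CONFIG.rf_n_permutations, seed=CONFIG.seed)
    panel = build_panel(svm_list, rf_list, k=CONFIG.k)
    print(f"panel: {len(panel.panel)} metabolites "
          f"({len(panel.consensus)} consensus, top-{CONFIG.k} of each ranking)")
    print("  " + ", ".join(panel.panel))

    OUT.mkdir(parents=True, exist_ok=True)
    write_table(pd.DataFrame(rows), OUT / "loo_metrics.tsv")
    ranked = pd.concat([
        pd.DataFrame([(i + 1, m, s, lst.classifier)
                      for i, (m, s) in enumerate(lst.entries)],
                     columns=["rank", "metabolite", "score", "classifier"])
        for lst in (svm_list, rf_list)])
    write_table(ranked, OUT / "ranked_lists.tsv")
    (OUT / "panel.txt").write_text("\n".join(panel.panel) + "\n")
    (OUT / "region.txt").write_text(region + "\n")


if __name__ == "__main__":
    main()
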