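#!/usr/bin/env python
"""Fit the ten endophenotype association categories for every panel metabolite.

Brain categories (signature region): proportional-odds group differences
(AD/ASYMAD/CN), covariate-adjusted Spearman correlations with CERAD and
Braak scores. Preclinical serum: Cox conversion hazard per log-unit and
mixed-model cognitive slopes per domain (converters, pre-onset). Prodromal
serum: OLS on the atrophy index and ln CSF markers, plus MCI→AD Cox. All
models adjust for age and sex; p-values are uncorrected by design.
"""

from common import CONFIG, RESULTS, load_processed_cohorts

from easead.battery import results_to_frame, run_battery
from easead.io import write_table

OUT = RESULTS / "04_battery"


def main() -> None:
    cohorts = load_processed_cohorts()
    panel = (RESULTS / "03_signature" / "panel.txt").read_text().split()
    region = (RESULTS / "03_signature" / "region.txt").read_text().strip()
    results = run_battery(
        panel, brain=cohorts["brain"], preclinical=cohorts["preclinical"],
        prodromal=cohorts["prodromal"], alpha=CONFIG.alpha, region=region)
    frame = results_to_frame(results, alpha=CONFIG.alpha)
    OUT.mkdir(parents=True, exist_ok=True)
    write_table(frame, OUT / "battery_results.tsv")

    sig = frame[frame["significant"]]
    print(f"battery: {len(frame)} model fits over {len(panel)} panel metabolites, "
          f"{len(sig)} significant at α={CONFIG.alpha} (uncorrected)")
    for cat, grp in sig.groupby("category"):
        mets = ", ".join(sorted(set(grp["metabolite"])))
        print(f"  {cat:14s}: {mets}")


if __name__ == "__main__":
    main()
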