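#!/usr/bin/env python
"""Summarize the battery as the EASE-AD score and export the heat map.

Collapses the five cognitive domains into one category, codes every
significant association against its category's AD-like polarity
(red = AD-like, green = protective), counts significant cells per
metabolite (max 10) and writes the ranked grid as TSV plus a raster
heat map.
"""

from common import CONFIG, PLANTED, RESULTS, load_processed_cohorts

from easead.battery import frame_to_results
from easead.io import read_table
from easead.scoring import PolarityMap, compute_ease_ad, plot_heatmap, write_heatmap_tsv

OUT = RESULTS / "05_score"


def main() -> None:
    frame = read_table(RESULTS / "04_battery" / "battery_results.tsv")
    region = (RESULTS / "03_signature" / "region.txt").read_text().strip()
    families = load_processed_cohorts()["brain"].concentrations[region].families
    table = compute_ease_ad(
        frame_to_results(frame), PolarityMap(), alpha=CONFIG.alpha,
        families=families)
    OUT.mkdir(parents=True, exist_ok=True)
    write_heatmap_tsv(table, OUT / "ease_ad_heatmap.tsv")
    plot_heatmap(table, OUT / "ease_ad_heatmap.png")

    print("EASE-AD scores (significant associations across 10 categories):")
    for met, score in table.ease_ad.items():
        marker = " *planted*" if met in PLANTED else ""
        print(f"  {met:8s} {score:2d}{marker}")
    planted_scores = table.ease_ad.loc[[m for m in PLANTED if m in table.ease_ad.index]]
    others = table.ease_ad.drop(planted_scores.index)
    print(f"median EASE-AD — planted sphingolipid analogs: "
          f"{planted_scores.median():.1f}, other panel members: {others.median():.1f}")


if __name__ == "__main__":
    main()
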