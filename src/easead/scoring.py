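"""EASE-AD: the Endophenotype Association Score in Early Alzheimer Disease.

The battery's per-domain cognitive results are collapsed into a single
category (significant in any domain), every significant association is coded
against the category's AD-like polarity (red = AD-like, green = protective),
and each metabolite's EASE-AD score is its count of significant cells across
the ten categories (max 10). The exported grid is the heat-map source: rows
sorted by score, cells in {+1 AD-like, −1 protective, 0 not significant}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .battery import CATEGORIES, DOMAINS, EndophenotypeResult

ADLIKE = "adlike_significant"
PROTECTIVE = "protective_significant"
NOT_SIG = "not_significant"

#: AD-like direction of the metabolite effect per category. "increase" means a
#: higher metabolite concentration accompanies the AD-like end of the
#: endophenotype (e.g. HR > 1 for conversion, positive slope on the atrophy
#: index, negative slope on cognition — coded via the estimate's sign).
DEFAULT_POLARITY = {
    "brain_group": "increase",    # AD group at the high-concentration extreme
    "cerad": "increase",
    "braak": "increase",
    "blsa_cox": "increase",       # HR > 1
    "blsa_cognition": "decrease",  # faster decline: negative slope per log-unit
    "spare_ad": "increase",
    "csf_abeta": "decrease",      # lower Aβ1-42 is AD-like
    "csf_ttau": "increase",
    "csf_ptau": "increase",
    "adni_cox": "increase",
}

#: Tie-break order for row sorting within equal scores: sphingolipids first,
#: then glycerophospholipids, then everything else.
_CLASS_ORDER = {"sphingolipid": 0, "glycerophospholipid": 1}


@dataclass
class PolarityMap:
    """Per-category AD-like direction; every category mapped exactly once."""

    directions: dict = field(default_factory=lambda: dict(DEFAULT_POLARITY))

    def __post_init__(self) -> None:
        missing = set(CATEGORIES) - set(self.directions)
        if missing:
            raise ValueError(f"polarity missing categories: {sorted(missing)}")

    def __getitem__(self, category: str) -> str:
        if category not in self.directions:
            raise KeyError(f"category {category!r} missing from polarity map")
        return self.directions[category]


@dataclass
class CollapsedCell:
    significant: bool
    direction: str          # "increase" | "decrease"
    conflict: bool = False  # significant domains disagreed on direction


def collapse_cognitive(
    domain_results: Sequence[EndophenotypeResult],
    alpha: float = 0.05,
) -> CollapsedCell:
    """Collapse per-domain trajectory results into one cognition cell.

    Significant iff any domain is significant; direction = majority
    direction among significant domains; an exact tie takes the direction of
    the first domain in the fixed order and records a conflict flag.
    """
    if not domain_results:
        raise ValueError("need at least one domain result")
    ordered = sorted(
        domain_results,
        key=lambda r: DOMAINS.index(r.domain) if r.domain in DOMAINS else len(DOMAINS),
    )
    sig = [r for r in ordered if r.significant(alpha)]
    if not sig:
        return CollapsedCell(False, ordered[0].direction)
    n_inc = sum(r.direction == "increase" for r in sig)
    n_dec = len(sig) - n_inc
    distinct = len({r.direction for r in sig}) > 1
    if n_inc != n_dec:
        direction = "increase" if n_inc > n_dec else "decrease"
        return CollapsedCell(True, direction, conflict=distinct)
    return CollapsedCell(True, sig[0].direction, conflict=True)


def code_direction(
    result: EndophenotypeResult,
    polarity: PolarityMap,
    alpha: float = 0.05,
) -> str:
    """Tri-state coding of one result against the category's AD-like polarity."""
    if not result.significant(alpha):
        return NOT_SIG
    return ADLIKE if result.direction == polarity[result.category] else PROTECTIVE


@dataclass
class EaseAdTable:
    """Metabolite × category tri-state grid plus the integer score per row."""

    cells: pd.DataFrame        # rows metabolites, columns CATEGORIES, values {+1,-1,0}
    ease_ad: pd.Series         # per metabolite, = count of nonzero cells
    conflicts: pd.Series       # cognition direction-conflict flag per metabolite

    def to_frame(self) -> pd.DataFrame:
        out = self.cells.copy()
        out["ease_ad"] = self.ease_ad
        return out


def compute_ease_ad(
    results: Iterable[EndophenotypeResult],
    polarity: PolarityMap | None = None,
    alpha: float = 0.05,
    families: pd.Series | None = None,
    adlike_only: bool = False,
) -> EaseAdTable:
    """Build the scored grid from the battery's uniform results.

    ``results`` may contain several cognition rows per metabolite (one per
    domain); they are collapsed here. The score counts significant cells
    regardless of AD-like vs. protective direction (the strict AD-like-only
    variant is available behind ``adlike_only``). Rows sort by score
    descending, ties by metabolite class (sphingolipids, then
    glycerophospholipids, then others), then lexicographically.
    """
    polarity = polarity or PolarityMap()
    by_met: dict[str, dict[str, list[EndophenotypeResult]]] = {}
    for r in results:
        slot = by_met.setdefault(r.metabolite_id, {})
        if r.category == "blsa_cognition":
            slot.setdefault("blsa_cognition", []).append(r)
        else:
            if r.category in slot:
                raise ValueError(
                    f"duplicate result for ({r.metabolite_id}, {r.category})")
            slot[r.category] = [r]

    rows, scores, conflicts = {}, {}, {}
    for met, slots in by_met.items():
        cells = {}
        conflict = False
        for cat in CATEGORIES:
            if cat not in slots:
                cells[cat] = 0
                continue
            if cat == "blsa_cognition":
                collapsed = collapse_cognitive(slots[cat], alpha)
                conflict = collapsed.conflict
                if not collapsed.significant:
                    cells[cat] = 0
                    continue
                state = (ADLIKE if collapsed.direction == polarity[cat]
                         else PROTECTIVE)
            else:
                state = code_direction(slots[cat][0], polarity, alpha)
            cells[cat] = {ADLIKE: 1, PROTECTIVE: -1, NOT_SIG: 0}[state]
        if adlike_only:
            scores[met] = int(sum(v == 1 for v in cells.values()))
        else:
            scores[met] = int(sum(v != 0 for v in cells.values()))
        rows[met] = cells
        conflicts[met] = conflict

    def sort_key(met: str):
        fam = families.get(met, "") if families is not None else ""
        return (-scores[met], _CLASS_ORDER.get(fam, 2), met)

    order = sorted(rows, key=sort_key)
    cells = pd.DataFrame([rows[m] for m in order], index=order, columns=list(CATEGORIES))
    return EaseAdTable(
        cells,
        pd.Series({m: scores[m] for m in order}, name="ease_ad").loc[order],
        pd.Series({m: conflicts[m] for m in order}, name="conflict").loc[order],
    )


def write_heatmap_tsv(table: EaseAdTable, path) -> None:
    """Heat-map TSV: category columns in fixed order, final ``ease_ad`` column."""
    table.to_frame().to_csv(path, sep="\t", index_label="metabolite")


def plot_heatmap(table: EaseAdTable, path) -> None:
    """Optional raster export with the red/green/gray encoding."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    data = table.cells.to_numpy()
    fig, ax = plt.subplots(
        figsize=(8, max(2.0, 0.3 * len(table.cells))), constrained_layout=True)
    cmap = ListedColormap(["#2ca02c", "#d3d3d3", "#d62728"])  # green/gray/red
    ax.imshow(data, cmap=cmap, vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(len(table.cells.columns)))
    ax.set_xticklabels(table.cells.columns, rotation=45, ha="right", fontsize=8)
    ax.set_yticks(range(len(table.cells)))
    ax.set_yticklabels(
        [f"{m} ({s})" for m, s in table.ease_ad.items()], fontsize=7)
    ax.set_title("Metabolite × endophenotype associations (EASE-AD in parentheses)")
    fig.savefig(path, dpi=150)
    plt.close(fig)
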