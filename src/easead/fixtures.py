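"""Packaged fixtures: the published signature-panel membership.

The printed top-metabolite table gives the 26-metabolite brain signature
panel (13 consensus metabolites starred as common to both classifier
rankings) plus hexose (h1), which was dropped from the panel because it was
not assayed in the prodromal serum dataset — a 27-member pre-exclusion
union. The table encodes membership only, not within-list order, and does
not say which ranking each unique metabolite came from; this fixture
therefore fixes an arbitrary-but-deterministic assignment (h1 to the RF
list, the printed non-consensus metabolites split 7 SVM / 6 RF in printed
order) and builds demo ranked lists consistent with it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .discovery import RankedList

#: Starred consensus metabolites (top-20 of both rankings).
TABLE3_CONSENSUS = (
    "lysoPC a C18:0",
    "PC aa C40:4",
    "PC aa C40:6",
    "PC ae C34:0",
    "PC ae C36:0",
    "PC ae C42:3",
    "Spermidine",
    "SM C16:1",
    "SM C24:1",
    "SM C26:1",
    "SM (OH) C22:1",
    "SM (OH) C22:2",
    "SM (OH) C24:1",
)

#: Panel members unique to one ranking, in printed order.
TABLE3_NONCONSENSUS = (
    "Arg",
    "C3",
    "lysoPC a C17:0",
    "PC aa C38:4",
    "PC aa C40:5",
    "PC ae C34:2",
    "PC ae C36:3",
    "PC ae C36:4",
    "PC ae C40:1",
    "Serotonin",
    "SM C16:0",
    "SM C18:1",
    "SM (OH) C14:1",
)

#: In the union but excluded from the panel: not assayed in the prodromal set.
TABLE3_EXCLUDED = {"h1": "not available in the prodromal serum dataset"}

_FAMILY = {
    "Arg": "amino acid",
    "C3": "acylcarnitine",
    "Serotonin": "biogenic amine",
    "Spermidine": "biogenic amine",
    "h1": "hexose",
}


def _family(met: str) -> str:
    if met in _FAMILY:
        return _FAMILY[met]
    if met.startswith("SM"):
        return "sphingolipid"
    return "glycerophospholipid"


@dataclass
class Table3Fixture:
    consensus: tuple
    svm_unique: tuple
    rf_unique: tuple
    excluded: dict
    panel: tuple                 # the 26 published panel members
    families: pd.Series
    svm_ranked: RankedList
    rf_ranked: RankedList


def load_table_fixtures(name: str) -> Table3Fixture:
    """Return a packaged fixture bundle by name (currently only ``"table3"``)."""
    if name != "table3":
        raise KeyError(f"unknown fixture {name!r}")
    svm_unique = TABLE3_NONCONSENSUS[:7]
    rf_unique = TABLE3_NONCONSENSUS[7:] + ("h1",)
    # demo ranked lists consistent with the membership: consensus metabolites
    # occupy the best ranks of both lists, unique members fill the remainder,
    # and each list carries the other's unique members below rank 20
    svm_entries = (
        [(m, float(29 - i)) for i, m in enumerate(TABLE3_CONSENSUS + svm_unique)]
        + [(m, float(5 - 0.1 * i)) for i, m in enumerate(rf_unique)]
    )
    rf_entries = (
        [(m, round(0.20 - 0.005 * i, 4)) for i, m in enumerate(TABLE3_CONSENSUS + rf_unique)]
        + [(m, round(0.01 - 0.0005 * i, 5)) for i, m in enumerate(svm_unique)]
    )
    panel = TABLE3_CONSENSUS + TABLE3_NONCONSENSUS
    members = panel + ("h1",)
    families = pd.Series({m: _family(m) for m in members}, name="family")
    return Table3Fixture(
        consensus=TABLE3_CONSENSUS,
        svm_unique=svm_unique,
        rf_unique=rf_unique,
        excluded=dict(TABLE3_EXCLUDED),
        panel=panel,
        families=families,
        svm_ranked=RankedList("svm", svm_entries),
        rf_ranked=RankedList("rf", rf_entries),
    )
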