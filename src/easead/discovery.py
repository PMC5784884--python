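"""Brain metabolite signature discovery.

Two classifiers with different inductive biases are evaluated per brain
region by leave-one-out (LOO) cross-validation on AD vs. CN samples (the
ASYMAD group is deliberately excluded from signature definition):

* a linear-kernel margin classifier (SVM) with per-fold recursive feature
  elimination down to ``n_selected`` metabolites — a metabolite's rank is the
  number of LOO folds in which it was selected;
* a random forest — LOO supplies the performance metrics, while ranking uses
  out-of-bag (OOB) permutation importance of a single forest fit on all
  samples (mean decrease in OOB accuracy when a metabolite's column is
  permuted).

The union of the two top-k lists, minus assay-availability exclusions, is
the signature panel carried into the blood analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import RFE
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

POSITIVE_CLASS = "AD"
REGION_ORDER = ("MFG", "ITG", "CBL")


@dataclass
class ClassifierSpec:
    """Configuration of one classifier arm."""

    kind: str                       # "svm" | "rf"
    n_selected: int = 20            # RFE target (svm only)
    C: float = 1.0                  # margin regularization (svm only)
    rfe_step: float = 0.2           # fraction of features dropped per RFE round
    n_trees: int = 500              # forest size (rf only)


@dataclass
class ClassifierMetrics:
    """Pooled LOO confusion counts and derived percentages (AD positive)."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / (self.tp + self.fn + self.tn + self.fp)

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)


@dataclass
class LooResult:
    metrics: ClassifierMetrics
    selections: list[frozenset]                  # per-fold selected features
    fold_weights: list[dict]                     # per-fold |margin weight| (svm)


@dataclass
class RankedList:
    classifier: str
    entries: list[tuple[str, float]]             # sorted by score descending

    def top(self, k: int) -> list[str]:
        return [m for m, _ in self.entries[:k]]


@dataclass
class SignaturePanel:
    consensus: list[str]
    svm_unique: list[str]
    rf_unique: list[str]
    excluded: dict = field(default_factory=dict)  # metabolite -> reason
    panel: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# LOO evaluation
# ---------------------------------------------------------------------------
def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def loo_evaluate(
    values: pd.DataFrame,
    labels: Sequence[str],
    spec: ClassifierSpec,
    seed: int = 0,
) -> LooResult:
    """Leave-one-out evaluation with per-fold embedded feature selection.

    Each fold standardizes features by training-fold mean/SD (no leakage),
    runs the classifier's selection step, fits, and predicts the held-out
    sample; metrics pool the held-out predictions.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("exactly two classes required (AD vs CN)")
    if min((labels == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 samples per class")
    X = values.to_numpy(dtype=float)
    cols = values.columns.to_numpy()
    n, p = X.shape
    if spec.kind == "svm" and spec.n_selected > p:
        raise ValueError("n_selected exceeds the number of metabolites")

    preds = np.empty(n, dtype=object)
    selections: list[frozenset] = []
    fold_weights: list[dict] = []
    rng = np.random.default_rng(seed)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        Xtr, Xte = _standardize(X[tr], X[~tr])
        ytr = labels[tr]
        if spec.kind == "svm":
            est = SVC(kernel="linear", C=spec.C)
            if spec.n_selected < p:
                rfe = RFE(est, n_features_to_select=spec.n_selected, step=spec.rfe_step)
                rfe.fit(Xtr, ytr)
                sel = rfe.support_
            else:
                sel = np.ones(p, dtype=bool)
            clf = SVC(kernel="linear", C=spec.C).fit(Xtr[:, sel], ytr)
            preds[i] = clf.predict(Xte[:, sel])[0]
            selections.append(frozenset(cols[sel]))
            w = np.abs(np.asarray(clf.coef_).ravel())
            fold_weights.append(dict(zip(cols[sel], w)))
        elif spec.kind == "rf":
            forest = _fit_bagged_forest(
                Xtr, ytr, spec.n_trees, int(rng.integers(2 ** 31)))
            preds[i] = _forest_predict(forest, Xte)[0]
            selections.append(frozenset())
            fold_weights.append({})
        else:
            raise ValueError(f"unknown classifier kind: {spec.kind!r}")
    pos = labels == POSITIVE_CLASS
    hit = preds == labels
    metrics = ClassifierMetrics(
        tp=int((hit & pos).sum()), fn=int((~hit & pos).sum()),
        tn=int((hit & ~pos).sum()), fp=int((~hit & ~pos).sum()),
    )
    return LooResult(metrics, selections, fold_weights)


# ---------------------------------------------------------------------------
# hand-bagged forest with OOB bookkeeping
# ---------------------------------------------------------------------------
@dataclass
class _Forest:
    trees: list
    boot_idx: list[np.ndarray]
    classes: np.ndarray
    n_samples: int


def _fit_bagged_forest(X, y, n_trees: int, seed: int) -> _Forest:
    """Bootstrap-aggregated CART trees with √p features per split.

    Bagging is done here (rather than via a library forest) so that each
    tree's out-of-bag sample set is known exactly, which OOB permutation
    importance requires.
    """
    rng = np.random.default_rng(seed)
    n = len(y)
    classes = np.unique(y)
    ycode = np.searchsorted(classes, y)
    trees, boots = [], []
    for _ in range(n_trees):
        idx = rng.integers(0, n, n)
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2 ** 31)))
        tree.fit(X[idx], ycode[idx])
        trees.append(tree)
        boots.append(idx)
    return _Forest(trees, boots, classes, n)


def _forest_predict(forest: _Forest, X) -> np.ndarray:
    votes = np.zeros((len(X), len(forest.classes)), dtype=int)
    for tree in forest.trees:
        pred = tree.predict(X).astype(int)
        votes[np.arange(len(X)), pred] += 1
    # ties break toward the lexicographically first class
    return forest.classes[votes.argmax(axis=1)]


def _oob_accuracy(forest: _Forest, X, ycode) -> float:
    n = forest.n_samples
    votes = np.zeros((n, len(forest.classes)), dtype=int)
    for tree, idx in zip(forest.trees, forest.boot_idx):
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        if oob.any():
            pred = tree.predict(X[oob]).astype(int)
            votes[np.flatnonzero(oob), pred] += 1
    covered = votes.sum(axis=1) > 0
    pred = votes.argmax(axis=1)
    return float((pred[covered] == ycode[covered]).mean())


def rank_rf(
    values: pd.DataFrame,
    labels: Sequence[str],
    n_trees: int = 500,
    n_permutations: int = 10,
    seed: int = 0,
) -> RankedList:
    """Rank metabolites by OOB permutation importance of one full-data forest.

    Importance = baseline OOB accuracy minus the mean OOB accuracy over
    ``n_permutations`` independent permutations of the metabolite's column.
    Ties break lexicographically on metabolite id.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    if n_trees < 1:
        raise ValueError("n_trees must be positive")
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("exactly two classes required")
    X = values.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    forest = _fit_bagged_forest(X, labels, n_trees, int(rng.integers(2 ** 31)))
    ycode = np.searchsorted(forest.classes, labels)
    base = _oob_accuracy(forest, X, ycode)
    scores = {}
    for j, met in enumerate(values.columns):
        drop = 0.0
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(X)), j]
            drop += base - _oob_accuracy(forest, Xp, ycode)
        scores[met] = drop / n_permutations
    entries = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankedList("rf", entries)


def rank_svm(loo: LooResult, all_metabolites: Sequence[str] | None = None) -> RankedList:
    """Rank metabolites by LOO selection frequency.

    Score = number of folds in which the metabolite survived recursive
    elimination (in [0, n folds]); ties break by mean |margin-model weight|
    across the folds that selected it, then lexicographically. Metabolites
    in ``all_metabolites`` that no fold selected are listed with score 0.
    """
    if not loo.selections:
        raise ValueError("no fold selections recorded")
    counts: dict[str, int] = {}
    wsums: dict[str, list] = {}
    for sel, weights in zip(loo.selections, loo.fold_weights):
        for met in sel:
            counts[met] = counts.get(met, 0) + 1
            wsums.setdefault(met, []).append(weights.get(met, 0.0))
    all_mets = set().union(*loo.selections)
    if all_metabolites is not None:
        all_mets |= set(all_metabolites)
    entries = sorted(
        ((m, float(counts.get(m, 0))) for m in all_mets),
        key=lambda kv: (-kv[1], -float(np.mean(wsums.get(kv[0], [0.0]))), kv[0]),
    )
    return RankedList("svm", entries)


# ---------------------------------------------------------------------------
# panel and region selection
# ---------------------------------------------------------------------------
def build_panel(
    svm: RankedList,
    rf: RankedList,
    k: int = 20,
    exclude: Mapping[str, str] | Sequence[str] = (),
) -> SignaturePanel:
    """Combine the two top-k lists into the signature panel.

    Consensus = intersection of the top-k lists; unique = each list's
    remainder; panel = union minus exclusions, consensus first, then by each
    metabolite's best rank across the two lists.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if len(svm.entries) < k or len(rf.entries) < k:
        raise ValueError("ranked lists shorter than k")
    top_s, top_r = svm.top(k), rf.top(k)
    cons = [m for m in top_s if m in set(top_r)]
    s_uni = [m for m in top_s if m not in set(top_r)]
    r_uni = [m for m in top_r if m not in set(top_s)]
    excl = dict(exclude) if isinstance(exclude, Mapping) else {m: "excluded" for m in exclude}
    best_rank = {}
    for lst in (top_s, top_r):
        for i, m in enumerate(lst):
            best_rank[m] = min(best_rank.get(m, k), i)
    union = sorted(set(top_s) | set(top_r), key=lambda m: (m not in set(cons), best_rank[m], m))
    panel = [m for m in union if m not in excl]
    return SignaturePanel(cons, s_uni, r_uni, {m: r for m, r in excl.items() if m in set(union)}, panel)


def select_region(metrics: Mapping[str, Mapping[str, ClassifierMetrics]]) -> str:
    """Pick the brain region whose classifiers discriminate AD vs CN best.

    Maximum mean accuracy across classifiers; ties break by SVM accuracy,
    then by the fixed anatomical order MFG, ITG, CBL.
    """
    if not metrics:
        raise ValueError("no regions supplied")

    def key(region: str):
        ms = metrics[region]
        mean_acc = float(np.mean([m.accuracy for m in ms.values()]))
        svm_acc = ms.get("svm").accuracy if "svm" in ms else -1.0
        order = REGION_ORDER.index(region) if region in REGION_ORDER else len(REGION_ORDER)
        return (-mean_acc, -svm_acc, order)

    return min(metrics, key=key)
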