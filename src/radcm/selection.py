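"""Symptom selection: RAD-ranked backward elimination and an MRMR baseline.

The RAD selector ranks symptoms by their contribution to the syndrome,
C(symptom | syndrome) = P(symptom = 1 | syndrome = 1), then removes the
lowest-ranked symptom one at a time, re-evaluating a classifier at every
subset size and keeping the subset with the best cross-validated
G-means. The MRMR (minimum redundancy, maximum relevance) baseline
greedily ranks symptoms by mutual information with the label penalised
by mean mutual information with the already-selected symptoms, and the
same wrapper evaluates its nested prefixes — so the two selectors differ
only in the ranking they feed the identical wrapper.

To avoid selection leakage, rankings are recomputed on the training
portion of every fold by default; ``rank_on_all=True`` restores the
naive variant that ranks once on the full data set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC

from .data_model import CaseTable
from .evaluation import EvaluationProtocol, confusion, metrics

RankFn = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass
class ClassifierSpec:
    """Classifier family + hyperparameters used inside the wrapper.

    family
        ``svm``: max-margin linear classifier (hinge loss, L2 penalty)
        with regularization strength ``c``.
        ``knn``: k-nearest-neighbour majority vote with ``k`` neighbours;
        vote ties (possible for even ``k``) break toward the positive
        class.
    """

    family: Literal["svm", "knn"] = "svm"
    c: float = 1.0
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("svm", "knn"):
            raise ValueError(f"unknown classifier family {self.family!r}")
        if self.c <= 0:
            raise ValueError("regularization strength c must be > 0")
        if self.k < 1:
            raise ValueError("neighbour count k must be >= 1")

    def build(self):
        if self.family == "svm":
            return LinearSVC(C=self.c, random_state=self.seed)
        return _TieBreakingKNN(k=self.k)


class _TieBreakingKNN:
    """kNN majority vote; exact 50/50 vote ties go to the positive class."""

    def __init__(self, k: int) -> None:
        self.k = k
        self._m = KNeighborsClassifier(n_neighbors=k)

    def fit(self, X, y):
        self._m.fit(X, y)
        return self

    def predict(self, X):
        proba = self._m.predict_proba(X)
        if proba.shape[1] == 1:  # training fold had one class
            return np.full(len(X), int(self._m.classes_[0]))
        pos = list(self._m.classes_).index(1)
        return (proba[:, pos] >= 0.5).astype(int)


@dataclass
class SelectionResult:
    """Outcome of one wrapper run for one syndrome.

    ranking
        All symptoms ordered best-first by the selector's criterion on
        the full data (the elimination order is its reverse).
    trace
        ``(subset_size, gmeans)`` for every size from S down to 1.
    selected
        The subset attaining the best G-means (ties go to the smallest
        subset).
    """

    syndrome: str
    selector: Literal["rad", "mrmr", "none"]
    ranking: list[str]
    scores: list[float]
    trace: list[tuple[int, float]]
    selected: list[str]
    best_gmeans: float
    classifier: ClassifierSpec = field(repr=False, default=None)  # type: ignore[assignment]
    protocol: EvaluationProtocol = field(repr=False, default=None)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        return {
            "syndrome": self.syndrome,
            "selector": self.selector,
            "ranking": self.ranking,
            "scores": self.scores,
            "trace": [[int(s), float(g)] for s, g in self.trace],
            "selected": self.selected,
            "best_gmeans": float(self.best_gmeans),
        }


def mutual_information(x: Sequence[int], y: Sequence[int]) -> float:
    """Plug-in mutual information of two binary vectors, in bits.

    Uses the empirical 2x2 joint with the convention 0*log(0) = 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = x.size
    mi = 0.0
    for xv in (0, 1):
        for yv in (0, 1):
            pxy = ((x == xv) & (y == yv)).sum() / n
            if pxy == 0.0:
                continue
            px = (x == xv).sum() / n
            py = (y == yv).sum() / n
            mi += pxy * math.log2(pxy / (px * py))
    return max(mi, 0.0)


def _rad_scores(F: np.ndarray, y: np.ndarray) -> np.ndarray:
    pos = y.sum()
    if pos == 0:
        raise ValueError("label never positive; RAD ranking undefined")
    return (F[y == 1].sum(axis=0)) / pos


def _rad_order(F: np.ndarray, y: np.ndarray) -> np.ndarray:
    # stable descending sort: ties keep column order
    return np.argsort(-_rad_scores(F, y), kind="stable")


def rad_rank(table: CaseTable, syndrome: str) -> list[tuple[str, float]]:
    """Rank symptoms by contribution to ``syndrome``, best first.

    The score of symptom *i* is C(F_i | L_j) = (cases with both) /
    (cases with the syndrome); ties keep the table's column order.
    """
    y = table.syndrome_column(syndrome)
    scores = _rad_scores(table.F, y)
    order = _rad_order(table.F, y)
    return [(table.symptom_names[i], float(scores[i])) for i in order]


def _mi_table(F: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised plug-in MI: (relevance vector, pairwise MI matrix)."""
    n, s = F.shape
    rel = np.array([mutual_information(F[:, i], y) for i in range(s)])
    red = np.zeros((s, s))
    for i in range(s):
        for j in range(i + 1, s):
            red[i, j] = red[j, i] = mutual_information(F[:, i], F[:, j])
    return rel, red


def _mrmr_order(
    F: np.ndarray,
    y: np.ndarray,
    n_select: int | None = None,
    criterion: Literal["mid", "miq"] = "mid",
    redundancy_weight: float = 1.0,
) -> np.ndarray:
    s = F.shape[1]
    n_select = s if n_select is None else n_select
    rel, red = _mi_table(F, y)
    selected: list[int] = []
    remaining = list(range(s))
    eps = 1e-12
    while remaining and len(selected) < n_select:
        if not selected:
            crit = rel[remaining]
        else:
            mean_red = red[np.ix_(remaining, selected)].mean(axis=1)
            if criterion == "mid":
                crit = rel[remaining] - redundancy_weight * mean_red
            else:  # miq
                crit = rel[remaining] / (redundancy_weight * mean_red + eps)
        best = remaining[int(np.argmax(crit))]  # argmax keeps column order on ties
        selected.append(best)
        remaining.remove(best)
    return np.asarray(selected)


def mrmr_rank(
    table: CaseTable,
    syndrome: str,
    n_select: int | None = None,
    *,
    criterion: Literal["mid", "miq"] = "mid",
    redundancy_weight: float = 1.0,
) -> list[str]:
    """Greedy MRMR ranking of symptoms for ``syndrome``.

    First picks the symptom with maximal MI with the label; each further
    pick maximises relevance minus (MID) or over (MIQ) the mean MI with
    the already-selected symptoms. Ties keep column order.
    """
    s = table.n_symptoms
    n_sel = s if n_select is None else n_select
    if not 1 <= n_sel <= s:
        raise ValueError(f"n_select must be in [1, {s}]")
    y = table.syndrome_column(syndrome)
    order = _mrmr_order(table.F, y, n_sel, criterion, redundancy_weight)
    return [table.symptom_names[i] for i in order]


def _wrapper_select(
    table: CaseTable,
    syndrome: str,
    selector: Literal["rad", "mrmr"],
    clf: ClassifierSpec,
    protocol: EvaluationProtocol,
    rank_on_all: bool,
    rank_fn: RankFn,
) -> SelectionResult:
    y = table.syndrome_column(syndrome)
    protocol.check_feasible(y)
    X = table.F.astype(float)
    s = table.n_symptoms
    splits = list(protocol.splits(y))
    full_order = rank_fn(table.F, y)

    # per-split ranking (leakage-safe default), or the full-data ranking
    orders = []
    for train, _ in splits:
        if rank_on_all:
            orders.append(full_order)
        else:
            orders.append(rank_fn(table.F[train], y[train]))

    # pooled confusion at every subset size
    conf = {size: [0, 0, 0, 0] for size in range(1, s + 1)}
    for (train, test), order in zip(splits, orders):
        for size in range(1, s + 1):
            cols = order[:size]
            model = clf.build()
            model.fit(X[np.ix_(train, cols)], y[train])
            pred = model.predict(X[np.ix_(test, cols)])
            tp, tn, fp, fn = confusion(pred, y[test])
            c = conf[size]
            c[0] += tp; c[1] += tn; c[2] += fp; c[3] += fn

    trace: list[tuple[int, float]] = []
    for size in range(s, 0, -1):
        rep = metrics(*conf[size], syndrome=syndrome)
        gm = rep.gmeans if rep.gmeans is not None else 0.0
        trace.append((size, gm))
    # best G-means; ties -> smallest subset
    best_size, best_gm = min(trace, key=lambda t: (-t[1], t[0]))

    if selector == "rad":
        scores = _rad_scores(table.F, y)  # contribution C(F_i | L_j)
    else:
        scores = np.array([mutual_information(table.F[:, i], y) for i in range(s)])
    ranking = [table.symptom_names[i] for i in full_order]
    return SelectionResult(
        syndrome=syndrome,
        selector=selector,
        ranking=ranking,
        scores=[float(scores[i]) for i in full_order],
        trace=trace,
        selected=ranking[:best_size],
        best_gmeans=best_gm,
        classifier=clf,
        protocol=protocol,
    )


def rad_select(
    table: CaseTable,
    syndrome: str,
    clf: ClassifierSpec,
    protocol: EvaluationProtocol,
    *,
    rank_on_all: bool = False,
) -> SelectionResult:
    """Backward-elimination wrapper driven by the RAD ranking.

    Symptoms with low RAD contribution to the syndrome are removed one
    by one (full sweep S -> 1); the classifier is evaluated at every
    step and the subset with the highest pooled G-means is returned.
    """
    return _wrapper_select(table, syndrome, "rad", clf, protocol,
                           rank_on_all, _rad_order)


def mrmr_select(
    table: CaseTable,
    syndrome: str,
    clf: ClassifierSpec,
    protocol: EvaluationProtocol,
    *,
    rank_on_all: bool = False,
    criterion: Literal["mid", "miq"] = "mid",
) -> SelectionResult:
    """Wrapper over nested prefixes of the MRMR ranking (sizes 1..S).

    Structurally identical to :func:`rad_select` so the two selectors
    are compared on the ranking alone.
    """
    fn: RankFn = lambda F, y: _mrmr_order(F, y, criterion=criterion)
    return _wrapper_select(table, syndrome, "mrmr", clf, protocol,
                           rank_on_all, fn)
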