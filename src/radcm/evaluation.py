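"""Classifier evaluation: stratified protocols and TPR/TNR/G-means.

For imbalanced syndrome labels overall accuracy is dominated by the
majority class, so prediction quality is reported as the true positive
rate TPR = TP/(TP+FN), the true negative rate TNR = TN/(FP+TN), and
their geometric mean G-means = sqrt(TPR * TNR), which is high only when
both classes are predicted well. Confusion counts are pooled across
cross-validation folds before the rates are computed, so every case
contributes exactly once and the pooled rates are defined whenever the
label has both classes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import TYPE_CHECKING, Iterator, Literal, Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .data_model import CaseTable

if TYPE_CHECKING:  # pragma: no cover
    from .selection import ClassifierSpec


def round3(x: float) -> float:
    """Round to 3 decimals, half away from zero (report formatting)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


@dataclass
class EvaluationProtocol:
    """How to split cases for wrapper evaluation.

    scheme
        ``stratified_kfold`` (default) or ``holdout``.
    folds
        Number of folds for k-fold (>= 2).
    train_fraction
        Training fraction for the holdout scheme.
    seed
        Governs fold shuffling; recorded in all outputs.
    """

    scheme: Literal["stratified_kfold", "holdout"] = "stratified_kfold"
    folds: int = 5
    train_fraction: float = 0.8
    seed: int = 42

    def __post_init__(self) -> None:
        if self.scheme == "stratified_kfold" and self.folds < 2:
            raise ValueError("stratified k-fold needs folds >= 2")
        if self.scheme == "holdout" and not 0.0 < self.train_fraction < 1.0:
            raise ValueError("holdout train_fraction must be in (0, 1)")

    def check_feasible(self, y: np.ndarray) -> None:
        pos = int(y.sum())
        neg = int(len(y) - pos)
        if pos == 0 or neg == 0:
            raise ValueError("label has a single class; evaluation is undefined")
        if self.scheme == "stratified_kfold" and min(pos, neg) < self.folds:
            raise ValueError(
                f"minority class has {min(pos, neg)} cases but the protocol "
                f"uses {self.folds} folds; use fewer folds"
            )

    def splits(self, y: np.ndarray) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        self.check_feasible(y)
        X = np.zeros((len(y), 1))
        if self.scheme == "stratified_kfold":
            cv = StratifiedKFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
        else:
            cv = StratifiedShuffleSplit(
                n_splits=1, train_size=self.train_fraction, random_state=self.seed
            )
        yield from cv.split(X, y)


def confusion(pred: Sequence[int], truth: Sequence[int]) -> tuple[int, int, int, int]:
    """Return ``(tp, tn, fp, fn)`` for binary prediction vs truth."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 1 or pred.size < 1:
        raise ValueError("pred and truth must be equal-length 1-d vectors")
    tp = int(((pred == 1) & (truth == 1)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    return tp, tn, fp, fn


@dataclass
class MetricReport:
    """Confusion counts and rates for one syndrome label.

    ``tpr``/``tnr``/``gmeans`` are ``None`` when the corresponding
    denominator is zero (undefined, never reported as 0).
    """

    syndrome: str
    tp: int
    tn: int
    fp: int
    fn: int
    tpr: Optional[float]
    tnr: Optional[float]
    gmeans: Optional[float]

    def to_json(self, **extra) -> str:
        d = asdict(self)
        d.update(extra)
        return json.dumps(d, sort_keys=True, indent=2)

    def text_row(self) -> str:
        fmt = lambda v: "undefined" if v is None else f"{round3(v):.3f}"
        return (
            f"{self.syndrome}\tTP={self.tp} TN={self.tn} FP={self.fp} FN={self.fn}\t"
            f"TPR={fmt(self.tpr)}\tTNR={fmt(self.tnr)}\tG-means={fmt(self.gmeans)}"
        )


def metrics(tp: int, tn: int, fp: int, fn: int, syndrome: str = "") -> MetricReport:
    """Compute TPR, TNR and G-means from confusion counts."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    tpr = tp / (tp + fn) if (tp + fn) > 0 else None
    tnr = tn / (fp + tn) if (fp + tn) > 0 else None
    gm = math.sqrt(tpr * tnr) if (tpr is not None and tnr is not None) else None
    return MetricReport(syndrome=syndrome, tp=tp, tn=tn, fp=fp, fn=fn,
                        tpr=tpr, tnr=tnr, gmeans=gm)


def evaluate(
    table: CaseTable,
    syndrome: str,
    symptom_subset: Sequence[str],
    clf: "ClassifierSpec",
    protocol: EvaluationProtocol,
) -> MetricReport:
    """Cross-validated metrics for one syndrome using a symptom subset.

    Trains the classifier on each training split restricted to
    ``symptom_subset``, predicts the held-out cases, pools the confusion
    counts over splits and computes the metric suite. Deterministic for
    a fixed protocol seed and classifier spec.
    """
    if len(symptom_subset) == 0:
        raise ValueError("symptom_subset must be non-empty")
    idx = [table.symptom_names.index(s) for s in symptom_subset]
    X = table.F[:, idx].astype(float)
    y = table.syndrome_column(syndrome)
    tp = tn = fp = fn = 0
    for train, test in protocol.splits(y):
        model = clf.build()
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        a, b, c, d = confusion(pred, y[test])
        tp, tn, fp, fn = tp + a, tn + b, fp + c, fn + d
    return metrics(tp, tn, fp, fn, syndrome=syndrome)


def summarize(reports: Sequence[MetricReport]) -> dict:
    """Average a set of per-syndrome reports.

    Returns the arithmetic means of TPR and TNR, and the summary G-means
    under both common conventions, each labelled: the mean of the
    per-syndrome G-means values (``gmeans_mean``) and the geometric mean
    of the averaged rates, sqrt(meanTPR * meanTNR)
    (``gmeans_of_mean_rates``).
    """
    if not reports:
        raise ValueError("summarize needs at least one report")
    if any(r.tpr is None or r.tnr is None for r in reports):
        raise ValueError("summarize needs reports with defined rates")
    mean_tpr = float(np.mean([r.tpr for r in reports]))
    mean_tnr = float(np.mean([r.tnr for r in reports]))
    return {
        "syndromes": [r.syndrome for r in reports],
        "mean_tpr": mean_tpr,
        "mean_tnr": mean_tnr,
        "gmeans_mean": float(np.mean([r.gmeans for r in reports])),
        "gmeans_of_mean_rates": math.sqrt(mean_tpr * mean_tnr),
    }
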