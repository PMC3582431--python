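"""Evaluation: one-vs-rest counting with rejection, ROC sweeps, cross-validation.

The multiclass classifier is scored with binary ROC curves by nominating one
class as positive and pooling the rest as negative.  The counting rules keep
totals conserved under rejection:

* TP — positives predicted as the positive class;
* FN — positives predicted as any other class *or left unclassified*;
* FP — negatives predicted as the positive class;
* TN — everything else: negatives correctly placed, negatives confused with
  a *different* negative class, and unclassified negatives.  Cross-negative
  confusions count as true negatives because the instance was correctly kept
  out of the positive class.

FPR = FP / (FP + TN) and TPR = TP / (TP + FN).  The ROC sweep re-thresholds
a single set of decoded posteriors over a grid of rejection thresholds
(default 0.30 to 0.99 in steps of 0.01, 70 points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .codes import CodingMatrix, ap_matrix, ovr_matrix, random_code_matrix
from .datasets import LabeledDataset
from .model import (
    UNCLASSIFIED,
    McRUMModel,
    decode_posteriors,
    predict_batch,
    train_mcrum,
)

__all__ = [
    "EvalCounts",
    "RocPoint",
    "one_vs_rest_counts",
    "rates",
    "roc_sweep",
    "roc_table",
    "CVResult",
    "cross_validate",
    "make_code",
]


@dataclass(frozen=True)
class EvalCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    fpr: float
    tpr: float
    unclassified_fraction: float


def one_vs_rest_counts(true_labels, predictions, positive_class: str) -> EvalCounts:
    """Confusion counts for one positive class under the rejection rules."""
    true_labels = [str(t) for t in true_labels]
    predictions = [str(p) for p in predictions]
    if len(true_labels) != len(predictions):
        raise ValueError("labels and predictions must align")
    if positive_class not in set(true_labels):
        raise ValueError(f"positive class {positive_class!r} absent from labels")
    tp = fp = tn = fn = 0
    for t, p in zip(true_labels, predictions):
        if t == positive_class:
            if p == positive_class:
                tp += 1
            else:  # wrong class or UNCLASSIFIED
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:  # correct, cross-negative confusion, or UNCLASSIFIED
                tn += 1
    return EvalCounts(tp, fp, tn, fn)


def rates(counts: EvalCounts) -> tuple[float, float]:
    """(FPR, TPR) = (FP / (FP + TN), TP / (TP + FN))."""
    if counts.fp + counts.tn == 0:
        raise ValueError("no negative instances: FPR undefined")
    if counts.tp + counts.fn == 0:
        raise ValueError("no positive instances: TPR undefined")
    return (
        counts.fp / (counts.fp + counts.tn),
        counts.tp / (counts.tp + counts.fn),
    )


def roc_sweep(
    model: McRUMModel,
    data: LabeledDataset,
    positive_class: str,
    decoder: str = "naive",
    t_min: float = 0.30,
    t_max: float = 0.99,
    step: float = 0.01,
) -> list[RocPoint]:
    """ROC points over a rejection-threshold grid.

    Posteriors are decoded once and re-thresholded per grid point, so the
    positive and negative totals are conserved across the sweep.
    """
    if not (0.0 <= t_min <= t_max < 1.0 and step > 0):
        raise ValueError("invalid threshold grid")
    n_steps = int(round((t_max - t_min) / step))
    thresholds = np.round(t_min + step * np.arange(n_steps + 1), 10)
    P = decode_posteriors(model, data.features, decoder=decoder)
    argmax = np.argmax(P, axis=1)
    top = P[np.arange(P.shape[0]), argmax]
    names = model.class_names
    points = []
    for t in thresholds:
        labels = [
            names[k] if s >= t else UNCLASSIFIED for k, s in zip(argmax, top)
        ]
        counts = one_vs_rest_counts(data.labels, labels, positive_class)
        fpr, tpr = rates(counts)
        unc = sum(l == UNCLASSIFIED for l in labels) / data.n
        points.append(RocPoint(float(t), fpr, tpr, unc))
    return points


def roc_table(points: list[RocPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "threshold": [p.threshold for p in points],
            "fpr": [p.fpr for p in points],
            "tpr": [p.tpr for p in points],
            "unclassified_fraction": [p.unclassified_fraction for p in points],
        }
    )


def make_code(kind: str, K: int, L: int | None = None, seed: int = 0) -> CodingMatrix:
    """Decomposition by name: "ap", "ovr", "dense" or "sparse"."""
    if kind == "ap":
        return ap_matrix(K)
    if kind == "ovr":
        return ovr_matrix(K)
    if kind in ("dense", "sparse"):
        if L is None:
            L = K
        return random_code_matrix(K, L, kind=kind, seed=seed)
    raise ValueError(f"unknown decomposition {kind!r}")


@dataclass
class CVResult:
    accuracies: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0


def cross_validate(
    data: LabeledDataset,
    folds: int,
    decomp: str | CodingMatrix = "ap",
    decoder: str = "naive",
    seed: int = 0,
    M: int | str = "auto",
    gamma: float | str = "auto",
    threshold: float = 0.0,
    standardize: bool = True,
    L: int | None = None,
) -> CVResult:
    """Stratified k-fold cross-validated accuracy.

    An UNCLASSIFIED prediction counts as an error (it can only arise when
    ``threshold`` > 0; the benchmark protocol uses threshold 0, where every
    input receives the argmax class).
    """
    if folds < 2:
        raise ValueError("need at least two folds")
    code = decomp if isinstance(decomp, CodingMatrix) else make_code(
        decomp, data.n_classes, L=L, seed=seed
    )
    y = data.class_indices()
    counts = np.bincount(y, minlength=data.n_classes)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} instances, fewer than {folds} folds; "
            "use fewer folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(data.features, y):
        model = train_mcrum(
            data.subset(train_idx), code, M=M, gamma=gamma, seed=seed,
            standardize=standardize,
        )
        test = data.subset(test_idx)
        preds = predict_batch(model, test.features, decoder=decoder, threshold=threshold)
        correct = sum(p.label == t for p, t in zip(preds, test.labels))
        accs.append(correct / test.n)
    return CVResult(accs)
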