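"""Clinical screening metrics for murmur and outcome prediction.

``weighted_accuracy`` implements the class-weighted recall-style score used
for three-class murmur grading, with weights 5 / 3 / 1 on true Present /
Unknown / Absent patients, so that missing a murmur-present patient is
penalised most.  ``outcome_cost`` is the mean per-patient screening cost
composed of four pluggable components: running the algorithm, expert review
of algorithm-positive patients, treatment of true positives and the cost of
a missed (untreated) abnormal outcome.

The default cost components follow the published George B. Moody PhysioNet
Challenge 2022 cost model (external provenance; they are inputs to this
package, not results of it):

    c_algorithm(n_p)        = 10 * n_p
    c_expert(s, n_p)        = (25 + 397 (s/n_p) - 1718 (s/n_p)^2
                               + 11296 (s/n_p)^4) * n_p
    c_treatment(n_TP)       = 10000 * n_TP
    c_error(n_FN)           = 50000 * n_FN

where s = n_TP + n_FP is the number of patients sent to an expert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn import metrics as skm

MURMUR_CLASSES = ("Present", "Unknown", "Absent")
UNDEFINED = float("nan")


@dataclass
class MurmurConfusion:
    """3x3 counts; ``counts[i, j]`` = predicted class i, true class j."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3) or (self.counts < 0).any():
            raise ValueError("confusion must be a non-negative 3x3 matrix")

    @classmethod
    def from_labels(cls, predicted, true,
                    classes: tuple[str, ...] = MURMUR_CLASSES) -> "MurmurConfusion":
        counts = np.zeros((3, 3), dtype=np.int64)
        for p, t in zip(predicted, true):
            counts[classes.index(p), classes.index(t)] += 1
        return cls(counts)


@dataclass
class OutcomeCounts:
    n_tp: int
    n_fp: int
    n_fn: int
    n_tn: int

    def __post_init__(self):
        if min(self.n_tp, self.n_fp, self.n_fn, self.n_tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")

    @property
    def n_patients(self) -> int:
        return self.n_tp + self.n_fp + self.n_fn + self.n_tn

    @classmethod
    def from_labels(cls, predicted, true,
                    positive: str = "Abnormal") -> "OutcomeCounts":
        p = np.asarray([x == positive for x in predicted])
        t = np.asarray([x == positive for x in true])
        return cls(int(np.sum(p & t)), int(np.sum(p & ~t)),
                   int(np.sum(~p & t)), int(np.sum(~p & ~t)))


def _default_expert_cost(n_screened: float, n_patients: float) -> float:
    f = n_screened / n_patients
    return (25.0 + 397.0 * f - 1718.0 * f ** 2 + 11296.0 * f ** 4) * n_patients


@dataclass
class CostParams:
    """Pluggable cost components of the outcome screening cost."""

    c_algorithm: Callable[[float], float] = field(
        default=lambda n_p: 10.0 * n_p)
    c_expert: Callable[[float, float], float] = field(
        default=_default_expert_cost)
    c_treatment: Callable[[float], float] = field(
        default=lambda n_tp: 10000.0 * n_tp)
    c_error: Callable[[float], float] = field(
        default=lambda n_fn: 50000.0 * n_fn)


def weighted_accuracy(confusion: MurmurConfusion,
                      weights: tuple[float, float, float] = (5.0, 3.0, 1.0)) -> float:
    """Class-weighted accuracy over (Present, Unknown, Absent) patients.

    numerator = 5 m_PP + 3 m_UU + m_AA; denominator weights each true-class
    column total by the same 5/3/1 factors.
    """
    m = confusion.counts
    w = np.asarray(weights, dtype=np.float64)
    denom = float(np.sum(w * m.sum(axis=0)))
    if denom <= 0:
        raise ValueError("confusion matrix is empty")
    return float(np.sum(w * np.diag(m)) / denom)


def outcome_cost(counts: OutcomeCounts,
                 params: CostParams | None = None) -> float:
    """Mean per-patient screening cost with the supplied cost components."""
    params = params or CostParams()
    n_p = counts.n_patients
    total = (params.c_algorithm(n_p)
             + params.c_expert(counts.n_tp + counts.n_fp, n_p)
             + params.c_treatment(counts.n_tp)
             + params.c_error(counts.n_fn))
    return float(total / n_p)


def standard_metrics(scores, labels) -> dict[str, float]:
    """AUROC, AUPRC, F1 and accuracy for binary scores/labels.

    Ranking metrics are NaN when only one class is present.  ``scores`` are
    probabilities of the positive class; hard decisions use 0.5.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    out: dict[str, float] = {}
    if len(np.unique(y)) < 2:
        out["auroc"] = UNDEFINED
        out["auprc"] = UNDEFINED
    else:
        out["auroc"] = float(skm.roc_auc_score(y, s))
        out["auprc"] = float(skm.average_precision_score(y, s))
    pred = (s >= 0.5).astype(int)
    out["f1"] = float(skm.f1_score(y, pred, zero_division=0))
    out["accuracy"] = float(skm.accuracy_score(y, pred))
    return out


def multiclass_metrics(prob_matrix, labels,
                       classes: tuple[str, ...] = MURMUR_CLASSES) -> dict[str, float]:
    """Macro one-vs-rest AUROC/AUPRC, macro F1 and accuracy for 3 classes."""
    probs = np.asarray(prob_matrix, dtype=np.float64)
    y_idx = np.asarray([classes.index(lab) for lab in labels])
    pred_idx = probs.argmax(axis=1)
    out = {
        "f1": float(skm.f1_score(y_idx, pred_idx, average="macro",
                                 zero_division=0)),
        "accuracy": float(skm.accuracy_score(y_idx, pred_idx)),
    }
    aurocs, auprcs = [], []
    for c in range(len(classes)):
        y_bin = (y_idx == c).astype(int)
        if len(np.unique(y_bin)) < 2:
            continue
        aurocs.append(skm.roc_auc_score(y_bin, probs[:, c]))
        auprcs.append(skm.average_precision_score(y_bin, probs[:, c]))
    out["auroc"] = float(np.mean(aurocs)) if aurocs else UNDEFINED
    out["auprc"] = float(np.mean(auprcs)) if auprcs else UNDEFINED
    return out
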