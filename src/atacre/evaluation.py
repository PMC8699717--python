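"""Model evaluation: multiclass metrics, naive threshold baselines, and
Fisher exact overlap tests.

Metrics follow the conventions used for multiclass annotation benchmarks:
micro-averaging pools all (class, example) decisions; the Matthews
correlation coefficient uses the generalized (Gorodkin) multiclass formula;
average precision is the step integral of the precision-recall curve.  The
naive baseline assigns promoter by TSS distance, then insulator by CTCF
motif count, then enhancer versus other by the peak caller's FDR q-value —
priority promoters first, then insulators — emitting hard 0/1 probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import fisher_exact
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)

from .genomic_io import CLASS_NAMES


@dataclass
class MetricReport:
    """Confusion matrix (rows = truth, cols = predicted) plus summary and
    per-class scores.  Per-class ROC AUC is None when the truth is degenerate
    (a single class present)."""

    confusion: np.ndarray
    accuracy: float
    micro_average_precision: float
    micro_f1: float
    mcc: float
    per_class: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "micro_average_precision": self.micro_average_precision,
            "micro_f1": self.micro_f1,
            "mcc": self.mcc,
            "per_class": self.per_class,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def confusion_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("truth\\pred\t" + "\t".join(CLASS_NAMES) + "\n")
            for name, row in zip(CLASS_NAMES, self.confusion):
                fh.write(name + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def _label_indices(labels: Sequence) -> np.ndarray:
    out = []
    for lab in labels:
        value = getattr(lab, "value", lab)
        if isinstance(value, str):
            out.append(CLASS_NAMES.index(value))
        else:
            out.append(int(value))
    return np.array(out, dtype=int)


def compute_metrics(true_labels: Sequence, probs: np.ndarray) -> MetricReport:
    """Evaluate 4-class probability predictions against true labels."""
    y = _label_indices(true_labels)
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 4:
        raise ValueError("probs must be (n, 4)")
    if len(y) != len(probs):
        raise ValueError("labels and probabilities must be aligned")
    pred = probs.argmax(axis=1)
    onehot = np.eye(4)[y]

    conf = confusion_matrix(y, pred, labels=range(4))
    acc = float((pred == y).mean())
    micro_ap = float(average_precision_score(onehot, probs, average="micro"))
    micro_f1 = float(f1_score(y, pred, average="micro"))
    mcc = float(matthews_corrcoef(y, pred))

    per_class: dict[str, dict] = {}
    for k, name in enumerate(CLASS_NAMES):
        present = 0 < onehot[:, k].sum() < len(y)
        per_class[name] = {
            "average_precision": float(
                average_precision_score(onehot[:, k], probs[:, k])
            )
            if onehot[:, k].sum() > 0
            else None,
            "roc_auc": float(roc_auc_score(onehot[:, k], probs[:, k]))
            if present
            else None,
            "f1": float(f1_score(y == k, pred == k)),
        }
    return MetricReport(conf, acc, micro_ap, micro_f1, mcc, per_class)


# ---------------------------------------------------------------------------
# naive threshold baseline
# ---------------------------------------------------------------------------

TSS_DISTANCE_MENU = (1000, 2000, 5000)
QVAL_MENU = (0.01, 0.001, 0.0001)
CTCF_COUNT_MENU = (0, 2, 4)


@dataclass(frozen=True)
class NaiveThresholds:
    """Best-performing thresholds by default: promoter within 2 kb of a TSS,
    enhancer at FDR q <= 0.001, insulator at CTCF motif count > 0."""

    tss_distance_bp: int = 2000
    qval_threshold: float = 0.001
    ctcf_min_count: int = 0  # rule: count > value


def naive_classify(
    tss_distance: float,
    ctcf_count: int,
    qval: Optional[float] = None,
    neglog10_qval: Optional[float] = None,
    thresholds: NaiveThresholds = NaiveThresholds(),
) -> str:
    """Threshold-based annotation with total priority: promoter, then
    insulator, then enhancer-vs-other by q-value.  Supply the q-value either
    raw (``qval``) or as ``neglog10_qval``; the internal canonical form is
    raw q."""
    if abs(tss_distance) <= thresholds.tss_distance_bp:
        return "promoter"
    if ctcf_count > thresholds.ctcf_min_count:
        return "insulator"
    if qval is None:
        if neglog10_qval is None:
            raise ValueError("q-value required to separate enhancer from other")
        qval = 10.0 ** (-neglog10_qval)
    return "enhancer" if qval <= thresholds.qval_threshold else "other"


def naive_probabilities(label: str) -> np.ndarray:
    """Hard 0/1 probability vector for a naive call."""
    out = np.zeros(4)
    out[CLASS_NAMES.index(label)] = 1.0
    return out


# ---------------------------------------------------------------------------
# Fisher exact overlap test
# ---------------------------------------------------------------------------

def fisher_overlap(
    predicted: set,
    reference: set,
    background: set,
) -> tuple[float, float]:
    """Two-sided Fisher exact test for overlap between a predicted peak set
    and a reference peak set within a common background.

    Returns (odds ratio, p).  The odds ratio uses the Haldane 0.5 correction
    when any contingency cell is zero.
    """
    if not background:
        raise ValueError("background set must be non-empty")
    predicted = set(predicted) & set(background)
    reference = set(reference) & set(background)
    a = len(predicted & reference)
    b = len(predicted - reference)
    c = len(reference - predicted)
    d = len(background) - a - b - c
    table = np.array([[a, b], [c, d]])
    _, p = fisher_exact(table, alternative="two-sided")
    if (table == 0).any():
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)
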