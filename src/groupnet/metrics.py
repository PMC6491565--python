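"""Evaluation metrics over the 8 label-powerset classes.

Both model variants are scored on the same 8-class surface: LP
predictions are already class codes, BR per-disease decisions are
recombined into a code first, so the two transformations are directly
comparable.

From the one-vs-rest confusion counts TP_i, TN_i, FP_i, FN_i of each
class i (l = 8 classes) and the class support proportions
k_i = support_i / n:

* accuracy          = mean_i (TP_i + TN_i) / (TP_i + FP_i + TN_i + FN_i),
  the macro-averaged one-vs-rest binary accuracy;
* subset accuracy   = fraction of records whose full label combination is
  exactly right (reported alongside, since the two differ a lot at l = 8);
* precision_weighted = sum_i k_i TP_i / (TP_i + FP_i)
* recall_weighted    = sum_i k_i TP_i / (TP_i + FN_i)
* f1_weighted        = sum_i k_i * harmonic mean of the two.

Because each per-class F1 is at most min(precision_i, recall_i), the
support-weighted F1 is bounded above by both weighted precision and
weighted recall — unlike a plain harmonic mean of the weighted averages.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import N_LP_CLASSES, SplitIndices, lp_encode
from .exceptions import ValidationError


@dataclass
class ConfusionSummary:
    """One-vs-rest confusion counts per LP class."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.tp, self.tn, self.fp, self.fn):
            if arr.shape != (N_LP_CLASSES,):
                raise ValidationError(f"expected {N_LP_CLASSES} per-class counts")

    @property
    def n(self) -> int:
        return int(self.tp[0] + self.tn[0] + self.fp[0] + self.fn[0])

    @property
    def supports(self) -> np.ndarray:
        return self.tp + self.fn

    @property
    def k(self) -> np.ndarray:
        """Class proportions k_i = support_i / n."""
        return self.supports / self.n


@dataclass
class MetricsReport:
    """The metric suite plus a per-class breakdown."""

    accuracy: float
    subset_accuracy: float
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float
    per_class: list[dict]

    def to_json(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "subset_accuracy": self.subset_accuracy,
            "precision_weighted": self.precision_weighted,
            "recall_weighted": self.recall_weighted,
            "f1_weighted": self.f1_weighted,
            "per_class": self.per_class,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=2)

    def table(self) -> str:
        rows = [
            ("accuracy", self.accuracy),
            ("subset_accuracy", self.subset_accuracy),
            ("precision_weighted", self.precision_weighted),
            ("recall_weighted", self.recall_weighted),
            ("f1_weighted", self.f1_weighted),
        ]
        width = max(len(name) for name, _ in rows)
        return "\n".join(f"{name:<{width}}  {value:.4f}" for name, value in rows)


def confusion_from_predictions(
    true_lp: np.ndarray, pred_lp: np.ndarray
) -> ConfusionSummary:
    """One-vs-rest confusion counts from true and predicted class codes."""
    true_lp = np.asarray(true_lp)
    pred_lp = np.asarray(pred_lp)
    if true_lp.shape != pred_lp.shape:
        raise ValidationError("true and predicted label vectors differ in length")
    if true_lp.size == 0:
        raise ValidationError("empty prediction vectors")
    for v in (true_lp, pred_lp):
        if v.min() < 0 or v.max() >= N_LP_CLASSES:
            raise ValidationError("LP class out of range {0..7}")
    n = true_lp.size
    tp = np.empty(N_LP_CLASSES)
    fp = np.empty(N_LP_CLASSES)
    fn = np.empty(N_LP_CLASSES)
    for c in range(N_LP_CLASSES):
        t = true_lp == c
        p = pred_lp == c
        tp[c] = np.sum(t & p)
        fp[c] = np.sum(~t & p)
        fn[c] = np.sum(t & ~p)
    tn = n - tp - fp - fn
    return ConfusionSummary(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(cs: ConfusionSummary) -> MetricsReport:
    """Compute the metric suite from one-vs-rest confusion counts."""
    n = cs.n
    if n == 0:
        raise ValidationError("empty confusion summary")
    tp, tn, fp, fn = cs.tp, cs.tn, cs.fp, cs.fn
    k = cs.k

    accuracy = float(np.mean((tp + tn) / n))
    subset_accuracy = float(tp.sum() / n)

    predicted = tp + fp
    never_predicted = np.flatnonzero((predicted == 0) & (cs.supports > 0))
    if never_predicted.size:
        warnings.warn(
            f"classes {never_predicted.tolist()} never predicted: "
            "precision taken as 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted > 0, tp / np.maximum(predicted, 1), 0.0)
        recall = np.where(cs.supports > 0, tp / np.maximum(cs.supports, 1), 0.0)
        pr_sum = precision + recall
        f1 = np.where(pr_sum > 0, 2 * precision * recall / np.maximum(pr_sum, 1e-300), 0.0)

    per_class = [
        {
            "lp_class": c,
            "support": int(cs.supports[c]),
            "k": float(k[c]),
            "precision": float(precision[c]),
            "recall": float(recall[c]),
            "f1": float(f1[c]),
        }
        for c in range(N_LP_CLASSES)
    ]
    return MetricsReport(
        accuracy=accuracy,
        subset_accuracy=subset_accuracy,
        precision_weighted=float(k @ precision),
        recall_weighted=float(k @ recall),
        f1_weighted=float(k @ f1),
        per_class=per_class,
    )


def br_decisions_to_lp(positive_probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Recombine BR per-disease positive probabilities into LP class codes.

    With 2-unit softmax heads, thresholding the positive probability at
    0.5 is the per-head argmax decision.
    """
    return lp_encode((np.asarray(positive_probs) > threshold).astype(int))


def evaluate_model(
    network, cohort, split: SplitIndices, json_path=None
) -> MetricsReport:
    """Score a built network on the test rows of a (standardized) cohort."""
    rows = split.test_rows
    true_lp = lp_encode(cohort.labels[rows])
    probs = network.predict(cohort.features[rows])
    if network.variant == "LP":
        pred_lp = probs.argmax(axis=1)
    else:
        pred_lp = br_decisions_to_lp(probs)
    report = metrics(confusion_from_predictions(true_lp, pred_lp))
    if json_path is not None:
        report.save(json_path)
    return report
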