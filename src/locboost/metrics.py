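"""Multi-label evaluation: per-protein Jaccard accuracy and per-location F1.

For a protein with true label set T and predicted set P, the per-protein
accuracy is the Jaccard index TP/(TP+FP+FN) = |T∩P| / |T∪P|.  Per-location
precision averages, over the proteins *predicted* at that location, the
per-protein ratio TP/(TP+FP); recall averages, over the proteins *truly*
at that location, TP/(TP+FN); F1 is their harmonic mean.  The summary
report carries the mean Jaccard accuracy over proteins (ACC-mean) and the
unweighted mean F1 over locations that occur in truth or prediction
(F1-mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .records import LabelVocabulary


@dataclass
class PredictionSet:
    """Predicted and true location sets for one protein."""

    protein_id: str
    predicted: set[str]
    truth: set[str]


@dataclass
class LocationScores:
    precision: float  # NaN when the location is never predicted
    recall: float  # NaN when the location never occurs in truth
    f1: float
    n_predicted: int  # |P_j|
    n_true: int  # |T_j|


@dataclass
class EvaluationReport:
    per_location: dict[str, LocationScores]
    acc_mean: float
    f1_mean: float

    def to_frame(self) -> pd.DataFrame:
        """Tabular report: one row per location plus two summary rows."""
        rows = [
            {
                "location": name,
                "precision": s.precision,
                "recall": s.recall,
                "F1": s.f1,
                "n_predicted": s.n_predicted,
                "n_true": s.n_true,
            }
            for name, s in self.per_location.items()
        ]
        rows.append({"location": "ACC-mean", "F1": self.acc_mean})
        rows.append({"location": "F1-mean", "F1": self.f1_mean})
        return pd.DataFrame(rows)


def protein_acc(truth: set[str], predicted: set[str]) -> float:
    """Jaccard index |truth ∩ predicted| / |truth ∪ predicted|."""
    if not truth:
        raise ValueError("true label set must be non-empty")
    return len(truth & predicted) / len(truth | predicted)


def f1_harmonic(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def location_prf(
    predictions: list[PredictionSet], location: str,
    vocabulary: LabelVocabulary | None = None,
) -> LocationScores:
    """Precision, recall and F1 of one location.

    Precision averages per-protein TP/(TP+FP) over proteins predicted at
    the location; recall averages per-protein TP/(TP+FN) over proteins
    truly at the location.  An undefined side (empty P_j or T_j) is NaN
    and forces F1 to 0.
    """
    if vocabulary is not None and location not in vocabulary:
        raise KeyError(f"unknown location {location!r}")
    pred_at = [p for p in predictions if location in p.predicted]
    true_at = [p for p in predictions if location in p.truth]
    if pred_at:
        precision = sum(
            len(p.truth & p.predicted) / len(p.predicted) for p in pred_at
        ) / len(pred_at)
    else:
        precision = math.nan
    if true_at:
        recall = sum(
            len(p.truth & p.predicted) / len(p.truth) for p in true_at
        ) / len(true_at)
    else:
        recall = math.nan
    if math.isnan(precision) or math.isnan(recall):
        f1 = 0.0
    else:
        f1 = f1_harmonic(precision, recall)
    return LocationScores(
        precision=precision,
        recall=recall,
        f1=f1,
        n_predicted=len(pred_at),
        n_true=len(true_at),
    )


def evaluate(
    predictions: list[PredictionSet], vocabulary: LabelVocabulary
) -> EvaluationReport:
    """Full report over a prediction list.

    ``acc_mean`` is the mean per-protein Jaccard accuracy; ``f1_mean``
    averages F1 over locations that occur at least once in truth or
    prediction.
    """
    if not predictions:
        raise ValueError("need at least one prediction")
    per_location = {
        name: location_prf(predictions, name) for name in vocabulary
    }
    acc_mean = sum(
        protein_acc(p.truth, p.predicted) for p in predictions
    ) / len(predictions)
    occupied = [
        s.f1
        for s in per_location.values()
        if s.n_predicted + s.n_true > 0
    ]
    f1_mean = sum(occupied) / len(occupied) if occupied else 0.0
    return EvaluationReport(
        per_location=per_location, acc_mean=acc_mean, f1_mean=f1_mean
    )
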