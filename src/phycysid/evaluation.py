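"""Performance matrices, dataset statistics and the stringency table.

Metrics are support-weighted across classes: precision, recall and F1 via
the usual one-vs-rest definitions, specificity as the weighted mean of
per-class TN/(TN+FP), and the false-positive rate as 1 - specificity
(exactly, by construction).  Binary confusion matrices can be rendered in
the compact ``[[TP, FP], [FN, TN]]`` bracket form used in the performance
tables, where the first row holds everything predicted positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .ensemble import SubtypePrediction
from .io import ProteinRecord


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer count grid, rows = true class, columns = predicted class."""

    labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)

    def accuracy(self) -> float:
        arr = self.array
        return float(np.trace(arr) / arr.sum())

    def binary_bracket(self) -> list[list[int]]:
        """[[TP, FP], [FN, TN]] with labels[0] as the positive class."""
        if len(self.labels) != 2:
            raise ValueError("bracket form is binary-only")
        (tp, fn), (fp, tn) = self.array
        return [[int(tp), int(fp)], [int(fn), int(tn)]]

    def __str__(self) -> str:
        if len(self.labels) == 2:
            return json.dumps(self.binary_bracket())
        return json.dumps(self.array.tolist())


@dataclass
class EvaluationReport:
    """The metric set of one model evaluation."""

    accuracy: float
    precision: float
    specificity: float
    recall: float
    fpr: float
    f1: float
    auc_roc: float | None
    confusion: ConfusionMatrix
    cv_accuracy: float | None = None
    cv_error: float | None = None

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy, "precision": self.precision,
            "specificity": self.specificity, "recall": self.recall,
            "fpr": self.fpr, "f1": self.f1,
            "auc_roc": self.auc_roc,
            "cv_accuracy": self.cv_accuracy, "cv_error": self.cv_error,
            "confusion": self.confusion.array.tolist(),
            "labels": list(self.confusion.labels),
        }
        return d


def compute_metrics(y_true, y_pred, scores=None,
                    labels: Sequence[str] | None = None,
                    average: str = "weighted") -> EvaluationReport:
    """Support-weighted metric set plus confusion matrix.

    ``scores`` (per-class probability columns in ``labels`` order, or a 1-D
    positive-class score for binary tasks) enables AUC-ROC; without scores
    the AUC is reported as None.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    if labels is None:
        labels = sorted(set(map(str, y_true)) | set(map(str, y_pred)))
    labels = [str(l) for l in labels]
    y_true = y_true.astype(str)
    y_pred = y_pred.astype(str)

    cm = skm.confusion_matrix(y_true, y_pred, labels=labels)
    support = cm.sum(axis=1)
    total = cm.sum()

    # per-class one-vs-rest specificity, support-weighted
    spec_per_class = np.zeros(len(labels))
    for i in range(len(labels)):
        fp = cm[:, i].sum() - cm[i, i]
        tn = total - cm[i, :].sum() - cm[:, i].sum() + cm[i, i]
        spec_per_class[i] = tn / (tn + fp) if (tn + fp) else 0.0
    weights = support / support.sum() if average == "weighted" \
        else np.full(len(labels), 1 / len(labels))
    specificity = float(spec_per_class @ weights)

    # scores columns follow the sorted label order (sklearn classes_ order)
    auc = None
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        order = sorted(labels)
        if scores.ndim == 1:
            auc = float(skm.roc_auc_score(y_true == order[-1], scores))
        elif len(order) == 2:
            auc = float(skm.roc_auc_score(y_true == order[1], scores[:, 1]))
        else:
            auc = float(skm.roc_auc_score(y_true, scores, labels=order,
                                          multi_class="ovr", average=average))

    return EvaluationReport(
        accuracy=float(skm.accuracy_score(y_true, y_pred)),
        precision=float(skm.precision_score(y_true, y_pred, labels=labels,
                                            average=average, zero_division=0)),
        specificity=specificity,
        recall=float(skm.recall_score(y_true, y_pred, labels=labels,
                                      average=average, zero_division=0)),
        fpr=float(1.0 - specificity),
        f1=float(skm.f1_score(y_true, y_pred, labels=labels, average=average,
                              zero_division=0)),
        auc_roc=auc,
        confusion=ConfusionMatrix(tuple(labels),
                                  tuple(map(tuple, cm.tolist()))),
    )


def expand_binary_bracket(bracket) -> tuple[np.ndarray, np.ndarray]:
    """Label vectors realizing a [[TP, FP], [FN, TN]] count grid.

    Positive class is "1", negative "0"; useful to recompute the metric set
    from a printed confusion matrix.
    """
    (tp, fp), (fn, tn) = bracket
    y_true = np.array(["1"] * tp + ["0"] * fp + ["1"] * fn + ["0"] * tn)
    y_pred = np.array(["1"] * tp + ["1"] * fp + ["0"] * fn + ["0"] * tn)
    return y_true, y_pred


def metrics_from_binary_bracket(bracket) -> EvaluationReport:
    y_true, y_pred = expand_binary_bracket(bracket)
    return compute_metrics(y_true, y_pred, labels=["1", "0"])


def dataset_cysteine_prevalence(records: Sequence[ProteinRecord | str],
                                min_cys: int = 2) -> float:
    """Fraction of sequences containing at least ``min_cys`` cysteines."""
    if not records:
        raise ValueError("empty record list")
    seqs = [r.residues if isinstance(r, ProteinRecord) else str(r)
            for r in records]
    return sum(1 for s in seqs if s.count("C") >= min_cys) / len(seqs)


STRINGENCY_COLUMNS = tuple(range(12, 3, -1))  # 12 down to 4 supporting models


def stringency_table(predictions: Sequence[SubtypePrediction],
                     subtypes: Sequence[str] = ("I1", "I2", "IwI", "II"),
                     ) -> pd.DataFrame:
    """Counts of sequences per (subtype, number of supporting models).

    Rows are subtypes, columns run from 12 supporting models down to 4.
    Frequencies below 4 cannot occur for a modal class of 12 votes over 4
    classes, but any such row would be dropped rather than miscounted.
    """
    table = pd.DataFrame(0, index=list(subtypes),
                         columns=list(STRINGENCY_COLUMNS))
    for p in predictions:
        if p.final_class in table.index and p.frequency in table.columns:
            table.loc[p.final_class, p.frequency] += 1
    table.index.name = "subtype"
    return table


def stringency_cumulative_pct(table: pd.DataFrame) -> pd.DataFrame:
    """Row-wise cumulative percentages, nondecreasing left to right."""
    totals = table.sum(axis=1)
    cum = table.cumsum(axis=1)
    pct = 100.0 * cum.div(totals.replace(0, np.nan), axis=0)
    return pct.fillna(0.0)


def report_table(reports: Mapping[str, EvaluationReport]) -> pd.DataFrame:
    """Stack named EvaluationReports into one table (rows = model names)."""
    rows = {}
    for name, rep in reports.items():
        d = rep.to_dict()
        d["confusion"] = str(rep.confusion)
        d.pop("labels")
        rows[name] = d
    df = pd.DataFrame(rows).T
    df.index.name = "model"
    return df
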