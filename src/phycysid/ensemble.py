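"""The two voting stages.

Stage 1 — Index-TF8M: eight binary classifiers each vote TRUE/FALSE on
"is this a phytocystatin"; the index is the TRUE count (0–8) and a
sequence passes with index >= 4.

Stage 2 — PhyCysID-12M: twelve classifiers each call a subtype
(I1/I2/IwI/II); the final class is the modal call and its vote count is
the "frequency".  Stage 2 only runs on sequences that passed stage 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import TrainedModel

#: frozen stage-1 member list: the models whose cross-validation accuracy
#: cleared the 0.9 cutoff on the reference corpus
TF8M_MEMBERS = ("GB", "AdaBoost", "Bagging", "MLPC", "RF", "QDA", "KNN", "LR")
TF8M_THRESHOLD = 4

#: frozen stage-2 member list (12 models)
SUBTYPE12M_MEMBERS = ("AdaBoost", "MLPC", "RF", "LDA", "RC", "LR", "Bagging",
                      "GB", "Perceptron", "SGDC", "GNB", "KNN")

#: fixed tie priority, ordered by per-class sensitivity (best first)
SUBTYPE_TIE_PRIORITY = ("II", "IwI", "I2", "I1")


@dataclass(frozen=True)
class EnsembleConfig:
    """Which members vote at a stage, and the stage-1 pass threshold."""

    stage: str  # "tf8m" | "subtype12m"
    members: tuple[str, ...]
    vote_threshold: int | None = None
    accuracy_cutoff: float = 0.9

    @classmethod
    def default_tf8m(cls) -> "EnsembleConfig":
        return cls("tf8m", TF8M_MEMBERS, TF8M_THRESHOLD)

    @classmethod
    def default_subtype12m(cls) -> "EnsembleConfig":
        return cls("subtype12m", SUBTYPE12M_MEMBERS, None)


@dataclass(frozen=True)
class BinaryPrediction:
    """Stage-1 verdicts for one sequence."""

    id: str
    verdicts: tuple[tuple[str, bool], ...]  # (member, TRUE?) in member order
    tf8m_index: int
    is_phycys: bool

    @classmethod
    def from_verdicts(cls, seq_id: str,
                      verdicts: Mapping[str, bool] | Sequence[tuple[str, bool]],
                      threshold: int = TF8M_THRESHOLD) -> "BinaryPrediction":
        items = tuple(verdicts.items()) if isinstance(verdicts, Mapping) \
            else tuple(verdicts)
        index = sum(1 for _, v in items if v)
        return cls(seq_id, items, index, index >= threshold)


@dataclass(frozen=True)
class SubtypePrediction:
    """Stage-2 calls for one sequence."""

    id: str
    calls: tuple[tuple[str, str], ...]  # (member, subtype) in member order
    frequency: int
    final_class: str
    tie_broken: bool


def select_members(cv_results: Mapping[str, float],
                   cutoff: float = 0.9) -> list[str]:
    """Members with CV accuracy >= cutoff, ordered by accuracy descending."""
    if not cv_results:
        raise ValueError("empty CV results")
    chosen = sorted((name for name, acc in cv_results.items() if acc >= cutoff),
                    key=lambda name: (-cv_results[name], name))
    if not chosen:
        raise ValueError(
            f"no model reaches CV accuracy {cutoff}; lower the cutoff")
    return chosen


def _as_matrix(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.Series):
        return features.to_numpy(dtype=float)[None, :], [str(features.name)]
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), [str(i) for i in features.index]
    arr = np.asarray(features, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr, [str(i) for i in range(arr.shape[0])]


def tf8m_classify(features, members: Mapping[str, TrainedModel],
                  threshold: int = TF8M_THRESHOLD,
                  expected_size: int = 8) -> list[BinaryPrediction]:
    """Stage-1 vote over a feature row or table.

    ``members`` maps member name to a classifier fitted on the binary task
    (positive class encoded as 1).  Returns one prediction per row.
    """
    if len(members) != expected_size:
        raise ValueError(
            f"stage-1 ensemble needs {expected_size} members, got {len(members)}")
    X, ids = _as_matrix(features)
    votes = {name: np.asarray(model.predict(X)).astype(int)
             for name, model in members.items()}
    out = []
    for i, seq_id in enumerate(ids):
        verdicts = {name: bool(votes[name][i]) for name in members}
        out.append(BinaryPrediction.from_verdicts(seq_id, verdicts, threshold))
    return out


def _break_tie(tied: list[str], row: np.ndarray,
               members: Mapping[str, TrainedModel]) -> str:
    """Resolve a vote tie: summed class probabilities, then fixed priority."""
    proba_sums = dict.fromkeys(tied, 0.0)
    any_proba = False
    for model in members.values():
        proba = model.predict_proba(row[None, :])
        if proba is None:
            continue
        any_proba = True
        classes = list(model.classes_)
        for cls in tied:
            if cls in classes:
                proba_sums[cls] += float(proba[0, classes.index(cls)])
    if any_proba:
        best = max(proba_sums.values())
        tied = [c for c in tied if abs(proba_sums[c] - best) < 1e-12]
        if len(tied) == 1:
            return tied[0]
    for cls in SUBTYPE_TIE_PRIORITY:
        if cls in tied:
            return cls
    return sorted(tied)[0]


def subtype_classify(features, members: Mapping[str, TrainedModel],
                     expected_size: int = 12) -> list[SubtypePrediction]:
    """Stage-2 majority vote over a feature row or table.

    ``members`` maps member name to a classifier fitted on the 4-class
    subtype task.  Ties are resolved by summed predicted probabilities over
    probability-capable members, then by a fixed class priority; tied rows
    are flagged ``tie_broken``.
    """
    if len(members) != expected_size:
        raise ValueError(
            f"stage-2 ensemble needs {expected_size} members, got {len(members)}")
    X, ids = _as_matrix(features)
    calls = {name: np.asarray(model.predict(X)).astype(str)
             for name, model in members.items()}
    out = []
    for i, seq_id in enumerate(ids):
        row_calls = tuple((name, calls[name][i]) for name in members)
        tally = Counter(c for _, c in row_calls)
        frequency = max(tally.values())
        tied = sorted(c for c, n in tally.items() if n == frequency)
        if len(tied) == 1:
            final, tie_broken = tied[0], False
        else:
            final, tie_broken = _break_tie(tied, X[i], members), True
        out.append(SubtypePrediction(seq_id, row_calls, frequency, final,
                                     tie_broken))
    return out
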