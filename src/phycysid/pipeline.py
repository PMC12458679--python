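"""End-to-end training and batch prediction.

``train_bundle`` runs the full two-stage protocol on a labeled corpus:
GG-cleave, featurize, stratified 70/30 split, grid-searched training of
every requested classifier on the binary task, the same on the 4-class
subtype task using only the positive rows, and held-out evaluation of
each member plus the two voting indices.  ``predict_records`` replays the
serving path: cleave, featurize, stage-1 vote, and — for sequences with
Index-TF8M >= 4 — the stage-2 subtype vote.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd

from . import ensemble as ens
from .cleave import CleavedRecord, gg_cut
from .evaluation import EvaluationReport, compute_metrics, report_table
from .features import FEATURE_NAMES, featurize_records
from .io import ProteinRecord, SUBTYPES
from .models import (MODEL_NAMES, TrainedModel, build_zoo, split_dataset,
                     train_with_grid_search)

POSITIVE, NEGATIVE = "1", "0"  # binary task encoding (phytocystatin = "1")


@dataclass
class Bundle:
    """Fitted two-stage model bundle plus the metadata to replay it."""

    stage1: dict[str, TrainedModel]
    stage2: dict[str, TrainedModel]
    tf8m_members: tuple[str, ...]
    subtype_members: tuple[str, ...]
    vote_threshold: int
    feature_names: tuple[str, ...]
    seed: int
    window: int = 50
    keep_glycine: bool = True

    def sidecar(self) -> dict:
        return {
            "seed": self.seed,
            "window": self.window,
            "keep_glycine": self.keep_glycine,
            "vote_threshold": self.vote_threshold,
            "feature_names": list(self.feature_names),
            "tf8m_members": list(self.tf8m_members),
            "subtype_members": list(self.subtype_members),
            "stage1": {n: {"best_grid_point": m.best_grid_point,
                           "cv_accuracy_mean": m.cv_accuracy_mean,
                           "cv_accuracy_sd": m.cv_accuracy_sd}
                       for n, m in self.stage1.items()},
            "stage2": {n: {"best_grid_point": m.best_grid_point,
                           "cv_accuracy_mean": m.cv_accuracy_mean,
                           "cv_accuracy_sd": m.cv_accuracy_sd}
                       for n, m in self.stage2.items()},
        }


def cleave_and_featurize(records: Sequence[ProteinRecord], window: int = 50,
                         keep_glycine: bool = True,
                         scales=None) -> tuple[pd.DataFrame,
                                               list[CleavedRecord]]:
    """GG-cut every record and build the 21-descriptor feature table."""
    cleaved = [gg_cut(r, window=window, keep_glycine=keep_glycine)
               for r in records]
    return featurize_records(cleaved, scales=scales), cleaved


def binary_labels(records: Sequence[ProteinRecord]) -> np.ndarray:
    """Encode subtype labels as positive ("1") and NEG as negative ("0")."""
    out = []
    for r in records:
        if r.label in SUBTYPES:
            out.append(POSITIVE)
        elif r.label == "NEG":
            out.append(NEGATIVE)
        else:
            raise ValueError(
                f"record {r.id!r} has no training label (UNKNOWN)")
    return np.array(out)


def _evaluate_members(models: Mapping[str, TrainedModel], X: pd.DataFrame,
                      y: np.ndarray, labels: Sequence[str]
                      ) -> dict[str, EvaluationReport]:
    reports = {}
    for name, model in models.items():
        scores = model.predict_proba(X)
        rep = compute_metrics(y, model.predict(X), scores=scores,
                              labels=labels)
        rep.cv_accuracy = model.cv_accuracy_mean
        rep.cv_error = model.cv_accuracy_sd
        reports[name] = rep
    return reports


def train_bundle(records: Sequence[ProteinRecord], seed: int = 42,
                 specs: Sequence[str] | None = None,
                 grids: Mapping[str, Mapping[str, list]] | None = None,
                 tf8m_members: Sequence[str] = ens.TF8M_MEMBERS,
                 subtype_members: Sequence[str] = ens.SUBTYPE12M_MEMBERS,
                 vote_threshold: int = ens.TF8M_THRESHOLD,
                 window: int = 50, keep_glycine: bool = True,
                 select_cutoff: float | None = None,
                 ) -> tuple[Bundle, dict[str, pd.DataFrame]]:
    """Train the two stages and report held-out performance tables.

    ``specs`` restricts which classifier families are trained (default: all
    15).  With ``select_cutoff`` set, ensemble members are re-selected from
    stage-1 CV accuracies instead of the frozen lists.
    Returns the bundle and ``{"stage1": ..., "stage2": ...}`` report tables
    (one row per model plus the voting-index row).
    """
    specs = tuple(specs) if specs is not None else MODEL_NAMES
    needed = set(specs) | set(tf8m_members) | set(subtype_members)
    zoo = build_zoo(seed=seed, grids=grids, names=sorted(needed))

    X, _ = cleave_and_featurize(records, window=window,
                                keep_glycine=keep_glycine)
    y_bin = binary_labels(records)

    split1 = split_dataset(X, y_bin, seed=seed)
    stage1 = {name: train_with_grid_search(zoo[name], split1)
              for name in specs}
    for name in tf8m_members:
        if name not in stage1:
            stage1[name] = train_with_grid_search(zoo[name], split1)

    if select_cutoff is not None:
        cv = {n: m.cv_accuracy_mean for n, m in stage1.items()}
        tf8m_members = tuple(ens.select_members(cv, cutoff=select_cutoff))
    else:
        tf8m_members = tuple(tf8m_members)

    labels_bin = [POSITIVE, NEGATIVE]
    reports1 = _evaluate_members(stage1, split1.test_X, split1.test_y,
                                 labels_bin)
    members1 = {n: stage1[n] for n in tf8m_members}
    votes = ens.tf8m_classify(split1.test_X, members1,
                              threshold=vote_threshold,
                              expected_size=len(members1))
    y_vote = np.array([POSITIVE if v.is_phycys else NEGATIVE for v in votes])
    reports1["Index-TF8M"] = compute_metrics(split1.test_y, y_vote,
                                             labels=labels_bin)

    # stage 2: subtype task on the positive rows only
    pos_mask = np.array([r.label in SUBTYPES for r in records])
    pos_ids = [r.id for r, m in zip(records, pos_mask) if m]
    X2 = X.loc[pos_ids]
    y_sub = np.array([r.label for r in records if r.label in SUBTYPES])
    split2 = split_dataset(X2, y_sub, seed=seed)
    subtype_members = tuple(dict.fromkeys(tuple(subtype_members)))
    stage2_names = tuple(dict.fromkeys(specs + subtype_members))
    stage2 = {name: train_with_grid_search(zoo[name], split2)
              for name in stage2_names}
    labels_sub = list(SUBTYPES)
    reports2 = _evaluate_members(stage2, split2.test_X, split2.test_y,
                                 labels_sub)
    members2 = {n: stage2[n] for n in subtype_members}
    calls = ens.subtype_classify(split2.test_X, members2,
                                 expected_size=len(members2))
    y_call = np.array([c.final_class for c in calls])
    reports2["PhyCysID-12M"] = compute_metrics(split2.test_y, y_call,
                                               labels=labels_sub)

    bundle = Bundle(stage1=stage1, stage2=stage2,
                    tf8m_members=tf8m_members,
                    subtype_members=subtype_members,
                    vote_threshold=vote_threshold,
                    feature_names=tuple(X.columns), seed=seed,
                    window=window, keep_glycine=keep_glycine)
    tables = {"stage1": report_table(reports1),
              "stage2": report_table(reports2)}
    return bundle, tables


def predict_records(records: Sequence[ProteinRecord], bundle: Bundle,
                    scales=None) -> pd.DataFrame:
    """Serve a batch: one output row per input sequence.

    Columns: cleavage mode/index, per-member stage-1 index and verdict,
    then — for passing sequences — the 12 per-member subtype calls, the
    winning-vote Frequency and the Final class.  Sequences failing stage 1
    leave the subtype columns empty.
    """
    if tuple(bundle.feature_names) != tuple(FEATURE_NAMES):
        raise ValueError(
            "bundle feature order does not match this featurizer")
    member_cols = list(bundle.subtype_members)
    columns = (["id", "cleavage_mode", "cleavage_index", "tf8m_index",
                "is_phycys"] + member_cols
               + ["Frequency", "Final_class", "tie_broken"])
    if not records:
        return pd.DataFrame(columns=columns)

    X, cleaved = cleave_and_featurize(records, window=bundle.window,
                                      keep_glycine=bundle.keep_glycine,
                                      scales=scales)
    members1 = {n: bundle.stage1[n] for n in bundle.tf8m_members}
    votes = ens.tf8m_classify(X, members1, threshold=bundle.vote_threshold,
                              expected_size=len(members1))

    passing = [i for i, v in enumerate(votes) if v.is_phycys]
    sub_by_row: dict[int, ens.SubtypePrediction] = {}
    if passing:
        members2 = {n: bundle.stage2[n] for n in bundle.subtype_members}
        subs = ens.subtype_classify(X.iloc[passing], members2,
                                    expected_size=len(members2))
        sub_by_row = dict(zip(passing, subs))

    rows = []
    for i, (rec, cl, vote) in enumerate(zip(records, cleaved, votes)):
        row: dict = {"id": rec.id, "cleavage_mode": cl.mode,
                     "cleavage_index": cl.cleavage_index,
                     "tf8m_index": vote.tf8m_index,
                     "is_phycys": vote.is_phycys}
        sub = sub_by_row.get(i)
        if sub is not None:
            row.update(dict(sub.calls))
            row["Frequency"] = sub.frequency
            row["Final_class"] = sub.final_class
            row["tie_broken"] = sub.tie_broken
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)


def tf8m_holdout_accuracy(records: Sequence[ProteinRecord], seed: int = 42,
                          members: Sequence[str] = ens.TF8M_MEMBERS,
                          threshold: int = ens.TF8M_THRESHOLD,
                          grids=None) -> float:
    """Held-out accuracy of the stage-1 voting index on a labeled corpus."""
    X, _ = cleave_and_featurize(records)
    y = binary_labels(records)
    split = split_dataset(X, y, seed=seed)
    zoo = build_zoo(seed=seed, grids=grids, names=sorted(set(members)))
    models = {n: train_with_grid_search(zoo[n], split) for n in members}
    votes = ens.tf8m_classify(split.test_X, models, threshold=threshold,
                              expected_size=len(models))
    y_pred = np.array([POSITIVE if v.is_phycys else NEGATIVE for v in votes])
    return float((y_pred == split.test_y).mean())


def subtype12m_holdout_accuracy(records: Sequence[ProteinRecord],
                                seed: int = 42,
                                members: Sequence[str] = ens.SUBTYPE12M_MEMBERS,
                                grids=None) -> float:
    """Held-out accuracy of the stage-2 majority vote on labeled positives."""
    positives = [r for r in records if r.label in SUBTYPES]
    X, _ = cleave_and_featurize(positives)
    y = np.array([r.label for r in positives])
    split = split_dataset(X, y, seed=seed)
    zoo = build_zoo(seed=seed, grids=grids, names=sorted(set(members)))
    models = {n: train_with_grid_search(zoo[n], split) for n in members}
    calls = ens.subtype_classify(split.test_X, models,
                                 expected_size=len(models))
    y_pred = np.array([c.final_class for c in calls])
    return float((y_pred == split.test_y).mean())


def save_bundle(bundle: Bundle, directory: str | Path) -> None:
    """Serialize to ``bundle.joblib`` plus a human-readable JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(bundle, directory / "bundle.joblib")
    with open(directory / "bundle.json", "w") as fh:
        json.dump(bundle.sidecar(), fh, indent=2, default=str)


def load_bundle(directory: str | Path) -> Bundle:
    return joblib.load(Path(directory) / "bundle.joblib")
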