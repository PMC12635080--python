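"""Stratified k-fold evaluation of any scorer with a fit/predict_proba surface."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .model import LabeledExample


def _fold_metrics(y_true, proba, classes) -> dict:
    pred = classes[np.asarray(proba).argmax(axis=1)]
    row = {"accuracy": accuracy_score(y_true, pred)}
    if len(classes) == 2:
        pos = proba[:, 1]
        y = (np.asarray(y_true) == classes[1]).astype(int)
        row["roc_auc"] = roc_auc_score(y, pos)
        row["pr_auc"] = average_precision_score(y, pos)
    else:
        onehot = (np.asarray(y_true)[:, None] == classes[None, :]).astype(int)
        present = onehot.sum(axis=0) > 0
        # macro one-vs-rest over classes present in the fold
        row["roc_auc"] = roc_auc_score(
            onehot[:, present], proba[:, present], average="macro",
            multi_class="ovr")
        row["pr_auc"] = float(np.mean([
            average_precision_score(onehot[:, j], proba[:, j])
            for j in range(len(classes)) if present[j]
        ]))
    return row


def cross_validate(dataset, scorer_factory, k: int = 10, seed: int = 0) -> pd.DataFrame:
    """Stratified k-fold cross-validation.

    ``dataset`` is a list of :class:`LabeledExample` or a (sequences, labels)
    pair; ``scorer_factory()`` must return an unfitted object exposing
    ``fit(sequences, labels)`` and ``predict_proba(sequences)``. Folds
    partition the data; per-fold accuracy, ROC-AUC and PR-AUC (macro
    one-vs-rest for multiclass) are reported together with their mean.
    """
    if isinstance(dataset, tuple):
        sequences, labels = dataset
    else:
        sequences = [ex.sequence for ex in dataset]
        labels = [ex.label for ex in dataset]
    sequences = list(sequences)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    _, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class count ({counts.min()})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(sequences, labels)):
        scorer = scorer_factory()
        scorer.fit([sequences[i] for i in tr], labels[tr])
        proba = np.asarray(scorer.predict_proba([sequences[i] for i in te]))
        row = {"fold": fold, "n_test": len(te)}
        row.update(_fold_metrics(labels[te], proba, classes))
        rows.append(row)
    df = pd.DataFrame(rows)
    mean = df.drop(columns=["fold"]).mean().to_dict()
    mean["fold"] = "mean"
    return pd.concat([df, pd.DataFrame([mean])], ignore_index=True)
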