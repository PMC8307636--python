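"""Exposure-label prediction from miRNA feature panels.

Mirrors the signature-validation step: a feed-forward neural network with
one hidden layer is trained to predict each patient's exposed/unexposed
label from their tumor miRNA profile, once from all miRNAs (the baseline)
and once from the exposure's signature panel, under stratified k-fold
cross-validation.  The quantity of interest is the accuracy gain of the
panel over the all-feature baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .io import ExpressionMatrix, ValidationError


@dataclass
class ClassifierReport:
    panel_name: str
    n_features: int
    overall_accuracy: float
    fold_accuracies: list[float]
    baseline_accuracy: float | None = None
    hyperparameters: dict = field(default_factory=dict)

    @property
    def delta(self) -> float | None:
        if self.baseline_accuracy is None:
            return None
        return self.overall_accuracy - self.baseline_accuracy


def _hidden_width(n_features: int) -> int:
    return max(4, math.ceil(math.sqrt(n_features)))


def train_predict_nn(
    features: ExpressionMatrix,
    labels: Sequence[int] | Sequence[bool],
    panel: Sequence[str] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    panel_name: str = "panel",
) -> ClassifierReport:
    """Cross-validated accuracy of a one-hidden-layer MLP on a feature panel.

    ``features`` is miRNAs x samples; ``labels`` aligns with its columns.
    ``panel=None`` uses every miRNA (the all-feature baseline).  Features
    are z-scored inside each training fold.  Deterministic given ``seed``.
    """
    y = np.asarray(labels).astype(int)
    if len(y) != features.shape[1]:
        raise ValidationError("labels must align with sample columns")
    if len(y) < 6:
        raise ValidationError("need at least 6 labeled samples")
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("labels contain a single class")
    if panel is not None:
        panel = list(panel)
        if not panel:
            raise ValidationError("empty feature panel")
        mat = features.subset_mirnas(sorted(set(panel)))
    else:
        mat = features
    x = mat.values.T  # samples x features
    folds = min(cv_folds, int(class_counts.min()))
    if folds < 2:
        raise ValidationError("minority class too small for cross-validation")

    width = _hidden_width(x.shape[1])
    hyper = {
        "hidden_layer_sizes": (width,),
        "activation": "logistic",
        "solver": "lbfgs",
        "alpha": 1e-2,
        "max_iter": 500,
        "cv_folds": folds,
        "scaling": "per-fold z-score",
    }
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_acc: list[float] = []
    n_correct = 0
    for k, (train, test) in enumerate(skf.split(x, y)):
        clf = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPClassifier(
                        hidden_layer_sizes=(width,),
                        activation="logistic",
                        solver="lbfgs",
                        alpha=1e-2,
                        max_iter=500,
                        random_state=seed + k,
                    ),
                ),
            ]
        )
        clf.fit(x[train], y[train])
        pred = clf.predict(x[test])
        fold_acc.append(float((pred == y[test]).mean()))
        n_correct += int((pred == y[test]).sum())
    return ClassifierReport(
        panel_name=panel_name,
        n_features=x.shape[1],
        overall_accuracy=n_correct / len(y),
        fold_accuracies=fold_acc,
        hyperparameters=hyper,
    )


def accuracy_delta_table(
    baseline: ClassifierReport, panels: Sequence[ClassifierReport]
) -> pd.DataFrame:
    """Panel-vs-baseline accuracy table, sorted by accuracy gain descending."""
    rows = []
    for r in panels:
        rows.append(
            {
                "panel": r.panel_name,
                "n_features": r.n_features,
                "baseline_accuracy": baseline.overall_accuracy,
                "panel_accuracy": r.overall_accuracy,
                "delta": r.overall_accuracy - baseline.overall_accuracy,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["panel", "n_features", "baseline_accuracy", "panel_accuracy", "delta"],
    )
    if len(df):
        df = df.sort_values("delta", ascending=False, kind="mergesort").reset_index(drop=True)
    return df
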