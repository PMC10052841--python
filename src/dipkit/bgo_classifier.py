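"""Biogeographic-origin classification harness.

Trains off-the-shelf multi-class models (random forest, XGBoost, SVM,
decision tree) on insertion-dosage features with continent labels, using
a stratified holdout split, and reports confusion matrices (rows =
predicted, columns = truth) with exact binomial (Clopper-Pearson)
confidence intervals on the holdout accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest
from sklearn.model_selection import train_test_split

from .io_formats import GenotypeMatrix

__all__ = ["ConfusionMatrix", "AccuracyCI", "accuracy_ci", "train_eval",
           "MODEL_NAMES"]

MODEL_NAMES = ("rf", "xgb", "svm", "dt")


@dataclass
class ConfusionMatrix:
    """Integer counts with rows = predicted class, columns = true class."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.counts.sum() <= 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def correct(self) -> int:
        return int(np.trace(self.counts))


@dataclass
class AccuracyCI:
    accuracy: float
    lower: float
    upper: float
    level: float = 0.95
    method: str = "clopper-pearson"


def accuracy_ci(cm: ConfusionMatrix, level: float = 0.95) -> AccuracyCI:
    """Holdout accuracy with the exact binomial confidence interval."""
    k, n = cm.correct, cm.total
    if n < 1:
        raise ValueError("empty confusion matrix")
    ci = binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    return AccuracyCI(k / n, float(ci.low), float(ci.high), level)


def _make_model(name: str, seed: int):
    if name == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=seed)
    if name == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=seed)
    if name == "svm":
        from sklearn.svm import SVC

        return SVC(random_state=seed)
    if name == "dt":
        from sklearn.tree import DecisionTreeClassifier

        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown model {name!r}")


def train_eval(
    g: GenotypeMatrix,
    models: tuple[str, ...] = MODEL_NAMES,
    test_size: float = 0.25,
    seed: int = 0,
) -> dict[str, tuple[ConfusionMatrix, AccuracyCI]]:
    """Fit each model on a stratified holdout split of continent labels.

    Features are insertion dosages with per-locus mean imputation of
    missing calls; all hyperparameters are library defaults.  Returns
    per-model (confusion matrix, accuracy CI).
    """
    X = g.dosage.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    labels = sorted(set(g.continent))
    if len(labels) < 2:
        raise ValueError("need at least 2 continent classes")
    lab_index = {lab: i for i, lab in enumerate(labels)}
    y = np.array([lab_index[c] for c in g.continent])
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )
    if len(set(y_tr)) < len(labels):
        raise ValueError("a class is absent from the training split")
    out: dict[str, tuple[ConfusionMatrix, AccuracyCI]] = {}
    for name in models:
        model = _make_model(name, seed)
        model.fit(X_tr, y_tr)
        pred = np.asarray(model.predict(X_te))
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        np.add.at(counts, (pred, y_te), 1)  # rows predicted, cols truth
        cm = ConfusionMatrix(labels, counts)
        out[name] = (cm, accuracy_ci(cm))
    return out
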