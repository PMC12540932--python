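"""Disease-status classifiers, balanced-accuracy evaluation, and the
label-randomization and leave-one-subject-out generalization checks.

Four fixed classifier families are supported (case = positive class):
a one-hidden-layer neural network, L1 logistic regression, random forest,
and a linear-kernel SVM. Training always uses stratified five-fold
cross-validation on the training split, yielding five models that are each
evaluated independently on the held-out test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .core_data import CellMatrix
from .synthetic import randomize_labels

POSITIVE = "case"
NEGATIVE = "control"


class StratificationError(ValueError):
    """A condition class is absent from a split or fold."""


@dataclass
class ClassifierSpec:
    """One of the four classifier families with its fixed hyperparameters.

    Defaults: NN — one hidden layer of 100 rectified-linear units, Adam,
    500-iteration cap; LR — L1 penalty, inverse regularization strength 2.0,
    liblinear, 100-iteration cap; RF — 100 trees, Gini impurity, minimum
    split 2, minimum leaf 1, bootstrap; SVM — linear kernel, C = 1, no
    iteration cap. Overrides are recorded so run logs can show deviations.
    """

    family: str = "nn"
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("nn", "lr", "rf", "svm"):
            raise ValueError(f"unknown family {self.family!r}")

    def build(self, seed: int | None = None):
        seed = self.seed if seed is None else seed
        if self.family == "nn":
            params = dict(hidden_layer_sizes=(100,), activation="relu",
                          solver="adam", max_iter=500, random_state=seed)
        elif self.family == "lr":
            params = dict(penalty="l1", C=2.0, solver="liblinear",
                          max_iter=100, random_state=seed)
        elif self.family == "rf":
            params = dict(n_estimators=100, criterion="gini",
                          min_samples_split=2, min_samples_leaf=1,
                          bootstrap=True, random_state=seed)
        else:  # svm; probability outputs needed by the explainer
            params = dict(kernel="linear", C=1.0, max_iter=-1,
                          probability=True, random_state=seed)
        params.update(self.overrides)
        cls = {"nn": MLPClassifier, "lr": LogisticRegression,
               "rf": RandomForestClassifier, "svm": SVC}[self.family]
        return cls(**params)


@dataclass(frozen=True)
class ConfusionCounts:
    """Case-positive confusion counts for one model on one test set."""

    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion counts must be non-negative")


def balanced_accuracy(c: ConfusionCounts) -> float:
    """Mean of sensitivity and specificity:
    (TP/(TP+FN) + TN/(TN+FP)) / 2, with case as the positive class."""
    if c.TP + c.FN == 0 or c.TN + c.FP == 0:
        raise ValueError("balanced accuracy undefined: a condition class is empty")
    return 0.5 * (c.TP / (c.TP + c.FN) + c.TN / (c.TN + c.FP))


@dataclass
class EvaluationResult:
    """Per-model test performance plus per-cell predictions.

    ``predictions`` is (n_models, n_cells) of predicted labels;
    ``correct`` the matching boolean correctness flags.
    """

    confusions: list[ConfusionCounts]
    balanced_accuracies: np.ndarray
    predictions: np.ndarray
    correct: np.ndarray
    cell_ids: list[str] | None = None

    @property
    def mean_balanced_accuracy(self) -> float:
        return float(np.mean(self.balanced_accuracies))

    @property
    def std_balanced_accuracy(self) -> float:
        return float(np.std(self.balanced_accuracies))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": np.arange(len(self.confusions)),
            "TP": [c.TP for c in self.confusions],
            "FN": [c.FN for c in self.confusions],
            "TN": [c.TN for c in self.confusions],
            "FP": [c.FP for c in self.confusions],
            "balanced_accuracy": self.balanced_accuracies,
        })


def train_cv(X: np.ndarray, y: Sequence[str], spec: ClassifierSpec,
             k_folds: int = 5, seed: int = 0) -> list:
    """Train ``k_folds`` models, model i on all folds except i (stratified).

    Each model's estimator seed derives from ``seed`` plus the fold index so
    weight initialization differs across folds but is reproducible.
    """
    y = np.asarray(y, dtype=object)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("both condition classes must be present")
    if counts.min() < k_folds:
        raise StratificationError(
            f"minority class has {counts.min()} cells < k_folds={k_folds}")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    models = []
    for i, (train_idx, _) in enumerate(skf.split(X, y)):
        est = spec.build(seed=(seed + i) % (2**31 - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X[train_idx], y[train_idx])
        models.append(est)
    return models


def evaluate(models: Sequence, X_test: np.ndarray, y_test: Sequence[str],
             cell_ids: Sequence[str] | None = None) -> EvaluationResult:
    """Score every model independently on the held-out test split."""
    y_test = np.asarray(y_test, dtype=object)
    if X_test.shape[1] != getattr(models[0], "n_features_in_", X_test.shape[1]):
        raise ValueError("feature dimension mismatch between model and test data")
    preds = np.empty((len(models), len(y_test)), dtype=object)
    confusions, accs = [], []
    for i, mdl in enumerate(models):
        p = mdl.predict(X_test)
        preds[i] = p
        c = ConfusionCounts(
            TP=int(((p == POSITIVE) & (y_test == POSITIVE)).sum()),
            FN=int(((p == NEGATIVE) & (y_test == POSITIVE)).sum()),
            TN=int(((p == NEGATIVE) & (y_test == NEGATIVE)).sum()),
            FP=int(((p == POSITIVE) & (y_test == NEGATIVE)).sum()),
        )
        confusions.append(c)
        accs.append(balanced_accuracy(c))
    correct = preds == y_test[None, :]
    return EvaluationResult(
        confusions=confusions, balanced_accuracies=np.array(accs),
        predictions=preds, correct=correct,
        cell_ids=list(cell_ids) if cell_ids is not None else None,
    )


def run_pipeline(m: CellMatrix, genes: Sequence[str], spec: ClassifierSpec,
                 seed: int = 0, test_fraction: float = 0.2, k_folds: int = 5,
                 ) -> tuple[list, EvaluationResult, CellMatrix, CellMatrix]:
    """Split -> restrict to ``genes`` -> train CV models -> evaluate.

    The shared train/evaluate path used by the randomization curve, the
    elimination curves and transfer evaluation. Returns (models, evaluation,
    train split, test split).
    """
    from .core_data import split_train_test

    train, test = split_train_test(m, test_fraction=test_fraction, seed=seed)
    genes = list(genes)
    Xtr, Xte = train.lognorm(genes), test.lognorm(genes)
    models = train_cv(Xtr, train.labels(), spec, k_folds=k_folds, seed=seed)
    result = evaluate(models, Xte, test.labels(), cell_ids=list(test.cell_ids))
    return models, result, train, test


def label_randomization_curve(m: CellMatrix, genes: Sequence[str],
                              spec: ClassifierSpec,
                              fractions: Sequence[float], seed: int = 0,
                              test_fraction: float = 0.2, k_folds: int = 5,
                              ) -> pd.DataFrame:
    """Mean test balanced accuracy after randomizing a fraction of labels.

    For each fraction the labels are randomized, the pipeline (split,
    training, evaluation) is rerun from scratch, and the mean balanced
    accuracy over the CV models is recorded. With informative genes the curve
    decays from the baseline accuracy toward chance at fraction 1.
    """
    rows = []
    for f in fractions:
        mr = randomize_labels(m, float(f), seed=seed)
        _, result, _, _ = run_pipeline(
            mr, genes, spec, seed=seed, test_fraction=test_fraction,
            k_folds=k_folds)
        rows.append({"fraction": float(f),
                     "mean_balanced_accuracy": result.mean_balanced_accuracy})
    return pd.DataFrame(rows)


def leave_one_subject_out(m: CellMatrix, genes: Sequence[str],
                          spec: ClassifierSpec, n_permutations: int = 10,
                          seed: int = 0) -> pd.DataFrame:
    """Train on all subjects but one; score the held-out subject's cells.

    Accuracy per subject is the raw fraction of that subject's cells
    classified to the subject's condition (each subject carries a single
    condition, so balanced accuracy is undefined at the subject level).
    Training is repeated ``n_permutations`` times with re-seeded model
    initialization; the per-subject median and mean absolute deviation of the
    accuracies are reported.
    """
    if len(genes) == 0:
        raise ValueError("gene list is empty")
    subjects = m.obs["subject_id"].unique().tolist()
    if len(subjects) < 3:
        raise ValueError("need >= 3 subjects for leave-one-subject-out")
    genes = list(genes)
    L = m.lognorm(genes)
    subj_arr = m.obs["subject_id"].to_numpy(dtype=object)
    y = m.labels()
    rows = []
    for s_idx, subj in enumerate(subjects):
        held = subj_arr == subj
        if not held.any():
            warnings.warn(f"subject {subj} has no cells; skipped")
            continue
        Xtr, ytr = L[~held], y[~held]
        Xte, yte = L[held], y[held]
        if len(np.unique(ytr)) < 2:
            raise StratificationError("training subjects span a single condition")
        accs = []
        for p in range(n_permutations):
            est = spec.build(seed=(seed + 1000 * s_idx + p) % (2**31 - 1))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(Xtr, ytr)
            accs.append(float(np.mean(est.predict(Xte) == yte)))
        accs = np.asarray(accs)
        med = float(np.median(accs))
        rows.append({
            "subject_id": subj, "condition": str(y[held][0]),
            "n_cells": int(held.sum()), "median_accuracy": med,
            "mad_accuracy": float(np.mean(np.abs(accs - med))),
        })
    return pd.DataFrame(rows)
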