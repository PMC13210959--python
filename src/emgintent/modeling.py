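"""Trial-level evaluation harness: splits, metrics, feature-set screening,
classifier benchmarking and random-forest hyperparameter tuning.

All partitioning — the train/test split and the cross-validation folds —
assigns whole trials, never individual windows.  Windows of one movement
repetition are strongly autocorrelated, so any split that separates them
across sets inflates accuracy; keeping trials atomic removes that leakage
by construction.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.svm import SVC

from .datatypes import MOTION_CLASSES, TrialAnnotation
from .features import FEATURE_NAMES, FeatureMatrix, extract_features, normalize_subset
from .windowing import WindowBatch

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "ClassifierSpec",
    "CVSpec",
    "EvaluationReport",
    "split_trials",
    "split_trial_ids",
    "accuracy",
    "confusion_and_per_class",
    "make_classifier",
    "fit_and_evaluate",
    "evaluate_single_features",
    "DEFAULT_FUSIONS",
    "evaluate_fusions",
    "benchmark_classifiers",
    "grid_search_rf",
    "trial_folds",
    "aggregate_subject_table",
]

CLASSIFIER_KINDS = ("SVM-RBF", "LDA", "QDA", "GradientBoosting", "RandomForest")


@dataclass(frozen=True)
class SplitSpec:
    """Trial-level train/test split parameters."""

    train_fraction: float = 0.9
    stratify: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train fraction must lie in (0, 1)")


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the five benchmarked classifier families."""

    kind: str = "RandomForest"
    params: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(
                f"unknown classifier kind {self.kind!r}; choose from {CLASSIFIER_KINDS}"
            )


@dataclass(frozen=True)
class CVSpec:
    """K-fold grid-search configuration for the random forest."""

    k: int = 5
    n_estimators_grid: tuple[int, ...] = (11, 51, 101, 151, 181, 201)
    max_depth_grid: tuple[int | None, ...] = (31, 71, 131, None)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("K must be at least 2")
        if not self.n_estimators_grid or not self.max_depth_grid:
            raise ValueError("hyperparameter grids must be non-empty")


@dataclass
class EvaluationReport:
    """Accuracy, per-class recall and confusion matrix with provenance."""

    overall_accuracy: float
    per_class_accuracy: dict[str, float]
    confusion: pd.DataFrame  # rows = true, cols = predicted
    classes: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    @property
    def n_test_windows(self) -> int:
        return int(self.confusion.to_numpy().sum())

    def to_json(self) -> str:
        payload = {
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "confusion": self.confusion.to_dict(),
            "classes": list(self.classes),
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, default=str)

    def render(self) -> str:
        lines = [
            f"overall accuracy: {self.overall_accuracy:.4f}",
            "confusion matrix (rows = true, cols = predicted):",
            self.confusion.to_string(),
            "per-class accuracy: "
            + ", ".join(f"{c}={a:.4f}" for c, a in self.per_class_accuracy.items()),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Splitting


def split_trial_ids(
    trial_ids: Sequence[int],
    labels: Sequence[str],
    spec: SplitSpec,
) -> tuple[list[int], list[int]]:
    """Split unique trials into train/test sets.

    With stratification the per-class test count is max(1, round((1-f) * n)),
    so every class is represented in the test set.
    """
    pairs = sorted(set(zip((int(t) for t in trial_ids), labels)))
    ids = [p[0] for p in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("a trial id maps to more than one label")
    rng = np.random.default_rng(spec.seed)
    train: list[int] = []
    test: list[int] = []
    if spec.stratify:
        by_class: dict[str, list[int]] = {}
        for tid, lab in pairs:
            by_class.setdefault(lab, []).append(tid)
        for lab in sorted(by_class):
            members = by_class[lab]
            if len(members) < 2:
                raise ValueError(
                    f"class {lab} has {len(members)} trial(s); stratified "
                    "splitting needs at least 2"
                )
            n_test = max(1, int(np.floor((1 - spec.train_fraction) * len(members) + 0.5)))
            order = rng.permutation(len(members))
            test.extend(members[i] for i in order[:n_test])
            train.extend(members[i] for i in order[n_test:])
    else:
        n_test = max(1, int(np.floor((1 - spec.train_fraction) * len(ids) + 0.5)))
        order = rng.permutation(len(ids))
        test.extend(ids[i] for i in order[:n_test])
        train.extend(ids[i] for i in order[n_test:])
    return sorted(train), sorted(test)


def split_trials(
    annotations: Sequence[TrialAnnotation], spec: SplitSpec
) -> tuple[list[int], list[int]]:
    """Trial-level split over an annotation table."""
    return split_trial_ids(
        [a.trial_id for a in annotations], [a.label for a in annotations], spec
    )


# ---------------------------------------------------------------------------
# Metrics


def accuracy(pred: Sequence, true: Sequence) -> float:
    """Fraction of correctly classified samples."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("prediction and truth must be equal-length, non-empty")
    return float(np.mean(pred == true))


def confusion_and_per_class(
    pred: Sequence,
    true: Sequence,
    classes: Sequence[str] = MOTION_CLASSES,
) -> EvaluationReport:
    """Confusion matrix (rows = true, cols = predicted), per-class recall
    (diagonal / row sum) and overall accuracy."""
    classes = tuple(classes)
    cm = confusion_matrix(true, pred, labels=list(classes))
    frame = pd.DataFrame(cm, index=list(classes), columns=list(classes))
    row_sums = cm.sum(axis=1)
    per_class = {
        c: (float(cm[i, i] / row_sums[i]) if row_sums[i] else float("nan"))
        for i, c in enumerate(classes)
    }
    return EvaluationReport(
        overall_accuracy=accuracy(pred, true),
        per_class_accuracy=per_class,
        confusion=frame,
        classes=classes,
    )


def aggregate_subject_table(table: pd.DataFrame) -> pd.Series:
    """Column means of a per-subject accuracy table (rows = subjects,
    columns = per-class accuracies and/or a per-subject mean column).

    The mean of a "Mean Value"-style column is the grand mean accuracy
    across subjects.
    """
    return table.mean(axis=0)


# ---------------------------------------------------------------------------
# Classifier construction and evaluation


def make_classifier(spec: ClassifierSpec):
    """Instantiate one of the benchmarked sklearn classifiers.

    Hyperparameters beyond those given keep library defaults; the concrete
    values are recorded into every report for provenance.
    """
    params = dict(spec.params)
    if spec.kind == "SVM-RBF":
        return SVC(kernel="rbf", **params)
    if spec.kind == "LDA":
        return LinearDiscriminantAnalysis(**params)
    if spec.kind == "QDA":
        # a tiny ridge and a loose rank tolerance keep near-constant classes
        # (rest) from producing a singular class covariance
        params.setdefault("reg_param", 1e-6)
        params.setdefault("tol", 1e-12)
        return QuadraticDiscriminantAnalysis(**params)
    if spec.kind == "GradientBoosting":
        return GradientBoostingClassifier(random_state=spec.seed, **params)
    return RandomForestClassifier(random_state=spec.seed, **params)


def _select(fm: FeatureMatrix, trial_ids: Sequence[int]):
    mask = np.isin(fm.trial_ids, list(trial_ids))
    return fm.X.to_numpy()[mask], fm.labels[mask]


def fit_and_evaluate(
    fm: FeatureMatrix,
    train_ids: Sequence[int],
    test_ids: Sequence[int],
    spec: ClassifierSpec,
    classes: Sequence[str] = MOTION_CLASSES,
) -> EvaluationReport:
    """Train on the train-trial windows, score on the test-trial windows."""
    if set(train_ids) & set(test_ids):
        raise ValueError("train and test trial sets overlap")
    x_train, y_train = _select(fm, train_ids)
    x_test, y_test = _select(fm, test_ids)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data covers fewer than two classes")
    clf = make_classifier(spec)
    clf.fit(x_train, y_train)
    pred = clf.predict(x_test)
    report = confusion_and_per_class(pred, y_test, classes)
    report.provenance = {
        "classifier": spec.kind,
        "classifier_params": clf.get_params(),
        "seed": spec.seed,
        "train_trials": sorted(int(t) for t in train_ids),
        "test_trials": sorted(int(t) for t in test_ids),
        "feature_subset": list(fm.feature_subset),
        "n_train_windows": int(len(y_train)),
        "n_test_windows": int(len(y_test)),
    }
    return report


def _classes_present(batch: WindowBatch) -> tuple[str, ...]:
    present = tuple(c for c in MOTION_CLASSES if c in set(batch.labels))
    if len(present) < 2:
        raise ValueError(
            "classification is undefined on data with fewer than two classes"
        )
    return present


def evaluate_single_features(
    batch: WindowBatch,
    classifier: ClassifierSpec | None = None,
    split: SplitSpec | None = None,
) -> pd.DataFrame:
    """Screen each descriptor independently under one classifier and split.

    Returns an 8-row table (one per feature) of per-class accuracies plus a
    ``Mean Value`` column (arithmetic mean of the class accuracies).
    """
    classifier = classifier or ClassifierSpec("RandomForest")
    split = split or SplitSpec()
    classes = _classes_present(batch)
    train_ids, test_ids = split_trial_ids(batch.trial_ids, batch.labels, split)
    rows = {}
    for feature in FEATURE_NAMES:
        fm = extract_features(batch, [feature])
        report = fit_and_evaluate(fm, train_ids, test_ids, classifier, classes)
        rows[feature] = report.per_class_accuracy
    table = pd.DataFrame(rows).T.reindex(columns=list(classes))
    table["Mean Value"] = table[list(classes)].mean(axis=1)
    return table


#: Candidate fusions screened by default: pairwise extensions of the best
#: single feature followed by the leading triplets and the full quadruple.
DEFAULT_FUSIONS: tuple[tuple[str, ...], ...] = (
    ("RMS", "MAV"),
    ("RMS", "VAR"),
    ("RMS", "KU"),
    ("RMS", "WF"),
    ("RMS", "IF"),
    ("RMS", "SK"),
    ("RMS", "MAV", "CF"),
    ("MAV", "IF", "CF"),
    ("MAV", "IF", "RMS"),
    ("IF", "CF", "RMS"),
    ("MAV", "IF", "CF", "RMS"),
)


def evaluate_fusions(
    batch: WindowBatch,
    combos: Sequence[Sequence[str]] = DEFAULT_FUSIONS,
    classifier: ClassifierSpec | None = None,
    split: SplitSpec | None = None,
) -> pd.DataFrame:
    """Evaluate fused feature sets under one classifier and split."""
    classifier = classifier or ClassifierSpec("RandomForest")
    split = split or SplitSpec()
    classes = _classes_present(batch)
    train_ids, test_ids = split_trial_ids(batch.trial_ids, batch.labels, split)
    rows = {}
    for combo in combos:
        subset = normalize_subset(combo)
        name = " + ".join(subset)
        fm = extract_features(batch, subset)
        report = fit_and_evaluate(fm, train_ids, test_ids, classifier, classes)
        rows[name] = report.per_class_accuracy
    table = pd.DataFrame(rows).T.reindex(columns=list(classes))
    table["Mean Value"] = table[list(classes)].mean(axis=1)
    return table


def benchmark_classifiers(
    fm: FeatureMatrix,
    specs: Sequence[ClassifierSpec],
    split: SplitSpec | None = None,
) -> list[EvaluationReport]:
    """Train every classifier on the identical split and feature matrix;
    reports are returned sorted by decreasing overall accuracy."""
    split = split or SplitSpec()
    train_ids, test_ids = split_trial_ids(fm.trial_ids, fm.labels, split)
    classes = tuple(c for c in MOTION_CLASSES if c in set(fm.labels))
    reports = [
        fit_and_evaluate(fm, train_ids, test_ids, spec, classes) for spec in specs
    ]
    return sorted(reports, key=lambda r: r.overall_accuracy, reverse=True)


def default_benchmark_specs(seed: int = 0) -> list[ClassifierSpec]:
    return [ClassifierSpec(kind, seed=seed) for kind in CLASSIFIER_KINDS]


# ---------------------------------------------------------------------------
# K-fold grid search (trial-level folds)


def trial_folds(
    trial_ids: Sequence[int],
    labels: Sequence[str],
    k: int,
    seed: int = 0,
) -> list[list[int]]:
    """Assign whole trials to K folds, stratified by class.

    Trials of each class are shuffled and dealt round-robin, so every fold
    holds roughly balanced class counts and all windows of a trial land in
    one fold.
    """
    pairs = sorted(set(zip((int(t) for t in trial_ids), labels)))
    by_class: dict[str, list[int]] = {}
    for tid, lab in pairs:
        by_class.setdefault(lab, []).append(tid)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for lab in sorted(by_class):
        members = by_class[lab]
        if len(members) < k:
            raise ValueError(
                f"class {lab} has only {len(members)} trial(s); cannot form "
                f"{k} trial-level folds"
            )
        order = rng.permutation(len(members))
        for i, j in enumerate(order):
            folds[i % k].append(members[j])
    return [sorted(f) for f in folds]


def _depth_key(depth: int | None) -> float:
    return float("inf") if depth is None else float(depth)


def grid_search_rf(
    fm: FeatureMatrix,
    cv: CVSpec | None = None,
    seed: int = 0,
) -> tuple[int, int | None, pd.DataFrame]:
    """Exhaustive (n_estimators, max_depth) search by trial-level K-fold
    cross-validation.

    Each grid cell holds the mean validation accuracy over the K folds.
    Returns the arg-max cell, with ties broken toward the smaller
    (n_estimators, max_depth) pair (``None`` depth ordered last).
    """
    cv = cv or CVSpec()
    folds = trial_folds(fm.trial_ids, fm.labels, cv.k, seed)
    n_grid = sorted(cv.n_estimators_grid)
    d_grid = sorted(set(cv.max_depth_grid), key=_depth_key)
    surface = pd.DataFrame(
        np.zeros((len(n_grid), len(d_grid))),
        index=pd.Index(n_grid, name="n_estimators"),
        columns=pd.Index([str(d) for d in d_grid], name="max_depth"),
    )
    X = fm.X.to_numpy()
    y = fm.labels
    fold_masks = [np.isin(fm.trial_ids, f) for f in folds]
    for n_est, depth in itertools.product(n_grid, d_grid):
        scores = []
        for i in range(cv.k):
            val = fold_masks[i]
            train = ~val
            clf = RandomForestClassifier(
                n_estimators=n_est, max_depth=depth, random_state=seed
            )
            clf.fit(X[train], y[train])
            scores.append(accuracy(clf.predict(X[val]), y[val]))
        surface.loc[n_est, str(depth)] = float(np.mean(scores))
    best_score = -np.inf
    best: tuple[int, int | None] = (n_grid[0], d_grid[0])
    for n_est in n_grid:  # ascending: first strict improvement wins ties
        for depth in d_grid:
            score = surface.loc[n_est, str(depth)]
            if score > best_score:
                best_score = score
                best = (n_est, depth)
    logger.info(
        "grid search best: n_estimators=%d max_depth=%s (CV accuracy %.4f)",
        best[0],
        best[1],
        best_score,
    )
    return best[0], best[1], surface
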