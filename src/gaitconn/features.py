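"""Connectivity feature families and locomotion-state classification.

Six feature families describe one gait cycle (−1,000 … +500 ms around the
RC event, i.e. the preparation phase plus the three walking sub-phases):

========================  =========================================  =====
family                    content                                     dim
========================  =========================================  =====
raw                       flattened 32-channel signal, 750 samples   24000
whole_pli                 one PLI matrix over the full 1.5 s          1024
tv_pli                    the 4 gait-phase PLI matrices               4096
merged_phases(k)          the first k phase matrices in gait order   k*1024
global_metrics(metric)    one global metric per phase                    4
local_metrics(metric)     one local metric per node per phase          128
========================  =========================================  =====

Classifiers are standard scikit-learn implementations (RBF-kernel SVM,
Gaussian naive Bayes, 5-nearest-neighbors), evaluated with stratified
5-fold cross-validation on folds that depend only on the labels and the
seed — so every family is scored on identical splits.  Features are
standardized with training-fold statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .connectivity import (
    ConnectivityTensor,
    PhaseConnectivity,
    instantaneous_phase,
    pli_matrix,
)
from .network import (
    GLOBAL_METRIC_NAMES,
    LOCAL_METRIC_NAMES,
    WeightedGraph,
    global_metrics,
    local_metrics,
)
from .preprocess import EpochSet

FAMILIES = ("raw", "whole_pli", "tv_pli", "global_metrics", "local_metrics",
            "merged_phases")
CLASSIFIERS = ("SVM", "NB", "KNN")

#: samples of the −1,000…+500 ms analysis span at 500 Hz
CYCLE_SAMPLES = 750


@dataclass
class FeatureSet:
    matrix: np.ndarray
    labels: np.ndarray
    family: str
    metric: str | None = None
    k_phases: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=str)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("one label per epoch required")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite feature values")

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass
class EvalReport:
    """Cross-validated scores of one classifier on one feature family."""

    classifier: str
    family: str
    fold_accuracy: np.ndarray  # percent
    fold_f1: np.ndarray  # percent, macro-averaged
    confusion: np.ndarray  # summed over folds
    classes: tuple[str, ...]
    seed: int
    fold_assignment: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def f1(self) -> float:
        return float(np.mean(self.fold_f1))

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.fold_accuracy, ddof=1))

    @property
    def f1_sd(self) -> float:
        return float(np.std(self.fold_f1, ddof=1))

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "family": self.family,
            "accuracy": self.accuracy,
            "accuracy_sd": self.accuracy_sd,
            "f1": self.f1,
            "f1_sd": self.f1_sd,
            "fold_accuracy": self.fold_accuracy.tolist(),
            "fold_f1": self.fold_f1.tolist(),
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
            "seed": self.seed,
        }


def _whole_epoch_pli(epochs: EpochSet) -> np.ndarray:
    n_ep, n_ch = epochs.data.shape[:2]
    out = np.zeros((n_ep, n_ch, n_ch))
    for e in range(n_ep):
        phases = instantaneous_phase(epochs.data[e, :, :CYCLE_SAMPLES])
        out[e] = pli_matrix(phases)
    return out


def build_features(
    family: str,
    epochs: EpochSet | None = None,
    tensor: ConnectivityTensor | None = None,
    phase_conn: PhaseConnectivity | None = None,
    metric: str | None = None,
    k_phases: int | None = None,
) -> FeatureSet:
    """Assemble one feature family from pipeline artifacts.

    ``raw`` and ``whole_pli`` need ``epochs``; the phase-resolved families
    need ``phase_conn``.  ``metric`` selects the metric for the
    ``global_metrics``/``local_metrics`` families; ``k_phases`` (1..4) the
    prefix length for ``merged_phases``.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown feature family {family!r}")
    if family == "raw":
        if epochs is None:
            raise ValueError("raw features need the EpochSet")
        x = epochs.data[:, :, :CYCLE_SAMPLES].reshape(epochs.n_epochs, -1)
        return FeatureSet(x, epochs.conditions, family)
    if family == "whole_pli":
        if epochs is None:
            raise ValueError("whole_pli features need the EpochSet")
        pli = _whole_epoch_pli(epochs)
        return FeatureSet(pli.reshape(len(pli), -1), epochs.conditions, family)
    if phase_conn is None:
        raise ValueError(f"{family} features need the PhaseConnectivity")
    v = phase_conn.values
    n_ep = v.shape[0]
    if family == "tv_pli":
        return FeatureSet(v.reshape(n_ep, -1), phase_conn.conditions, family)
    if family == "merged_phases":
        if k_phases is None or not (1 <= k_phases <= 4):
            raise ValueError("merged_phases needs k_phases in 1..4")
        x = v[:, :k_phases].reshape(n_ep, -1)
        return FeatureSet(x, phase_conn.conditions, family, k_phases=k_phases)
    if family == "global_metrics":
        if metric not in GLOBAL_METRIC_NAMES:
            raise ValueError(f"metric must be one of {GLOBAL_METRIC_NAMES}")
        mi = GLOBAL_METRIC_NAMES.index(metric)
        x = np.zeros((n_ep, v.shape[1]))
        for e in range(n_ep):
            for p in range(v.shape[1]):
                x[e, p] = global_metrics(WeightedGraph(v[e, p])).as_tuple()[mi]
        return FeatureSet(x, phase_conn.conditions, family, metric=metric)
    # local_metrics
    if metric not in LOCAL_METRIC_NAMES:
        raise ValueError(f"metric must be one of {LOCAL_METRIC_NAMES}")
    n_ch = v.shape[-1]
    x = np.zeros((n_ep, v.shape[1], n_ch))
    for e in range(n_ep):
        for p in range(v.shape[1]):
            x[e, p] = local_metrics(WeightedGraph(v[e, p])).by_name(metric)
    return FeatureSet(x.reshape(n_ep, -1), phase_conn.conditions, family,
                      metric=metric)


def _make_classifier(name: str):
    if name == "SVM":
        return SVC(C=1.0, kernel="rbf", gamma="scale")
    if name == "NB":
        return GaussianNB()
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def make_folds(labels: np.ndarray, n_folds: int = 5, seed: int = 42) -> np.ndarray:
    """Stratified fold assignment depending only on (labels, seed)."""
    labels = np.asarray(labels, dtype=str)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"each class needs at least {n_folds} epochs for {n_folds}-fold "
            f"stratified CV (got {dict(zip(classes, counts))})"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for k, (_, test_idx) in enumerate(skf.split(np.zeros((len(labels), 1)), labels)):
        assignment[test_idx] = k
    return assignment


def train_eval(
    features: FeatureSet,
    classifier: str = "NB",
    n_folds: int = 5,
    seed: int = 42,
    fold_assignment: np.ndarray | None = None,
) -> EvalReport:
    """Stratified k-fold cross-validation with accuracy and macro F1 (%)."""
    y = features.labels
    if fold_assignment is None:
        fold_assignment = make_folds(y, n_folds, seed)
    classes = tuple(np.unique(y).tolist())
    accs, f1s = [], []
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for k in range(int(fold_assignment.max()) + 1):
        test = fold_assignment == k
        train = ~test
        if len(np.unique(y[train])) < len(classes):
            raise ValueError(f"fold {k}: a class is absent from the training split")
        model = make_pipeline(StandardScaler(), _make_classifier(classifier))
        model.fit(features.matrix[train], y[train])
        pred = model.predict(features.matrix[test])
        accs.append(100.0 * np.mean(pred == y[test]))
        f1s.append(100.0 * f1_score(y[test], pred, labels=classes, average="macro"))
        conf += confusion_matrix(y[test], pred, labels=classes)
    return EvalReport(
        classifier=classifier,
        family=features.family,
        fold_accuracy=np.asarray(accs),
        fold_f1=np.asarray(f1s),
        confusion=conf,
        classes=classes,
        seed=seed,
        fold_assignment=fold_assignment,
    )


def compare_families(
    feature_sets: dict[str, FeatureSet],
    classifiers: tuple[str, ...] = CLASSIFIERS,
    n_folds: int = 5,
    seed: int = 42,
) -> pd.DataFrame:
    """Score every (family, classifier) pair on identical folds."""
    sets = list(feature_sets.values())
    ref = sets[0].labels
    for fs in sets[1:]:
        if len(fs.labels) != len(ref) or not np.array_equal(fs.labels, ref):
            raise ValueError("feature families must cover the same epochs")
    folds = make_folds(ref, n_folds, seed)
    rows = []
    for name, fs in feature_sets.items():
        for clf in classifiers:
            rep = train_eval(fs, clf, n_folds, seed, fold_assignment=folds)
            rows.append(
                {
                    "family": name,
                    "classifier": clf,
                    "dim": fs.dim,
                    "accuracy": rep.accuracy,
                    "accuracy_sd": rep.accuracy_sd,
                    "f1": rep.f1,
                    "f1_sd": rep.f1_sd,
                }
            )
    return pd.DataFrame(rows)
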