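"""Five-class oil classification: models, confusion-matrix metrics, repeats.

Five standard classifiers are evaluated on the balanced 5-class dataset:
decision tree (DT), linear discriminant analysis (LD), 1-nearest-neighbour
(KNN), and support vector machines with linear (SVMl) and cubic-polynomial
(SVMc) kernels.  Each run uses a stratified 80/20 holdout split; the true
positive rate (TPR) is the percentage of held-out spectra assigned to their
correct class, and the training accuracy is the 5-fold cross-validated
accuracy inside the training partition.  Per-class metrics come from a
one-vs-rest collapse of the 5x5 confusion matrix:

    sensitivity = TP / (TP + FN) * 100 %
    specificity = TN / (TN + FP) * 100 %
    accuracy    = (TP + TN) / (TP + TN + FP + FN) * 100 %
    precision   = TP / (TP + FP) * 100 %

Precision is undefined (reported as NaN, never imputed) when a class is
never predicted.  Repeated runs (default seeds 1..10) are summarised by
per-metric mean, sample standard deviation and median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

METHODS = ("DT", "LD", "KNN", "SVMl", "SVMc")


def make_classifier(method: str, seed: int = 0):
    """Instantiate one of the five classification models.

    DT: CART with Gini impurity, at most 100 splits.  LD: pooled-covariance
    linear discriminant with automatic shrinkage (mandatory at p >> n).
    KNN: k = 1, Euclidean.  SVMl/SVMc: standardized inputs, one-vs-one SVC
    with linear resp. degree-3 polynomial kernel.
    """
    if method == "DT":
        return DecisionTreeClassifier(criterion="gini", max_leaf_nodes=101,
                                      random_state=seed)
    if method == "LD":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if method == "KNN":
        return KNeighborsClassifier(n_neighbors=1, metric="euclidean")
    if method == "SVMl":
        return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0,
                                                   random_state=seed))
    if method == "SVMc":
        return make_pipeline(StandardScaler(), SVC(kernel="poly", degree=3,
                                                   gamma="scale", coef0=1.0,
                                                   random_state=seed))
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


@dataclass
class ConfusionMatrix:
    """Square confusion matrix; rows = true class, columns = predicted."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix shape does not match class names")
        if np.any(self.counts < 0):
            raise ValueError("confusion-matrix entries must be >= 0")

    def row_normalized(self) -> np.ndarray:
        """Row-percentage view (each true class sums to 100 %)."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, 100.0 * self.counts / sums, np.nan)


@dataclass
class ClassMetrics:
    """Per-class and overall classification quality in percent."""

    class_names: tuple[str, ...]
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    precision: dict[str, float]          # NaN where the class was never predicted
    class_accuracy: dict[str, float]
    tpr: float
    accuracy_training: float | None = None
    accuracy_validation: float | None = None

    def as_flat_dict(self) -> dict[str, float]:
        out: dict[str, float] = {"TPR": self.tpr}
        if self.accuracy_training is not None:
            out["accuracy_training"] = self.accuracy_training
        if self.accuracy_validation is not None:
            out["accuracy_validation"] = self.accuracy_validation
        for name in self.class_names:
            out[f"sensitivity_{name}"] = self.sensitivity[name]
            out[f"specificity_{name}"] = self.specificity[name]
            out[f"precision_{name}"] = self.precision[name]
        return out


def compute_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """One-vs-rest metrics from a confusion matrix (see module docstring)."""
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    sens, spec, prec, acc = {}, {}, {}, {}
    for i, name in enumerate(cm.class_names):
        tp = counts[i, i]
        fn = counts[i, :].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens[name] = 100.0 * tp / (tp + fn) if tp + fn > 0 else np.nan
        spec[name] = 100.0 * tn / (tn + fp) if tn + fp > 0 else np.nan
        prec[name] = 100.0 * tp / (tp + fp) if tp + fp > 0 else np.nan
        acc[name] = 100.0 * (tp + tn) / total
    tpr = 100.0 * np.trace(counts) / total
    return ClassMetrics(
        class_names=cm.class_names,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        class_accuracy=acc,
        tpr=tpr,
        accuracy_validation=float(np.mean(list(acc.values()))),
    )


def train_and_eval(X: np.ndarray, y: np.ndarray, method: str, split_seed: int = 0,
                   cv_training_accuracy: bool = True,
                   ) -> tuple[ConfusionMatrix, ClassMetrics]:
    """Fit one classifier on a stratified 80/20 split and evaluate it.

    Returns the held-out confusion matrix (class order = sorted unique
    labels) and the metrics; ``accuracy_training`` is the mean 5-fold CV
    accuracy inside the training partition (skipped when
    ``cv_training_accuracy`` is False to save time).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    class_names = tuple(np.unique(y).tolist())
    _, counts = np.unique(y, return_counts=True)
    if np.any(counts < 5):
        raise ValueError("every class needs >= 5 members for a stratified 80/20 split "
                         "with 5-fold CV")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.2, stratify=y, random_state=split_seed
    )
    model = make_classifier(method, seed=split_seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X_tr, y_tr)
        y_pred = model.predict(X_te)
    cm = ConfusionMatrix(
        _sk_confusion_matrix(y_te, y_pred, labels=list(class_names)), class_names
    )
    metrics = compute_metrics(cm)
    if cv_training_accuracy:
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=split_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = cross_val_score(clone(make_classifier(method, seed=split_seed)),
                                     X_tr, y_tr, cv=cv)
        metrics.accuracy_training = 100.0 * float(scores.mean())
    return cm, metrics


@dataclass
class RunSummary:
    """Aggregate of repeated classification runs."""

    method: str
    seeds: tuple[int, ...]
    per_run: list[ClassMetrics]
    confusion_matrices: list[ConfusionMatrix] = field(default_factory=list)

    def metric_values(self, metric: str) -> np.ndarray:
        return np.array([m.as_flat_dict().get(metric, np.nan) for m in self.per_run])

    def aggregate(self) -> dict[str, dict[str, float]]:
        """mean / sample SD / median per metric, NaN-excluding (a warning is
        emitted when undefined precisions are dropped)."""
        names = sorted({k for m in self.per_run for k in m.as_flat_dict()})
        out: dict[str, dict[str, float]] = {}
        for name in names:
            vals = self.metric_values(name)
            ok = vals[~np.isnan(vals)]
            if len(ok) < len(vals):
                warnings.warn(
                    f"{metric_warning(name, len(vals) - len(ok))}", stacklevel=2
                )
            if len(ok) == 0:
                out[name] = {"mean": np.nan, "sd": np.nan, "median": np.nan}
                continue
            out[name] = {
                "mean": float(ok.mean()),
                "sd": float(ok.std(ddof=1)) if len(ok) > 1 else 0.0,
                "median": float(np.median(ok)),
            }
        return out


def metric_warning(name: str, n: int) -> str:
    return f"metric {name!r} undefined in {n} run(s); excluded from the aggregate"


def repeat_runs(X: np.ndarray, y: np.ndarray, method: str, n_runs: int = 10,
                seeds: tuple[int, ...] | None = None,
                cv_training_accuracy: bool = True) -> RunSummary:
    """Repeat train_and_eval over ``seeds`` (default 1..n_runs) and retain
    every per-run result."""
    if seeds is None:
        seeds = tuple(range(1, n_runs + 1))
    if len(seeds) < 2:
        raise ValueError("need at least 2 runs")
    per_run: list[ClassMetrics] = []
    cms: list[ConfusionMatrix] = []
    for s in seeds:
        cm, metrics = train_and_eval(X, y, method, split_seed=int(s),
                                     cv_training_accuracy=cv_training_accuracy)
        per_run.append(metrics)
        cms.append(cm)
    return RunSummary(method=method, seeds=tuple(int(s) for s in seeds),
                      per_run=per_run, confusion_matrices=cms)


def repeat_runs_augmented(dataset, method: str, modality: str = "fused",
                          n_runs: int = 10, seeds: tuple[int, ...] | None = None,
                          cv_training_accuracy: bool = True) -> RunSummary:
    """Repeated runs where each run re-simulates the augmentation spectra and
    re-splits with the same seed, so runs are fully independent replicates."""
    from .augment import assemble_classification_set

    if seeds is None:
        seeds = tuple(range(1, n_runs + 1))
    if len(seeds) < 2:
        raise ValueError("need at least 2 runs")
    per_run: list[ClassMetrics] = []
    cms: list[ConfusionMatrix] = []
    for s in seeds:
        labelled = assemble_classification_set(dataset, modality=modality, seed=int(s))
        cm, metrics = train_and_eval(labelled.X, labelled.class_labels, method,
                                     split_seed=int(s),
                                     cv_training_accuracy=cv_training_accuracy)
        per_run.append(metrics)
        cms.append(cm)
    return RunSummary(method=method, seeds=tuple(int(s) for s in seeds),
                      per_run=per_run, confusion_matrices=cms)
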