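"""Classifier evaluation: stratified cross-validation and per-class metrics.

Five classical classifiers (decision tree, linear discriminant, Gaussian
naive Bayes, RBF-kernel SVM, nearest neighbour) are evaluated with
stratified k-fold cross-validation.  Features are z-scored inside each fold
using training-fold statistics only.  Predictions pooled over folds form a
single confusion matrix, from which one-vs-rest sensitivity, specificity,
precision and F-score are computed per class, together with macro averages
and one-vs-rest ROC AUCs from the per-fold decision scores.

``run_pipeline`` chains the full study design — deep-feature extraction,
NCAR selection, SVM cross-validation — in two flavours:

* ``paper`` mode trains the feature extractor and runs the selector on the
  full dataset, then cross-validates only the classifier.  This mirrors the
  original study design but leaks extraction/selection information across
  folds, so its accuracies are optimistic.
* ``honest`` mode nests extraction and selection inside each fold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler, label_binarize
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .nca import NCAConfig
from .ncar import ncar_select
from .relieff import ReliefFConfig

CLASSIFIER_KINDS = ("DT", "LD", "NB", "SVM", "KNN")


@dataclass
class ClassifierSpec:
    kind: str = "SVM"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; valid: {CLASSIFIER_KINDS}")

    def build(self):
        hp = dict(self.hyperparameters)
        if self.kind == "DT":
            return DecisionTreeClassifier(random_state=self.seed, **hp)
        if self.kind == "LD":
            return LinearDiscriminantAnalysis(**hp)
        if self.kind == "NB":
            return GaussianNB(**hp)
        if self.kind == "SVM":
            hp.setdefault("kernel", "rbf")
            return SVC(random_state=self.seed, **hp)
        hp.setdefault("n_neighbors", 1)
        return KNeighborsClassifier(**hp)


@dataclass
class MetricsReport:
    classes: list
    confusion: np.ndarray
    per_class: dict  # metric name -> array over classes
    macro: dict  # metric name -> float
    accuracy: float
    auc_ovr: dict | None = None  # per-class + "macro"
    fold_assignments: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "per_class": {k: np.asarray(v).tolist() for k, v in self.per_class.items()},
            "macro": self.macro,
            "accuracy": self.accuracy,
            "auc_ovr": self.auc_ovr,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def per_class_metrics(confusion: np.ndarray, classes: list | None = None) -> MetricsReport:
    """One-vs-rest sensitivity/specificity/precision/F-score from a confusion matrix.

    Rows are true classes, columns predicted.  Undefined ratios (empty
    denominators) are reported as NaN with a warning.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got shape {cm.shape}")
    C = cm.shape[0]
    if classes is None:
        classes = list(range(C))
    total = cm.sum()
    tp = np.diag(cm)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp

    def ratio(num, den, name):
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
        if np.isnan(out).any():
            warnings.warn(f"{name} undefined for some classes (empty denominator)", stacklevel=3)
        return out

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    prec = ratio(tp, tp + fp, "precision")
    with np.errstate(invalid="ignore"):
        f_score = np.where(
            (sens + prec) > 0, 2.0 * sens * prec / np.where((sens + prec) > 0, sens + prec, 1), np.nan
        )
    per_class = {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f_score": f_score,
    }
    macro = {k: float(np.nanmean(v)) for k, v in per_class.items()}
    accuracy = float(tp.sum() / total) if total > 0 else float("nan")
    return MetricsReport(
        classes=list(classes),
        confusion=np.asarray(confusion),
        per_class=per_class,
        macro=macro,
        accuracy=accuracy,
    )


def f_score(sensitivity: float, precision: float) -> float:
    """Harmonic mean of sensitivity (recall) and precision."""
    if sensitivity + precision == 0:
        return float("nan")
    return 2.0 * sensitivity * precision / (sensitivity + precision)


def macro_average(values) -> float:
    """Unweighted mean over classes."""
    return float(np.nanmean(np.asarray(values, dtype=float)))


def stratified_cv(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec | None = None,
    k: int = 10,
    seed: int = 0,
) -> MetricsReport:
    """Stratified k-fold CV with in-fold z-scoring; pooled confusion and OvR AUC."""
    spec = spec or ClassifierSpec()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            f"smallest class has {counts.min()} members; reducing folds from {k}",
            stacklevel=2,
        )
        k = max(2, int(counts.min()))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    C = classes.size
    cm = np.zeros((C, C), dtype=int)
    fold_assign = np.full(len(y), -1)
    scores = np.full((len(y), C), np.nan)
    class_index = {c: i for i, c in enumerate(classes)}

    for fold, (tr, te) in enumerate(skf.split(X, y)):
        scaler = StandardScaler().fit(X[tr])
        clf = spec.build()
        clf.fit(scaler.transform(X[tr]), y[tr])
        Xte = scaler.transform(X[te])
        pred = clf.predict(Xte)
        for yt, yp in zip(y[te], pred):
            cm[class_index[yt], class_index[yp]] += 1
        fold_assign[te] = fold
        s = _decision_scores(clf, Xte, classes)
        if s is not None:
            scores[te] = s

    report = per_class_metrics(cm, list(classes))
    report.fold_assignments = fold_assign
    if not np.isnan(scores).all():
        report.auc_ovr = _ovr_auc(y, scores, classes)
    return report


def _decision_scores(clf, X, classes) -> np.ndarray | None:
    """Per-class scores aligned to the global class order, for ROC curves."""
    if hasattr(clf, "predict_proba"):
        try:
            s = clf.predict_proba(X)
        except AttributeError:  # pragma: no cover
            s = None
        else:
            cols = {c: i for i, c in enumerate(clf.classes_)}
            out = np.zeros((len(X), len(classes)))
            for j, c in enumerate(classes):
                if c in cols:
                    out[:, j] = s[:, cols[c]]
            return out
    if hasattr(clf, "decision_function"):
        s = np.asarray(clf.decision_function(X))
        if s.ndim == 1:  # binary: score for the positive (second) class
            out = np.column_stack([-s, s])
            return out
        cols = {c: i for i, c in enumerate(clf.classes_)}
        out = np.full((len(X), len(classes)), -np.inf)
        for j, c in enumerate(classes):
            if c in cols:
                out[:, j] = s[:, cols[c]]
        return out
    return None


def _ovr_auc(y, scores, classes) -> dict:
    Y = label_binarize(y, classes=list(classes))
    if Y.shape[1] == 1:  # binary comes back as one column
        Y = np.column_stack([1 - Y[:, 0], Y[:, 0]])
    aucs = {}
    vals = []
    for j, c in enumerate(classes):
        try:
            a = float(roc_auc_score(Y[:, j], scores[:, j]))
        except ValueError:
            a = float("nan")
        aucs[str(c)] = a
        vals.append(a)
    aucs["macro"] = float(np.nanmean(vals))
    return aucs


@dataclass
class PipelineConfig:
    """Settings for the extract -> select -> classify chain."""

    mode: str = "paper"  # "paper" trains extractor on all data; "honest" nests it
    thr1: float = 0.0005
    thr2: float = 0.01
    nca_cfg: NCAConfig | None = None
    relieff_cfg: ReliefFConfig | None = None
    classifier: ClassifierSpec | None = None
    cv_folds: int = 10
    seed: int = 0
    model_config: "object | None" = None  # ModelConfig; None -> defaults
    train_config: "object | None" = None  # TrainConfig; None -> defaults

    def __post_init__(self) -> None:
        if self.mode not in ("paper", "honest"):
            raise ValueError("mode must be 'paper' or 'honest'")


def run_pipeline(
    data: np.ndarray,
    labels: np.ndarray,
    config: PipelineConfig | None = None,
) -> MetricsReport:
    """Run the full chain on images (4-D input) or a ready feature table (2-D).

    Image input triggers extractor training and FC1 feature extraction;
    2-D input skips straight to selection + cross-validated classification.
    """
    config = config or PipelineConfig()
    data = np.asarray(data)
    y = np.asarray(labels)
    spec = config.classifier or ClassifierSpec("SVM")
    # deep features carry many near-redundant columns; the quasi-Newton NCA
    # solver resolves their near-zero weights so the level-1 threshold bites
    nca_cfg = config.nca_cfg or NCAConfig(solver="lbfgs", max_iters=1000)

    if data.ndim == 2:
        sel = ncar_select(data, y, nca_cfg, config.relieff_cfg, config.thr1, config.thr2)
        return stratified_cv(data[:, sel.keep_mask], y, spec, config.cv_folds, config.seed)
    if data.ndim != 4:
        raise ValueError("data must be a 2-D feature table or a 4-D image stack")

    from .model import ModelConfig, TrainConfig, build_model, extract_deep_features, train_model

    mcfg = config.model_config or ModelConfig(n_classes=len(np.unique(y)))
    tcfg = config.train_config or TrainConfig()

    if config.mode == "paper":
        model = build_model(mcfg, seed=config.seed)
        model, _ = train_model(model, data, y, tcfg)
        feats = extract_deep_features(model, data).matrix
        sel = ncar_select(feats, y, nca_cfg, config.relieff_cfg, config.thr1, config.thr2)
        return stratified_cv(feats[:, sel.keep_mask], y, spec, config.cv_folds, config.seed)

    # honest mode: extraction and selection are fitted inside each fold
    classes, counts = np.unique(y, return_counts=True)
    k = config.cv_folds
    if counts.min() < k:
        warnings.warn(f"reducing folds to smallest class size {counts.min()}", stacklevel=2)
        k = max(2, int(counts.min()))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    C = classes.size
    class_index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((C, C), dtype=int)
    fold_assign = np.full(len(y), -1)
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        model = build_model(mcfg, seed=config.seed + fold)
        model, _ = train_model(model, data[tr], y[tr], tcfg)
        ftr = extract_deep_features(model, data[tr]).matrix
        fte = extract_deep_features(model, data[te]).matrix
        sel = ncar_select(ftr, y[tr], nca_cfg, config.relieff_cfg, config.thr1, config.thr2)
        scaler = StandardScaler().fit(ftr[:, sel.keep_mask])
        clf = spec.build()
        clf.fit(scaler.transform(ftr[:, sel.keep_mask]), y[tr])
        pred = clf.predict(scaler.transform(fte[:, sel.keep_mask]))
        for yt, yp in zip(y[te], pred):
            cm[class_index[yt], class_index[yp]] += 1
        fold_assign[te] = fold
    report = per_class_metrics(cm, list(classes))
    report.fold_assignments = fold_assign
    return report
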