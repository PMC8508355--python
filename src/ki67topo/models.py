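"""Prognosis classifiers and baselines.

k-NN (k = 3, squared-inverse-distance weighting, nearest-neighbour tie
break), a cubic-polynomial-kernel soft-margin SVM, repeated stratified
5-fold cross-validation with per-repetition pooled confusion counts, and
single-metric threshold baselines. The positive class is "PP".
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

POSITIVE_CLASS = "PP"


@dataclass
class CVReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    accuracy_se: float
    n_features_used: int
    per_histology_accuracy: dict = field(default_factory=dict)
    reps: int = 0
    folds: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "accuracy_se": self.accuracy_se,
            "n_features_used": self.n_features_used,
            "per_histology_accuracy": self.per_histology_accuracy,
            "reps": self.reps,
            "folds": self.folds,
        }


@dataclass
class ThresholdBaseline:
    metric_name: str
    optimal_threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    per_histology_accuracy: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _zscore_train_test(x_train, x_test):
    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (x_train - mu) / sd, (x_test - mu) / sd


def knn_predict(x_train, y_train, x_test, k: int = 3) -> np.ndarray:
    """Weighted k-NN with 1/d² votes.

    A test point coinciding with a training point adopts that point's
    label; vote ties go to the class of the single nearest neighbour.
    """
    x_train = np.asarray(x_train, float)
    x_test = np.asarray(x_test, float)
    y_train = np.asarray(y_train)
    if len(x_train) < k:
        raise ValueError(f"k={k} exceeds {len(x_train)} training samples")
    classes = np.unique(y_train)
    preds = []
    for xt in x_test:
        d = np.sqrt(((x_train - xt) ** 2).sum(axis=1))
        order = np.argsort(d, kind="stable")
        if d[order[0]] == 0.0:
            preds.append(y_train[order[0]])
            continue
        nearest = order[:k]
        wts = 1.0 / d[nearest] ** 2
        scores = np.array([wts[y_train[nearest] == c].sum() for c in classes])
        best = scores.max()
        tied = classes[scores == best]
        if len(tied) > 1:
            # tie-break toward the class of the nearest neighbour among the tied
            for i in nearest:
                if y_train[i] in tied:
                    preds.append(y_train[i])
                    break
        else:
            preds.append(tied[0])
    return np.asarray(preds)


def svm_fit_predict(x_train, y_train, x_test, degree: int = 3, c: float = 1.0) -> np.ndarray:
    """Soft-margin SVM with kernel (1 + <u, v>)^degree, box constraint c."""
    from sklearn.svm import SVC

    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        warnings.warn("single-class training fold: predicting that class", stacklevel=2)
        return np.full(len(x_test), y_train[0])
    clf = SVC(kernel="poly", degree=degree, gamma=1.0, coef0=1.0, C=c, tol=1e-6)
    clf.fit(x_train, y_train)
    return clf.predict(x_test)


def _stratified_folds(y, n_folds, rng):
    folds = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % n_folds].append(i)
    return [np.asarray(sorted(f), dtype=int) for f in folds]


def _confusion(y_true, y_pred):
    pos = POSITIVE_CLASS
    tp = int(np.sum((y_true == pos) & (y_pred == pos)))
    tn = int(np.sum((y_true != pos) & (y_pred != pos)))
    fp = int(np.sum((y_true != pos) & (y_pred == pos)))
    fn = int(np.sum((y_true == pos) & (y_pred != pos)))
    return tp, tn, fp, fn


def _metrics(tp, tn, fp, fn):
    n = tp + tn + fp + fn
    acc = (tp + tn) / n if n else 0.0
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    return acc, sens, spec, prec


def repeated_cv(
    table: pd.DataFrame,
    labels,
    model: str = "knn",
    n_features: Optional[int] = None,
    ranking: Optional[list[str]] = None,
    reps: int = 100,
    folds: int = 5,
    seed: int = 0,
    histology=None,
    k: int = 3,
) -> CVReport:
    """Repeated stratified 5-fold CV with per-repetition pooled confusion.

    Features are z-scored on each training fold. When ``ranking`` is
    given, the top ``n_features`` of it are used.
    """
    y = np.asarray(labels)
    if ranking is not None and n_features is not None:
        cols = ranking[:n_features]
    elif n_features is not None:
        cols = list(table.columns[:n_features])
    else:
        cols = list(table.columns)
    x = table[cols].to_numpy(dtype=float)
    hist = np.asarray(histology) if histology is not None else None
    rng = np.random.default_rng(seed)
    accs, senss, specs, precs = [], [], [], []
    hist_hits: dict[str, list] = {}
    for _ in range(reps):
        fold_sets = _stratified_folds(y, folds, rng)
        tp = tn = fp = fn = 0
        preds_all = np.empty(len(y), dtype=y.dtype)
        for kf in range(folds):
            test = fold_sets[kf]
            train = np.setdiff1d(np.arange(len(y)), test)
            xtr, xte = _zscore_train_test(x[train], x[test])
            if model == "knn":
                pred = knn_predict(xtr, y[train], xte, k=k)
            elif model == "svm":
                pred = svm_fit_predict(xtr, y[train], xte)
            else:
                raise ValueError(f"unknown model {model!r}")
            preds_all[test] = pred
            dtp, dtn, dfp, dfn = _confusion(y[test], pred)
            tp, tn, fp, fn = tp + dtp, tn + dtn, fp + dfp, fn + dfn
        acc, sens, spec, prec = _metrics(tp, tn, fp, fn)
        accs.append(acc)
        senss.append(sens)
        specs.append(spec)
        precs.append(prec)
        if hist is not None:
            for h in np.unique(hist):
                hist_hits.setdefault(str(h), []).append(
                    float(np.mean(preds_all[hist == h] == y[hist == h]))
                )
    accs = np.asarray(accs)
    return CVReport(
        accuracy=float(accs.mean()),
        sensitivity=float(np.mean(senss)),
        specificity=float(np.mean(specs)),
        precision=float(np.mean(precs)),
        accuracy_se=float(accs.std(ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else 0.0,
        n_features_used=len(cols),
        per_histology_accuracy={h: float(np.mean(v)) for h, v in hist_hits.items()},
        reps=reps,
        folds=folds,
    )


def cv_sweep(
    table, labels, ranking, model="knn", n_range=range(3, 24), reps=100, folds=5,
    seed=0, histology=None,
) -> pd.DataFrame:
    """Metric table over the top-n feature sweep (n = 3..23 by default)."""
    rows = []
    for n in n_range:
        if n > len(ranking):
            break
        rep = repeated_cv(
            table, labels, model=model, n_features=n, ranking=ranking,
            reps=reps, folds=folds, seed=seed, histology=histology,
        )
        rows.append({"n_features": n, **{k: v for k, v in rep.to_dict().items()
                                         if not isinstance(v, dict)}})
    return pd.DataFrame(rows)


def threshold_baseline(values, labels, metric_name: str = "metric",
                       histology=None) -> ThresholdBaseline:
    """Accuracy-maximising single-metric threshold (value >= t -> PP).

    Candidates are midpoints between consecutive sorted unique values
    plus ±infinity; ties keep the lowest threshold.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    uniq = np.unique(v)
    cands = [-np.inf]
    cands += list((uniq[:-1] + uniq[1:]) / 2.0)
    cands.append(np.inf)
    best_t, best_acc = None, -1.0
    for t in cands:
        pred = np.where(v >= t, POSITIVE_CLASS, "GP")
        acc = float(np.mean(pred == y))
        if acc > best_acc:
            best_acc, best_t = acc, t
    pred = np.where(v >= best_t, POSITIVE_CLASS, "GP")
    acc, sens, spec, prec = _metrics(*_confusion(y, pred))
    per_hist = {}
    if histology is not None:
        hist = np.asarray(histology)
        for h in np.unique(hist):
            per_hist[str(h)] = float(np.mean(pred[hist == h] == y[hist == h]))
    return ThresholdBaseline(
        metric_name=metric_name,
        optimal_threshold=float(best_t),
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        per_histology_accuracy=per_hist,
    )
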