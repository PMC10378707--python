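"""Classifiers, cross-validated evaluation metrics, and the region/band
comparison harness.

Six classifier families are supported: SVM with linear / RBF / polynomial
kernels (one-vs-rest), k-nearest neighbors (k = 1, Euclidean), random forest
(500 trees, sqrt-feature splits) and an MC-dropout Bayesian neural network.
Evaluation uses stratified 10-fold cross-validation; accuracy is multi-class,
precision and recall are one-vs-rest macro averages, and
F1 = 2·precision·recall / (precision + recall) from the macro averages
(a variant computing F1 from accuracy instead of precision is available
behind ``f1_variant="accuracy"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .bnn import BNNConfig, MCDropoutBNN
from .core import CHANNEL_REGION, REGIONS
from .features import BAND_NAMES
from .selection import zscore

CLASSIFIER_KINDS = ("SVM-L", "SVM-R", "SVM-P", "KNN", "RF", "BNN")


@dataclass
class ClassifierSpec:
    """A named classifier with its hyperparameters.

    Defaults follow the reference settings: KNN with k = 1 neighbors and
    Euclidean distance, RF with 500 trees, SVM kernels via one-vs-rest,
    BNN per :class:`~mwl_eeg.bnn.BNNConfig`.
    """

    kind: str = "KNN"
    k: int = 1
    n_trees: int = 500
    sigma: float | None = None  # RBF kernel width; None -> sklearn 'scale'
    degree: int = 3  # polynomial degree; 1 degenerates to linear
    bnn: BNNConfig = field(default_factory=BNNConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.k < 1 or self.n_trees < 1 or self.degree < 1:
            raise ValueError("k, n_trees and degree must be >= 1")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")


def make_estimator(spec: ClassifierSpec):
    """Instantiate the scikit-learn (or BNN) estimator for a spec."""
    spec.validate()
    if spec.kind == "KNN":
        return KNeighborsClassifier(n_neighbors=spec.k, metric="euclidean")
    if spec.kind == "RF":
        return RandomForestClassifier(
            n_estimators=spec.n_trees, max_features="sqrt",
            bootstrap=True, random_state=spec.seed,
        )
    if spec.kind.startswith("SVM"):
        gamma = "scale" if spec.sigma is None else 1.0 / spec.sigma**2
        if spec.kind == "SVM-L":
            svc = SVC(kernel="linear", random_state=spec.seed)
        elif spec.kind == "SVM-R":
            svc = SVC(kernel="rbf", gamma=gamma, random_state=spec.seed)
        else:
            svc = SVC(kernel="poly", degree=spec.degree, gamma=gamma,
                      random_state=spec.seed)
        return OneVsRestClassifier(svc)
    if spec.kind == "BNN":
        cfg = BNNConfig(**{**spec.bnn.__dict__, "seed": spec.seed})
        return MCDropoutBNN(cfg)
    raise AssertionError


# ---------------------------------------------------------------------------
# metrics

@dataclass
class MetricsReport:
    """Multi-class accuracy plus one-vs-rest macro precision/recall/F1 and
    the per-class confusion counts they derive from."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def compute_metrics(y_true, y_pred, f1_variant: str = "standard") -> MetricsReport:
    """Metrics from first principles: per class, one-vs-rest TP/TN/FP/FN
    counts give precision TP/(TP+FP) and recall TP/(TP+FN), macro-averaged
    with equal class weight; zero-denominator ratios count as 0 (flagged)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    accuracy = float(np.mean(y_true == y_pred))
    per_class = {}
    precisions, recalls = [], []
    flags: list[str] = []
    for cls in classes:
        tp = int(np.sum((y_true == cls) & (y_pred == cls)))
        fp = int(np.sum((y_true != cls) & (y_pred == cls)))
        fn = int(np.sum((y_true == cls) & (y_pred != cls)))
        tn = int(np.sum((y_true != cls) & (y_pred != cls)))
        if tp + fp == 0:
            flags.append(f"precision undefined for class {cls!r}; set to 0")
            prec = 0.0
        else:
            prec = tp / (tp + fp)
        if tp + fn == 0:
            flags.append(f"recall undefined for class {cls!r}; set to 0")
            rec = 0.0
        else:
            rec = tp / (tp + fn)
        per_class[str(cls)] = {"TP": tp, "TN": tn, "FP": fp, "FN": fn,
                               "precision": prec, "recall": rec}
        precisions.append(prec)
        recalls.append(rec)
    precision = float(np.mean(precisions))
    recall = float(np.mean(recalls))
    first = accuracy if f1_variant == "accuracy" else precision
    if f1_variant not in ("standard", "accuracy"):
        raise ValueError(f"unknown f1_variant {f1_variant!r}")
    f1 = 0.0 if first + recall == 0 else 2 * first * recall / (first + recall)
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall,
                         f1=float(f1), per_class=per_class, flags=flags)


@dataclass
class CVReport:
    """Per-fold metrics with mean ± SD aggregates."""

    folds: list[MetricsReport]
    spec_kind: str = ""
    seed: int = 0

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(f, metric) for f in self.folds]))

    def std(self, metric: str) -> float:
        return float(np.std([getattr(f, metric) for f in self.folds]))

    def summary(self) -> dict[str, tuple[float, float]]:
        return {m: (self.mean(m), self.std(m))
                for m in ("accuracy", "precision", "recall", "f1")}

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": m, "mean": mu, "std": sd}
            for m, (mu, sd) in self.summary().items()
        ]
        return pd.DataFrame(rows)


def crossvalidate(
    spec: ClassifierSpec,
    features: pd.DataFrame,
    label_col: str = "mwl",
    columns: list[str] | None = None,
    folds: int = 10,
    standardize: str = "fold",  # "fold" (leakage-safe), "global", or "none"
    f1_variant: str = "standard",
) -> CVReport:
    """Stratified k-fold evaluation of a classifier spec on a feature table.

    z-scoring is fitted inside each training fold by default; ``"global"``
    standardizes on all rows first (the convention some analyses use), and
    ``"none"`` leaves features raw. Deterministic for a fixed (spec, data).
    """
    from sklearn.base import clone
    from sklearn.model_selection import StratifiedKFold

    if columns is None:
        columns = [c for c in features.columns
                   if c not in ("phase", "mwl", "start_s", label_col)]
    if not columns:
        raise ValueError("empty column selection")
    y = features[label_col].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has {counts.min()} samples "
            f"< {folds} folds"
        )
    df = features
    if standardize == "global":
        df = zscore(df, columns=columns)
    X = df[columns].to_numpy(dtype=float)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    fold_reports: list[MetricsReport] = []
    for train_idx, test_idx in skf.split(X, y):
        X_tr, X_te = X[train_idx], X[test_idx]
        if standardize == "fold":
            mu = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0)
            sd[sd == 0.0] = 1.0
            X_tr = (X_tr - mu) / sd
            X_te = (X_te - mu) / sd
        est = make_estimator(spec)
        try:
            est = clone(est)
        except Exception:
            pass
        est.fit(X_tr, y[train_idx])
        pred = est.predict(X_te)
        fold_reports.append(compute_metrics(y[test_idx], pred, f1_variant=f1_variant))
    return CVReport(folds=fold_reports, spec_kind=spec.kind, seed=spec.seed)


# ---------------------------------------------------------------------------
# region / band harness

def region_band_columns(region: str, band: str,
                        channel_names: list[str]) -> list[str]:
    """PSD columns for a (region, band) cell; region 'all' spans every
    channel, band 'mix' spans all six bands."""
    if region == "all":
        chans = list(channel_names)
    else:
        chans = [ch for ch in channel_names if CHANNEL_REGION.get(ch) == region]
    bands = list(BAND_NAMES) if band == "mix" else [band]
    return [f"{ch}-{b}" for ch in chans for b in bands]


def region_band_harness(
    features: pd.DataFrame,
    label_col: str = "mwl",
    folds: int = 10,
    seed: int = 0,
    regions: tuple[str, ...] = REGIONS + ("all",),
    bands: tuple[str, ...] = BAND_NAMES + ("mix",),
) -> pd.DataFrame:
    """Evaluate KNN (k = 1) on the PSD features of every region x band cell;
    returns a tidy table of mean ± SD metrics per cell."""
    channel_names = sorted(
        {c.split("-")[0] for c in features.columns if "-" in c}
        & set(CHANNEL_REGION),
        key=list(CHANNEL_REGION).index,
    )
    spec = ClassifierSpec(kind="KNN", k=1, seed=seed)
    rows = []
    for region in regions:
        for band in bands:
            cols = [c for c in region_band_columns(region, band, channel_names)
                    if c in features.columns]
            if not cols:
                raise ValueError(f"no PSD columns for ({region}, {band})")
            report = crossvalidate(spec, features, label_col=label_col,
                                   columns=cols, folds=folds)
            row = {"region": region, "band": band, "n_features": len(cols)}
            for m, (mu, sd) in report.summary().items():
                row[f"{m}_mean"] = mu
                row[f"{m}_std"] = sd
            rows.append(row)
    return pd.DataFrame(rows)
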