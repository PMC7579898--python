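"""Classifier training and cross-validated evaluation.

Three classifier families are supported, mirroring the screening study's
protocol: k-nearest neighbours (with correlation/Minkowski distances and
inverse / squared-inverse distance weighting), support vector machines
(linear/quadratic/cubic/RBF kernels) and naive Bayes (Gaussian, or a
per-feature kernel-density variant with box/Epanechnikov/Gaussian kernels).

Evaluation is stratified k-fold cross-validation (tenfold by default) with
confusion counts pooled over folds. For the binary PD-vs-healthy protocol
sensitivity is TP/(TP+FN) on the PD class and specificity TN/(TN+FP); for
the 5-level UPDRS protocol (labels 0-4) sensitivity/specificity are macro
one-vs-rest averages. Features are z-scored inside each training fold only,
so no information leaks from the held-out fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KernelDensity, KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import FoldError, ParameterError
from .io_formats import LabeledFeatureTable

_SVM_KERNELS = {"linear": ("linear", 1), "quadratic": ("poly", 2),
                "cubic": ("poly", 3), "rbf": ("rbf", 1)}
_NB_KERNELS = {"gaussian", "box", "epanechnikov"}
_KDE_KERNEL_MAP = {"box": "tophat", "epanechnikov": "epanechnikov",
                   "gaussian": "gaussian"}


def _squared_inverse(dist: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        w = 1.0 / (dist ** 2)
    # exact matches get all the weight
    inf_rows = np.isinf(w).any(axis=1)
    w[inf_rows] = np.isinf(w[inf_rows]).astype(float)
    return w


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm name plus validated hyperparameters.

    kNN params: ``k`` (int), ``metric`` ('euclidean', 'minkowski',
    'correlation', ...), ``weights`` ('uniform', 'inverse',
    'squared_inverse'). SVM params: ``kernel`` ('linear', 'quadratic',
    'cubic', 'rbf'), optional ``C``. NB params: ``kernel`` ('gaussian',
    'box', 'epanechnikov').
    """

    algo: str
    params: tuple[tuple[str, Any], ...] = field(default_factory=tuple)

    def __init__(self, algo: str, params: dict[str, Any] | None = None):
        params = dict(params or {})
        if algo == "knn":
            k = params.setdefault("k", 5)
            if not (isinstance(k, (int, np.integer)) and k >= 1):
                raise ParameterError(f"kNN k must be a positive int, got {k}")
            params.setdefault("metric", "euclidean")
            w = params.setdefault("weights", "uniform")
            if w not in ("uniform", "inverse", "squared_inverse"):
                raise ParameterError(f"unknown kNN weighting {w!r}")
        elif algo == "svm":
            kern = params.setdefault("kernel", "quadratic")
            if kern not in _SVM_KERNELS:
                raise ParameterError(f"unknown SVM kernel {kern!r}")
            params.setdefault("C", 1.0)
        elif algo == "nb":
            kern = params.setdefault("kernel", "gaussian")
            if kern not in _NB_KERNELS:
                raise ParameterError(f"unknown NB kernel {kern!r}")
        else:
            raise ParameterError(f"algo must be knn/svm/nb, got {algo!r}")
        object.__setattr__(self, "algo", algo)
        object.__setattr__(self, "params", tuple(sorted(params.items())))

    @property
    def param_dict(self) -> dict[str, Any]:
        return dict(self.params)

    def complexity(self) -> float:
        """Ordering key used to prefer simpler models on CV-accuracy ties."""
        p = self.param_dict
        if self.algo == "knn":
            return float(p["k"])
        if self.algo == "svm":
            return float(_SVM_KERNELS[p["kernel"]][1])
        return 0.0


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature 1-D kernel density class conditionals."""

    def __init__(self, kernel: str = "epanechnikov", bandwidth: float | None = None):
        self.kernel = kernel
        self.bandwidth = bandwidth

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.priors_ = np.array([np.mean(y == c) for c in self.classes_])
        self.kdes_ = []
        for c in self.classes_:
            Xc = X[y == c]
            feats = []
            for j in range(X.shape[1]):
                col = Xc[:, j][:, None]
                bw = self.bandwidth
                if bw is None:  # Scott's rule with a sane floor
                    bw = max(1e-3, 1.06 * col.std() * len(col) ** (-1 / 5))
                kde = KernelDensity(kernel=_KDE_KERNEL_MAP[self.kernel],
                                    bandwidth=bw).fit(col)
                feats.append(kde)
            self.kdes_.append(feats)
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, float)
        out = np.empty((len(X), len(self.classes_)))
        floor = np.log(1e-12)
        for i, feats in enumerate(self.kdes_):
            ll = np.log(self.priors_[i])
            total = np.zeros(len(X)) + ll
            for j, kde in enumerate(feats):
                lp = kde.score_samples(X[:, j][:, None])
                total += np.logaddexp(lp, floor)
            out[:, i] = total
        return out

    def predict(self, X):
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]

    def predict_proba(self, X):
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)


def build_estimator(spec: ModelSpec) -> Pipeline:
    """Scaler + classifier pipeline for a validated spec."""
    p = spec.param_dict
    if spec.algo == "knn":
        weights = {"uniform": "uniform", "inverse": "distance",
                   "squared_inverse": _squared_inverse}[p["weights"]]
        clf = KNeighborsClassifier(
            n_neighbors=p["k"], metric=p["metric"], weights=weights,
            algorithm="brute" if p["metric"] == "correlation" else "auto")
    elif spec.algo == "svm":
        kernel, degree = _SVM_KERNELS[p["kernel"]]
        clf = SVC(kernel=kernel, degree=degree, C=p["C"], gamma="scale",
                  coef0=1.0, decision_function_shape="ovo")
    else:
        clf = (GaussianNB() if p["kernel"] == "gaussian"
               else KernelNaiveBayes(kernel=p["kernel"]))
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class EvalReport:
    """Cross-validation aggregate: metrics in %, per-fold confusion counts."""

    accuracy: float
    specificity: float
    sensitivity: float
    fold_confusions: list[np.ndarray]   # per fold, (c x c) counts
    classes: list
    n_features: int
    stratum: str
    levels: int

    def pooled_confusion(self) -> np.ndarray:
        return np.sum(self.fold_confusions, axis=0)


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int,
                           ) -> dict[str, float]:
    """Accuracy / sensitivity / specificity (%) from binary confusion counts."""
    n = tp + fn + tn + fp
    if n == 0:
        raise ParameterError("empty confusion table")
    return {
        "accuracy": 100.0 * (tp + tn) / n,
        "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else 0.0,
        "specificity": 100.0 * tn / (tn + fp) if tn + fp else 0.0,
    }


def _labels_for(table: LabeledFeatureTable, levels: int) -> np.ndarray:
    if levels == 2:
        return table.status.to_numpy()
    if levels == 5:
        u = table.updrs.to_numpy(dtype=float)
        if np.any(~np.isfinite(u)):
            raise ParameterError("5-level protocol needs a UPDRS value per row")
        return u.astype(int)
    raise ParameterError(f"levels must be 2 or 5, got {levels}")


def _macro_ovr(conf: np.ndarray) -> tuple[float, float]:
    """Macro one-vs-rest sensitivity/specificity (%) from a c x c table."""
    c = conf.shape[0]
    sens, spec = [], []
    total = conf.sum()
    for i in range(c):
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens.append(tp / (tp + fn) if tp + fn else 0.0)
        spec.append(tn / (tn + fp) if tn + fp else 0.0)
    return 100.0 * float(np.mean(sens)), 100.0 * float(np.mean(spec))


def cross_validate(table: LabeledFeatureTable, spec: ModelSpec,
                   folds: int = 10, seed: int = 0, levels: int = 2,
                   stratum: str = "all") -> EvalReport:
    """Stratified k-fold evaluation; deterministic for a given seed."""
    y = _labels_for(table, levels)
    X = table.features.to_numpy(dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise FoldError(
            f"smallest class has {counts.min()} rows < {folds} folds; "
            f"use at most {counts.min()} folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    cls_index = {c: i for i, c in enumerate(classes)}
    fold_confs = []
    for train, test in skf.split(X, y):
        est = build_estimator(spec)
        est.fit(X[train], y[train])
        pred = est.predict(X[test])
        conf = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p_ in zip(y[test], pred):
            conf[cls_index[t], cls_index[p_]] += 1
        fold_confs.append(conf)
    pooled = np.sum(fold_confs, axis=0)
    accuracy = 100.0 * np.trace(pooled) / pooled.sum()
    if levels == 2:
        ipd = cls_index.get("PD")
        ihe = cls_index.get("healthy")
        tp = pooled[ipd, ipd]
        fn = pooled[ipd].sum() - tp
        tn = pooled[ihe, ihe]
        fp = pooled[:, ipd].sum() - tp
        m = metrics_from_confusion(tp, fn, tn, fp)
        sens, spec_ = m["sensitivity"], m["specificity"]
    else:
        sens, spec_ = _macro_ovr(pooled)
    return EvalReport(float(accuracy), float(spec_), float(sens),
                      fold_confs, list(classes), X.shape[1], stratum, levels)


def default_grid(algo: str) -> list[ModelSpec]:
    """Hyperparameter presets echoing the screening study's optimizer space."""
    if algo == "knn":
        return [ModelSpec("knn", {"k": k, "metric": m, "weights": w})
                for k in (1, 2, 3, 5, 9, 17, 33, 57)
                for m in ("minkowski", "correlation")
                for w in ("uniform", "inverse", "squared_inverse")]
    if algo == "svm":
        return [ModelSpec("svm", {"kernel": k})
                for k in ("linear", "quadratic", "cubic")]
    if algo == "nb":
        return [ModelSpec("nb", {"kernel": k})
                for k in ("gaussian", "box", "epanechnikov")]
    raise ParameterError(f"algo must be knn/svm/nb, got {algo!r}")


def optimize(table: LabeledFeatureTable, algo: str,
             grid: Sequence[ModelSpec] | None = None, folds: int = 10,
             seed: int = 0, levels: int = 2) -> tuple[ModelSpec, EvalReport]:
    """Grid search maximizing CV accuracy; ties go to the simpler model."""
    if grid is None:
        grid = default_grid(algo)
    grid = list(grid)
    if not grid:
        raise ParameterError("hyperparameter grid is empty")
    for spec in grid:
        if spec.algo != algo:
            raise ParameterError(
                f"grid entry for {spec.algo!r} in an {algo!r} search")
    # drop kNN entries whose k exceeds the guaranteed training-fold size
    n_train_min = (len(table) * (folds - 1)) // folds
    feasible = [s for s in grid
                if s.algo != "knn" or s.param_dict["k"] <= n_train_min]
    if not feasible:
        raise ParameterError(
            f"no grid entry is feasible for {len(table)} rows at {folds} folds")
    ordered = sorted(feasible, key=lambda s: s.complexity())
    best: tuple[ModelSpec, EvalReport] | None = None
    for spec in ordered:
        rep = cross_validate(table, spec, folds=folds, seed=seed, levels=levels)
        if best is None or rep.accuracy > best[1].accuracy:
            best = (spec, rep)
    return best


def train_final(table: LabeledFeatureTable, spec: ModelSpec,
                levels: int = 2) -> Pipeline:
    """Fit the spec's pipeline on the full table."""
    y = _labels_for(table, levels)
    X = table.features.to_numpy(dtype=float)
    est = build_estimator(spec)
    est.fit(X, y)
    return est


def predict(model: Pipeline, rows: np.ndarray,
            ) -> tuple[np.ndarray, np.ndarray | None]:
    """Labels plus per-class scores (None when the model exposes no scores)."""
    rows = np.asarray(rows, float)
    if rows.ndim == 1:
        rows = rows[None, :]
    labels = model.predict(rows)
    scores = None
    clf = model.named_steps["clf"]
    if hasattr(clf, "predict_proba"):
        scores = model.predict_proba(rows)
    elif hasattr(model, "decision_function"):
        scores = model.decision_function(rows)
    return labels, scores
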