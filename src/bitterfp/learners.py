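"""Grid-searched training of the six learner families with 5-fold CV.

Methods: KNN, SVM (RBF kernel with probability calibration), RF, GBM, and
two fully-connected neural networks (DNN2/DNN3: two or three hidden layers
of width equal to the input width, ReLU, adam). The neural networks are
scikit-learn multilayer perceptrons; their regularization grid axis is an L2
penalty (alpha) rather than dropout, which MLPClassifier does not expose.

For every grid point the mean F1 over the five internal-validation folds is
computed; the argmax point wins (ties: first in enumeration order) and the
final model is refit on the entire CV pool at those hyperparameters.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .data_split import SplitScheme
from .metrics import NA, compute_metrics, confusion, is_na

__all__ = [
    "METHODS",
    "HyperGrid",
    "TrainedModel",
    "default_grid",
    "grid_search_cv",
    "rf_feature_importance",
    "select_top_features",
    "predict_proba",
    "ExperimentPlan",
]

METHODS = ("KNN", "SVM", "RF", "GBM", "DNN2", "DNN3")

_TREE_COUNTS = [10, 50, 100, 200, 300, 400, 500, 600, 700, 800, 900, 1000]


@dataclass
class HyperGrid:
    method: str
    axes: dict[str, list]

    def points(self) -> list[dict]:
        names = list(self.axes)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.axes[n] for n in names))
        ]

    def __len__(self) -> int:
        return len(self.points())


def default_grid(method: str) -> HyperGrid:
    """The default hyperparameter grid explored for each learner family."""
    if method == "KNN":
        axes = {"n_neighbors": [1, 3, 5, 7, 9, 11, 13, 15],
                "weights": ["uniform", "distance"]}
    elif method == "SVM":
        axes = {"C": [1e3, 5e3, 1e4, 5e4, 1e5],
                "gamma": [1e-4, 5e-4, 1e-3, 5e-3, 1e-2, 1e-1]}
    elif method == "RF":
        axes = {"n_estimators": list(_TREE_COUNTS)}
    elif method == "GBM":
        axes = {"n_estimators": list(_TREE_COUNTS),
                "learning_rate": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]}
    elif method in ("DNN2", "DNN3"):
        axes = {"epochs": [100, 200, 300, 400, 500, 600],
                "batch_size": [60, 80, 100, 120, 140, 160],
                "alpha": [1e-5, 1e-4, 1e-3, 1e-2, 1e-1]}
    else:
        raise ValueError(f"unknown method {method!r}")
    return HyperGrid(method=method, axes=axes)


def _build_estimator(method: str, params: dict, n_features: int, seed: int):
    if method == "KNN":
        return KNeighborsClassifier(**params)
    if method == "SVM":
        return SVC(kernel="rbf", probability=True, random_state=seed, **params)
    if method == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if method == "GBM":
        return GradientBoostingClassifier(random_state=seed, **params)
    if method in ("DNN2", "DNN3"):
        depth = 2 if method == "DNN2" else 3
        p = dict(params)
        max_iter = p.pop("epochs")
        return MLPClassifier(
            hidden_layer_sizes=(n_features,) * depth,
            activation="relu",
            solver="adam",
            max_iter=max_iter,
            random_state=seed,
            **p,
        )
    raise ValueError(f"unknown method {method!r}")


@dataclass
class TrainedModel:
    method: str
    diameter: int
    k: int
    feature_subset: np.ndarray | None  # None means full features
    params: dict
    estimator: object
    cv_f1: float
    seed: int
    test_f1: float = NA
    test_metrics: dict = field(default_factory=dict)

    @property
    def feature_setting(self) -> str:
        return "full" if self.feature_subset is None else str(len(self.feature_subset))

    def _mask(self, X: np.ndarray) -> np.ndarray:
        if self.feature_subset is None:
            return X
        return X[:, self.feature_subset]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the bitter class for each row of X (full-k space)."""
        if X.shape[1] != self.k:
            raise ValueError(
                f"fingerprint length {X.shape[1]} does not match model k={self.k}"
            )
        proba = self.estimator.predict_proba(self._mask(X))
        cls = list(self.estimator.classes_)
        return proba[:, cls.index(1)]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def _fold_f1(y_true, y_pred) -> float:
    tp, tn, fp, fn = confusion(y_true, y_pred)
    if 2 * tp + fp + fn == 0:
        return NA
    return 2 * tp / (2 * tp + fp + fn)


def grid_search_cv(
    X: np.ndarray,
    y: np.ndarray,
    scheme: SplitScheme,
    method: str,
    grid: HyperGrid | None = None,
    feature_subset: np.ndarray | None = None,
    diameter: int = 4,
    k: int | None = None,
) -> TrainedModel:
    """Select hyperparameters by mean internal-validation F1, refit on CV pool.

    ``X`` is the (n, k) fingerprint matrix over the *whole* dataset; the
    scheme's fold indices address rows of ``X``. Degenerate folds containing
    a single class yield NA F1 and are excluded from the mean with a warning.
    """
    grid = grid or default_grid(method)
    k = k if k is not None else X.shape[1]
    y = np.asarray(y).astype(int)
    subset = None if feature_subset is None else np.asarray(feature_subset, dtype=int)
    n_features = k if subset is None else len(subset)

    def mask(rows):
        Xr = X[rows]
        return Xr if subset is None else Xr[:, subset]

    best_f1, best_params = -1.0, None
    for params in grid.points():
        fold_scores = []
        for i, fold in enumerate(scheme.folds):
            train_rows = np.concatenate(
                [f for j, f in enumerate(scheme.folds) if j != i]
            )
            if len(np.unique(y[fold])) < 2 or len(np.unique(y[train_rows])) < 2:
                warnings.warn(f"fold {i} is single-class; excluded from mean F1")
                continue
            est = _build_estimator(method, params, n_features, scheme.seed)
            est.fit(mask(train_rows), y[train_rows])
            f1 = _fold_f1(y[fold], est.predict(mask(fold)))
            if not is_na(f1):
                fold_scores.append(f1)
        mean_f1 = float(np.mean(fold_scores)) if fold_scores else -1.0
        if mean_f1 > best_f1:  # strict: ties keep the earlier grid point
            best_f1, best_params = mean_f1, params

    est = _build_estimator(method, best_params, n_features, scheme.seed)
    est.fit(mask(scheme.cv_idx), y[scheme.cv_idx])
    return TrainedModel(
        method=method,
        diameter=diameter,
        k=k,
        feature_subset=subset,
        params=best_params,
        estimator=est,
        cv_f1=best_f1,
        seed=scheme.seed,
    )


def evaluate_on_test(model: TrainedModel, X: np.ndarray, y, scheme: SplitScheme):
    """Attach test-set metrics (and test F1) to a trained model."""
    y = np.asarray(y).astype(int)
    pred = model.predict(X[scheme.test_idx])
    report = compute_metrics(*confusion(y[scheme.test_idx], pred))
    model.test_f1 = report.f1
    model.test_metrics = report.as_dict()
    return report


def rf_feature_importance(model: TrainedModel) -> np.ndarray:
    """Per-bit importance from a random-forest model, normalized to sum 1.

    Bits outside the model's feature subset get importance 0.
    """
    if model.method != "RF":
        raise ValueError("feature importance requires an RF model")
    raw = np.asarray(model.estimator.feature_importances_, dtype=float)
    full = np.zeros(model.k)
    if model.feature_subset is None:
        full[:] = raw
    else:
        full[model.feature_subset] = raw
    total = full.sum()
    return full / total if total > 0 else full


def select_top_features(importances: np.ndarray, top_n: int) -> np.ndarray:
    """Indices of the ``top_n`` largest importances, descending; ties broken
    by smaller bit index."""
    importances = np.asarray(importances, dtype=float)
    if top_n > len(importances):
        raise ValueError("top_n exceeds the number of bits")
    order = np.lexsort((np.arange(len(importances)), -importances))
    return order[:top_n]


def predict_proba(model: TrainedModel, fp) -> float:
    """Bitter probability for one fingerprint (Fingerprint or bit vector)."""
    bits = fp.bits if hasattr(fp, "bits") else np.asarray(fp)
    if hasattr(fp, "k") and (fp.k != model.k or fp.diameter != model.diameter):
        raise ValueError("fingerprint setting does not match the model")
    return float(model.predict_proba(bits.astype(float)[None, :])[0])


# ---------------------------------------------------------------------------
# Experiment planner (bookkeeping only; no fitting)
# ---------------------------------------------------------------------------

@dataclass
class ExperimentPlan:
    """Analytic bookkeeping for the full training campaign.

    With the defaults (4 fingerprint settings; 19 splitting schemes for
    KNN/SVM/RF/GBM and 3 for DNN2/DNN3; feature settings full/512/256/128)
    the campaign comprises 328 full-feature models, 984 feature-selected
    models (1,312 total), 96 average models and 76 RF importance runs.
    """

    n_bitter: int = 707
    n_nonbitter: int = 592
    test_fraction: float = 0.2
    n_fingerprints: int = 4
    schemes_fast: int = 19
    schemes_dnn: int = 3
    fast_methods: tuple = ("KNN", "SVM", "RF", "GBM")
    dnn_methods: tuple = ("DNN2", "DNN3")
    feature_subsets: tuple = (512, 256, 128)

    @property
    def test_bitter(self) -> int:
        return int(self.test_fraction * self.n_bitter)

    @property
    def test_nonbitter(self) -> int:
        return int(self.test_fraction * self.n_nonbitter)

    @property
    def cv_bitter(self) -> int:
        return self.n_bitter - self.test_bitter

    @property
    def cv_nonbitter(self) -> int:
        return self.n_nonbitter - self.test_nonbitter

    @property
    def models_per_fingerprint(self) -> int:
        return (self.schemes_fast * len(self.fast_methods)
                + self.schemes_dnn * len(self.dnn_methods))

    @property
    def full_feature_models(self) -> int:
        return self.n_fingerprints * self.models_per_fingerprint

    @property
    def feature_selected_models(self) -> int:
        return self.full_feature_models * len(self.feature_subsets)

    @property
    def total_models(self) -> int:
        return self.full_feature_models + self.feature_selected_models

    @property
    def average_models(self) -> int:
        n_methods = len(self.fast_methods) + len(self.dnn_methods)
        return self.n_fingerprints * n_methods * (1 + len(self.feature_subsets))

    @property
    def rf_importance_runs(self) -> int:
        return self.n_fingerprints * self.schemes_fast

    def summary(self) -> dict[str, int]:
        return {
            "test_bitter": self.test_bitter,
            "test_nonbitter": self.test_nonbitter,
            "cv_bitter": self.cv_bitter,
            "cv_nonbitter": self.cv_nonbitter,
            "full_feature_models": self.full_feature_models,
            "feature_selected_models": self.feature_selected_models,
            "total_models": self.total_models,
            "average_models": self.average_models,
            "rf_importance_runs": self.rf_importance_runs,
        }
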