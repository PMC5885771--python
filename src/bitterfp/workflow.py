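"""End-to-end orchestration: featurization, the training campaign over
fingerprints x methods x schemes x feature settings, and Y-randomization.

Everything here is a thin composition of the library modules; the CLI calls
into these functions. Grids and scheme counts are configurable so the full
campaign (1,312 models) can be scaled down to desk size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_split import (
    DEFAULT_SCHEMES_DNN,
    DEFAULT_SCHEMES_FAST,
    SplitScheme,
    make_scheme,
    y_randomize,
)
from .ensemble import (
    CONSENSUS_IDS,
    AverageModel,
    ConsensusModel,
    build_average_models,
    build_consensus,
)
from .fingerprint import Fingerprint, ecfp, fingerprint_matrix
from .learners import (
    HyperGrid,
    TrainedModel,
    default_grid,
    evaluate_on_test,
    grid_search_cv,
    rf_feature_importance,
    select_top_features,
)
from .metrics import compute_metrics, confusion
from .molecule_io import Molecule

__all__ = ["RunConfig", "ExperimentResult", "featurize", "run_experiment",
           "run_y_randomization", "labels_of"]

DNN_METHODS = ("DNN2", "DNN3")


@dataclass
class RunConfig:
    """Campaign configuration; defaults mirror the full published protocol."""

    fingerprints: list[tuple[int, int]] = field(
        default_factory=lambda: [(4, 1024), (4, 2048), (6, 1024), (6, 2048)]
    )  # (diameter, k)
    methods: list[str] = field(
        default_factory=lambda: ["KNN", "SVM", "RF", "GBM", "DNN2", "DNN3"]
    )
    schemes_fast: int = DEFAULT_SCHEMES_FAST
    schemes_dnn: int = DEFAULT_SCHEMES_DNN
    feature_settings: list = field(default_factory=lambda: ["full", 512, 256, 128])
    base_seed: int = 0
    test_fraction: float = 0.2
    n_folds: int = 5
    consensus_ids: list[str] = field(default_factory=lambda: list(CONSENSUS_IDS))
    #: optional per-method grid-axis overrides for scaled-down runs
    grid_overrides: dict = field(default_factory=dict)

    def grid_for(self, method: str) -> HyperGrid:
        if method in self.grid_overrides:
            return HyperGrid(method=method, axes=self.grid_overrides[method])
        return default_grid(method)

    def schemes_for(self, method: str) -> int:
        return self.schemes_dnn if method in DNN_METHODS else self.schemes_fast


@dataclass
class ExperimentResult:
    config: RunConfig
    labels: np.ndarray
    schemes: list[SplitScheme]
    matrices: dict[tuple[int, int], np.ndarray]  # (diameter, k) -> (n, k)
    fingerprints: dict[tuple[int, int], list[Fingerprint]]
    models: list[TrainedModel]
    averages: list[AverageModel]
    consensus: dict[str, ConsensusModel]
    rf_importances: dict[tuple, np.ndarray]  # (diameter, k, scheme seed)


def labels_of(molecules: list[Molecule]) -> np.ndarray:
    return np.asarray([1 if m.label == "bitter" else 0 for m in molecules])


def featurize(molecules: list[Molecule], diameter: int, k: int):
    fps = [ecfp(m, diameter=diameter, k=k) for m in molecules]
    return fps, fingerprint_matrix(fps)


def run_experiment(molecules: list[Molecule], config: RunConfig) -> ExperimentResult:
    """Run the (possibly scaled) campaign and assemble AM/CM ensembles.

    Feature selection for a given (fingerprint, scheme) uses the importances
    of the full-feature RF trained on that same scheme's CV data, so the
    held-out test set never leaks into the selection.
    """
    y = labels_of(molecules)
    n_schemes = max(config.schemes_for(m) for m in config.methods)
    schemes = [
        make_scheme(y, config.base_seed + i, fraction=config.test_fraction,
                    k=config.n_folds)
        for i in range(n_schemes)
    ]

    fingerprints, matrices = {}, {}
    for diameter, k in config.fingerprints:
        fps, X = featurize(molecules, diameter, k)
        fingerprints[(diameter, k)] = fps
        matrices[(diameter, k)] = X

    models: list[TrainedModel] = []
    rf_imps: dict[tuple, np.ndarray] = {}
    subset_tops = [fs for fs in config.feature_settings if fs != "full"]

    for (diameter, k), X in matrices.items():
        for i, scheme in enumerate(schemes):
            # full-feature models; the RF one also feeds feature selection
            per_scheme_full: dict[str, TrainedModel] = {}
            for method in config.methods:
                if i >= config.schemes_for(method):
                    continue
                if "full" not in config.feature_settings and method != "RF":
                    continue
                model = grid_search_cv(
                    X, y, scheme, method, grid=config.grid_for(method),
                    diameter=diameter, k=k,
                )
                evaluate_on_test(model, X, y, scheme)
                per_scheme_full[method] = model
                if "full" in config.feature_settings:
                    models.append(model)

            if subset_tops:
                rf_source = per_scheme_full.get("RF")
                if rf_source is None:
                    rf_source = grid_search_cv(
                        X, y, scheme, "RF", grid=config.grid_for("RF"),
                        diameter=diameter, k=k,
                    )
                importances = rf_feature_importance(rf_source)
                rf_imps[(diameter, k, scheme.seed)] = importances
                for top_n in subset_tops:
                    subset = select_top_features(importances, int(top_n))
                    for method in config.methods:
                        if i >= config.schemes_for(method):
                            continue
                        model = grid_search_cv(
                            X, y, scheme, method, grid=config.grid_for(method),
                            feature_subset=subset, diameter=diameter, k=k,
                        )
                        evaluate_on_test(model, X, y, scheme)
                        models.append(model)
            elif "RF" in per_scheme_full:
                rf_imps[(diameter, k, scheme.seed)] = rf_feature_importance(
                    per_scheme_full["RF"]
                )

    averages = build_average_models(models)
    consensus = {}
    for cid in config.consensus_ids:
        cm = build_consensus(cid, models, averages)
        if cm.constituents:  # e.g. no DNN-specific CM on a DNN-free run
            consensus[cid] = cm
    return ExperimentResult(
        config=config, labels=y, schemes=schemes, matrices=matrices,
        fingerprints=fingerprints, models=models, averages=averages,
        consensus=consensus, rf_importances=rf_imps,
    )


def run_y_randomization(
    molecules: list[Molecule],
    config: RunConfig,
    n_shuffles: int = 10,
    baseline: ExperimentResult | None = None,
):
    """Retrain under shuffled CV labels and measure the collapse on the
    untouched test set.

    Returns a report dict with per-method baseline test metrics, per-shuffle
    test metrics, and the shuffle confusion against the true CV labels.
    """
    y = labels_of(molecules)
    if baseline is None:
        baseline = run_experiment(molecules, config)
    scheme = baseline.schemes[0]
    diameter, k = config.fingerprints[0]
    X = baseline.matrices[(diameter, k)]

    baseline_metrics = {}
    for method in config.methods:
        best = max(
            (m for m in baseline.models
             if m.method == method and m.seed == scheme.seed),
            key=lambda m: m.test_f1,
        )
        baseline_metrics[method] = dict(best.test_metrics)

    shuffles = []
    for s in range(n_shuffles):
        y_shuf = y.copy()
        shuffled_cv, conf = y_randomize(y[scheme.cv_idx],
                                        seed=config.base_seed + 1000 + s)
        y_shuf[scheme.cv_idx] = shuffled_cv
        per_method = {}
        for method in config.methods:
            model = grid_search_cv(
                X, y_shuf, scheme, method, grid=config.grid_for(method),
                diameter=diameter, k=k,
            )
            pred = model.predict(X[scheme.test_idx])
            report = compute_metrics(*confusion(y[scheme.test_idx], pred))
            per_method[method] = report.as_dict()
        shuffles.append({"confusion_vs_truth": conf, "metrics": per_method})
    return {"baseline": baseline_metrics, "shuffles": shuffles}
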