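"""Average models, the nine named consensus models, and model comparison.

An *average model* (AM) groups the models sharing one (fingerprint setting,
method, feature setting) cell across repeated data-splitting schemes; its
metrics are the per-metric mean and standard deviation over members.

The consensus models:
  CM01 — per-scheme best individual model (one per splitting scheme);
  CM02 — best average model of each method family, with the two neural
         network depths pooled into one family (5 constituents);
  CM03 — top-5 average models overall by test F1;
  CM04–CM09 — top-5 average models within KNN, SVM, GBM, RF, DNN2, DNN3.

A consensus prediction averages the bitter probabilities of every
constituent (descending into average-model members) and thresholds the mean
at 0.5, bitter winning ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .learners import TrainedModel, predict_proba
from .metrics import NA, is_na

__all__ = [
    "AverageModel",
    "ConsensusModel",
    "build_average_models",
    "build_consensus",
    "consensus_predict",
    "ttest_compare",
    "CONSENSUS_IDS",
]

CONSENSUS_IDS = tuple(f"CM{i:02d}" for i in range(1, 10))

_METRIC_KEYS = ("accuracy", "precision", "specificity", "sensitivity", "f1", "mcc")


@dataclass
class AverageModel:
    method: str
    diameter: int
    k: int
    feature_setting: str
    members: list[TrainedModel]
    metric_mean: dict[str, float] = field(default_factory=dict)
    metric_std: dict[str, float] = field(default_factory=dict)

    @property
    def cell(self) -> tuple:
        return (self.diameter, self.k, self.method, self.feature_setting)

    @property
    def test_f1(self) -> float:
        return self.metric_mean.get("f1", NA)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.mean([m.predict_proba(X) for m in self.members], axis=0)


def _summarize(models: list[TrainedModel]):
    mean, std = {}, {}
    for key in _METRIC_KEYS:
        vals = [m.test_metrics.get(key, NA) for m in models]
        vals = [v for v in vals if not is_na(v)]
        mean[key] = float(np.mean(vals)) if vals else NA
        std[key] = float(np.std(vals)) if vals else NA
    return mean, std


def build_average_models(models: list[TrainedModel]) -> list[AverageModel]:
    """One AverageModel per (fingerprint x method x feature setting) cell.

    Cells with unequal member counts within a method family indicate a
    missing scheme and raise.
    """
    cells: dict[tuple, list[TrainedModel]] = {}
    for m in models:
        cells.setdefault((m.diameter, m.k, m.method, m.feature_setting), []).append(m)

    counts_by_method: dict[str, set[int]] = {}
    for (d, k, method, fs), members in cells.items():
        counts_by_method.setdefault(method, set()).add(len(members))
    for method, counts in counts_by_method.items():
        if len(counts) > 1:
            raise ValueError(
                f"incomplete cell for method {method}: member counts {sorted(counts)} "
                "differ across cells (a splitting scheme is missing)"
            )

    averages = []
    for (d, k, method, fs), members in sorted(
        cells.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2], kv[0][3])
    ):
        members = sorted(members, key=lambda m: m.seed)
        mean, std = _summarize(members)
        averages.append(
            AverageModel(
                method=method, diameter=d, k=k, feature_setting=fs,
                members=members, metric_mean=mean, metric_std=std,
            )
        )
    return averages


@dataclass
class ConsensusModel:
    id: str
    constituents: list  # TrainedModel (CM01) or AverageModel (CM02-09)
    metric_mean: dict[str, float] = field(default_factory=dict)
    metric_std: dict[str, float] = field(default_factory=dict)


def _top(averages: list[AverageModel], n: int, methods=None) -> list[AverageModel]:
    pool = [a for a in averages if methods is None or a.method in methods]
    pool = sorted(pool, key=lambda a: (-(a.test_f1 if not is_na(a.test_f1) else -1)))
    return pool[:n]


def build_consensus(
    cid: str,
    models: list[TrainedModel],
    averages: list[AverageModel] | None = None,
    top_n: int = 5,
) -> ConsensusModel:
    """Assemble one named consensus model from the model manifest."""
    if cid not in CONSENSUS_IDS:
        raise ValueError(f"unknown consensus id {cid!r}")
    averages = averages if averages is not None else build_average_models(models)

    if cid == "CM01":
        by_scheme: dict[int, TrainedModel] = {}
        for m in models:
            f1 = m.test_f1 if not is_na(m.test_f1) else -1
            cur = by_scheme.get(m.seed)
            cur_f1 = (cur.test_f1 if (cur and not is_na(cur.test_f1)) else -1)
            if cur is None or f1 > cur_f1:
                by_scheme[m.seed] = m
        constituents = [by_scheme[s] for s in sorted(by_scheme)]
    elif cid == "CM02":
        groups = [("KNN",), ("SVM",), ("GBM",), ("RF",), ("DNN2", "DNN3")]
        constituents = []
        for g in groups:
            best = _top(averages, 1, methods=g)
            if best:
                constituents.append(best[0])
    elif cid == "CM03":
        constituents = _top(averages, top_n)
    else:
        method = {"CM04": "KNN", "CM05": "SVM", "CM06": "GBM",
                  "CM07": "RF", "CM08": "DNN2", "CM09": "DNN3"}[cid]
        constituents = _top(averages, top_n, methods=(method,))

    mean, std = {}, {}
    for key in _METRIC_KEYS:
        vals = []
        for c in constituents:
            v = c.metric_mean.get(key, NA) if isinstance(c, AverageModel) \
                else c.test_metrics.get(key, NA)
            if not is_na(v):
                vals.append(v)
        mean[key] = float(np.mean(vals)) if vals else NA
        std[key] = float(np.std(vals)) if vals else NA
    return ConsensusModel(id=cid, constituents=constituents,
                          metric_mean=mean, metric_std=std)


def consensus_predict(cm: ConsensusModel, X: np.ndarray):
    """(labels, mean probabilities) for rows of the fingerprint matrix X.

    The unweighted mean over constituent probabilities is thresholded at
    0.5; a mean of exactly 0.5 predicts bitter.
    """
    probs = np.mean([c.predict_proba(X) for c in cm.constituents], axis=0)
    return (probs >= 0.5).astype(int), probs


def ttest_compare(f1_a, f1_b, alpha: float = 1e-4):
    """Two-sample Student t-test on per-scheme F1 samples.

    Returns (p_value, significant). Zero variance on both sides with equal
    means gives p = 1 (no evidence of difference).
    """
    a = np.asarray(f1_a, dtype=float)
    b = np.asarray(f1_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two F1 samples per side")
    if np.var(a) == 0 and np.var(b) == 0:
        p = 1.0 if np.mean(a) == np.mean(b) else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    return p, p < alpha
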