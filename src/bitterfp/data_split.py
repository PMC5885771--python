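"""Stratified train/test splitting, 5-fold CV partitioning, and label shuffling.

One repetition of the splitting protocol (a *scheme*) draws a stratified
held-out test set, then partitions the remaining pool into k stratified folds
for cross-validation. The protocol is repeated over several seeds (19 schemes
for the fast learners, 3 for the neural networks by default) to average out
split bias. Y-randomization permutes the CV labels while preserving the
class totals, providing a chance baseline any trustworthy model must beat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SplitScheme",
    "stratified_test_split",
    "kfold",
    "make_scheme",
    "make_schemes",
    "y_randomize",
]

DEFAULT_SCHEMES_FAST = 19  # KNN / SVM / RF / GBM
DEFAULT_SCHEMES_DNN = 3


@dataclass
class SplitScheme:
    seed: int
    test_idx: np.ndarray
    cv_idx: np.ndarray
    folds: list[np.ndarray]  # k disjoint subsets of cv_idx

    def __post_init__(self):
        assert not set(self.test_idx) & set(self.cv_idx)
        pooled = np.concatenate(self.folds)
        assert sorted(pooled) == sorted(self.cv_idx)


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "US" or y.dtype == object:
        y = np.asarray([1 if v in ("bitter", "Y", "1", 1) else 0 for v in y])
    return y.astype(int)


def stratified_test_split(labels, fraction: float = 0.2, seed: int = 0):
    """Draw floor(fraction * class size) test indices per class.

    Returns (cv_idx, test_idx). With 707 positives / 592 negatives at the
    default fraction this yields a 141/118 test set and a 566/474 CV pool.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    y = _as_binary(labels)
    rng = np.random.default_rng(seed)
    test_parts = []
    for cls in (0, 1):
        members = np.flatnonzero(y == cls)
        if members.size == 0:
            raise ValueError(f"class {cls} has no members")
        n_test = int(np.floor(fraction * members.size))
        test_parts.append(rng.choice(members, size=n_test, replace=False))
    test_idx = np.sort(np.concatenate(test_parts))
    cv_idx = np.setdiff1d(np.arange(len(y)), test_idx)
    return cv_idx, test_idx


def kfold(cv_idx, labels, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Stratified k-way partition of ``cv_idx`` with balanced fold totals.

    Each class is split as evenly as possible; per-class remainders are
    assigned to the folds with the smallest running totals, so overall fold
    sizes also differ by at most one (e.g. 566+474 compounds -> five folds
    of exactly 208).
    """
    cv_idx = np.asarray(cv_idx)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(cv_idx) < k:
        raise ValueError("fewer samples than folds")
    y = _as_binary(labels)[cv_idx]
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    class_order = sorted((0, 1), key=lambda c: -(y == c).sum())
    for cls in class_order:
        members = cv_idx[y == cls]
        members = rng.permutation(members)
        base, rem = divmod(len(members), k)
        sizes = [base] * k
        # remainder goes to the currently smallest folds (ties: lower index)
        order = sorted(range(k), key=lambda f: (len(folds[f]), f))
        for f in order[:rem]:
            sizes[f] += 1
        pos = 0
        for f in range(k):
            folds[f].extend(members[pos:pos + sizes[f]].tolist())
            pos += sizes[f]
    return [np.sort(np.asarray(f)) for f in folds]


def make_scheme(labels, seed: int, fraction: float = 0.2, k: int = 5) -> SplitScheme:
    cv_idx, test_idx = stratified_test_split(labels, fraction, seed)
    folds = kfold(cv_idx, labels, k=k, seed=seed)
    return SplitScheme(seed=seed, test_idx=test_idx, cv_idx=cv_idx, folds=folds)


def make_schemes(labels, n_schemes: int, base_seed: int = 0, **kw) -> list[SplitScheme]:
    """Repeated splitting schemes; scheme i uses seed ``base_seed + i``."""
    return [make_scheme(labels, base_seed + i, **kw) for i in range(n_schemes)]


def y_randomize(labels, seed: int = 0):
    """Uniformly permute a binary label vector, preserving class totals.

    Returns (shuffled labels, (TP, TN, FP, FN)) where the confusion counts
    compare shuffled against true labels (positive class = 1).
    """
    y = _as_binary(labels)
    rng = np.random.default_rng(seed)
    shuffled = y[rng.permutation(len(y))]
    tp = int(((shuffled == 1) & (y == 1)).sum())
    tn = int(((shuffled == 0) & (y == 0)).sum())
    fp = int(((shuffled == 1) & (y == 0)).sum())
    fn = int(((shuffled == 0) & (y == 1)).sum())
    return shuffled, (tp, tn, fp, fn)
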