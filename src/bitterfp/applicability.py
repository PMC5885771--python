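"""Applicability-domain scoring by mean Tanimoto similarity to the five
nearest training compounds.

A query whose average similarity to its five nearest CV-pool neighbors
exceeds 0.1 (strictly) is considered inside the domain: its prediction
interpolates the training chemistry. The neighbor count matches the optimal
K of the best full-feature KNN model; the 2048-bit diameter-6 fingerprint is
the default reference setting (most features, fewest collisions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fingerprint import Fingerprint, tanimoto

__all__ = ["DomainReport", "average_similarity", "in_domain", "DOMAIN_THRESHOLD"]

DOMAIN_THRESHOLD = 0.1


@dataclass
class DomainReport:
    query_id: str
    neighbor_ids: list[int]  # reference indices, most similar first
    neighbor_similarities: list[float]  # sorted descending
    average_similarity: float
    in_domain: bool


def average_similarity(
    query: Fingerprint,
    reference: list[Fingerprint],
    n: int = 5,
    exclude: int | None = None,
    query_id: str = "",
    threshold: float = DOMAIN_THRESHOLD,
) -> DomainReport:
    """Top-n Tanimoto neighbors of ``query`` in ``reference`` and their mean.

    ``exclude`` removes one reference index (self-exclusion when the query
    belongs to the reference set). Similarity ties at the n-th rank resolve
    to the lower reference index.
    """
    candidates = [i for i in range(len(reference)) if i != exclude]
    if len(candidates) < n:
        raise ValueError(f"reference set smaller than n={n}")
    sims = [(tanimoto(query, reference[i]), i) for i in candidates]
    sims.sort(key=lambda t: (-t[0], t[1]))
    top = sims[:n]
    avg = float(np.mean([s for s, _ in top]))
    return DomainReport(
        query_id=query_id,
        neighbor_ids=[i for _, i in top],
        neighbor_similarities=[s for s, _ in top],
        average_similarity=avg,
        in_domain=in_domain(avg, threshold),
    )


def in_domain(avg: float, threshold: float = DOMAIN_THRESHOLD) -> bool:
    """Strictly above the threshold counts as inside the domain."""
    return avg > threshold
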