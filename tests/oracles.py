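"""Independent brute-force oracles used to validate the fast implementations.

These deliberately recompute everything from first principles each step —
no Lance-Williams updates, no closed forms — so that agreement with the
package's implementations is a genuine dual-route check.
"""

from itertools import combinations

import numpy as np

__all__ = [
    "brute_force_agglomerate",
    "brute_force_ward_points",
    "monte_carlo_rarefy",
    "naive_silhouette",
]


def _set_distance(D: np.ndarray, A: frozenset, B: frozenset, linkage: str) -> float:
    pairs = [D[i, j] for i in A for j in B]
    if linkage == "single":
        return min(pairs)
    if linkage == "complete":
        return max(pairs)
    if linkage == "average":
        return float(np.mean(pairs))
    raise ValueError(linkage)


def brute_force_agglomerate(D: np.ndarray, linkage: str) -> list[float]:
    """Merge heights from a from-scratch agglomerator.

    Every step rescans all cluster pairs and recomputes the inter-cluster
    distance directly from the original leaf distances (min / max / mean of
    all cross pairs).
    """
    clusters = [frozenset([i]) for i in range(len(D))]
    heights = []
    while len(clusters) > 1:
        best = None
        for A, B in combinations(sorted(clusters, key=sorted), 2):
            d = _set_distance(D, A, B, linkage)
            if best is None or d < best[0]:
                best = (d, A, B)
        d, A, B = best
        heights.append(d)
        clusters.remove(A)
        clusters.remove(B)
        clusters.append(A | B)
    return heights


def brute_force_ward_points(points: np.ndarray) -> list[float]:
    """Merge heights for Ward clustering of Euclidean points, computed from
    cluster centroids (height = sqrt(2 * nA*nB/(nA+nB) * ||cA - cB||^2))."""
    clusters = [frozenset([i]) for i in range(len(points))]
    heights = []

    def ward_d(A, B):
        ca = points[list(A)].mean(axis=0)
        cb = points[list(B)].mean(axis=0)
        na, nb = len(A), len(B)
        return float(np.sqrt(2.0 * na * nb / (na + nb) * np.sum((ca - cb) ** 2)))

    while len(clusters) > 1:
        best = None
        for A, B in combinations(sorted(clusters, key=sorted), 2):
            d = ward_d(A, B)
            if best is None or d < best[0]:
                best = (d, A, B)
        d, A, B = best
        heights.append(d)
        clusters.remove(A)
        clusters.remove(B)
        clusters.append(A | B)
    return heights


def monte_carlo_rarefy(
    counts: np.ndarray, n: int, n_resamples: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Mean and standard error of subsample richness over random resamples."""
    labels = np.repeat(np.arange(len(counts)), counts)
    total = len(labels)
    # vectorized sampling without replacement via random-key argsort
    keys = rng.random((n_resamples, total))
    picks = np.argsort(keys, axis=1)[:, :n]
    richness = np.array(
        [len(np.unique(labels[row])) for row in picks], dtype=float
    )
    return float(richness.mean()), float(richness.std(ddof=1) / np.sqrt(n_resamples))


def naive_silhouette(labels: np.ndarray, D: np.ndarray) -> float:
    """Per-point silhouette recomputation, singletons scoring zero."""
    scores = []
    for i in range(len(labels)):
        same = [j for j in range(len(labels)) if labels[j] == labels[i] and j != i]
        if not same:
            scores.append(0.0)
            continue
        a = np.mean([D[i, j] for j in same])
        b = min(
            np.mean([D[i, j] for j in range(len(labels)) if labels[j] == k])
            for k in set(labels)
            if k != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))
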