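"""Jaccard distances, agglomerative clustering and the two-stage scheme.

Grid cells are compared by the Jaccard dissimilarity of their species sets
and clustered agglomeratively (average linkage by default, the conventional
partner of ecological incidence data).  The agglomerator is implemented
directly via the Lance–Williams update with a deterministic tie-break —
among all minimal-distance pairs the lexicographically smallest pair of
cluster ids is merged — so that dendrograms are reproducible across
platforms.  A primary cut at a caller-chosen K yields clusters whose pooled
species lists feed a secondary clustering; cutting that tree at a fixed
dissimilarity (0.935 by default) produces the final groupings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ContractViolation
from .grid import IncidenceMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "ClusterPartition",
    "ClusterPool",
    "jaccard_distance",
    "jaccard_sets",
    "agglomerate",
    "cut_k",
    "cut_height",
    "wss",
    "silhouette",
    "select_k",
    "pool_clusters",
    "secondary_grouping",
]

LINKAGES = ("average", "complete", "single", "ward")


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix over an ordered item list."""

    items: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.items)
        if self.values.shape != (n, n):
            raise ContractViolation("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ContractViolation("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ContractViolation("distance matrix diagonal must be zero")

    def __len__(self) -> int:
        return len(self.items)


def jaccard_distance(incidence: IncidenceMatrix) -> DistanceMatrix:
    """Pairwise Jaccard dissimilarity between cell species sets.

    ``d = 1 - |A & B| / |A | B|``; exact on binary incidence rows.
    """
    data = incidence.data.to_numpy(dtype=bool)
    if data.shape[0] < 2:
        raise ContractViolation("need at least two cells")
    if np.any(data.sum(axis=1) == 0):
        raise ContractViolation("empty incidence rows; filter cells first")
    condensed = pdist(data, metric="jaccard")
    return DistanceMatrix(list(incidence.data.index), squareform(condensed))


def jaccard_sets(a: set, b: set) -> float:
    """Jaccard dissimilarity between two plain sets."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return 1.0 - len(a & b) / union


@dataclass
class Dendrogram:
    """Agglomerative merge tree.

    ``merges`` has one row per merge: (left id, right id, height, size),
    where ids < n refer to leaves and id ``n + i`` to the cluster created by
    merge ``i`` (the scipy linkage-matrix convention).
    """

    merges: np.ndarray
    labels: list

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def is_monotone(self) -> bool:
        return bool(np.all(np.diff(self.heights) >= -1e-12))

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf ordering of the tree."""
        n = self.n_leaves
        if n == 1:
            return [0]

        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for i, (a, b, _, _) in enumerate(self.merges):
            members[n + i] = members[int(a)] + members[int(b)]
        return members[n + len(self.merges) - 1]

    def to_newick(self) -> str:
        """Newick string with merge heights as node depths (branch lengths
        are height differences; leaves sit at depth 0)."""
        n = self.n_leaves
        if n == 1:
            return f"{self.labels[0]};"
        text = {i: str(self.labels[i]).replace(" ", "_") for i in range(n)}
        height = {i: 0.0 for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            left = f"{text[a]}:{h - height[a]:g}"
            right = f"{text[b]}:{h - height[b]:g}"
            text[n + i] = f"({left},{right})"
            height[n + i] = float(h)
        return text[n + len(self.merges) - 1] + ";"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["left", "right", "height", "size"]
        )


@dataclass
class ClusterPartition:
    """Assignment of items to clusters labeled 1..K (labels by leaf order)."""

    labels: dict  # item -> int
    K: int
    diagnostics: dict = field(default_factory=dict)

    def label_array(self, items) -> np.ndarray:
        return np.array([self.labels[it] for it in items])

    def members(self, k: int) -> list:
        return [it for it, lab in self.labels.items() if lab == k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"item": str(it), "cluster": lab} for it, lab in self.labels.items()]
        )


def _lw_update(linkage: str, d_ik, d_jk, d_ij, ni, nj, nk):
    if linkage == "single":
        return min(d_ik, d_jk)
    if linkage == "complete":
        return max(d_ik, d_jk)
    if linkage == "average":
        return (ni * d_ik + nj * d_jk) / (ni + nj)
    if linkage == "ward":
        t = ni + nj + nk
        val = ((ni + nk) * d_ik**2 + (nj + nk) * d_jk**2 - nk * d_ij**2) / t
        return float(np.sqrt(max(val, 0.0)))
    raise ValueError(f"unknown linkage: {linkage!r}")


def agglomerate(dist: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative hierarchical clustering via Lance–Williams updates.

    Ties in the minimal inter-cluster distance are broken by merging the
    lexicographically smallest (id, id) pair.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    n = len(dist)
    # current distances keyed by unordered id pairs
    d: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(dist.values[i, j])
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                val = d[(i, j)]
                if best is None or val < best[0] - 1e-15 or (
                    abs(val - best[0]) <= 1e-15 and (i, j) < best[1:]
                ):
                    best = (val, i, j)
        height, i, j = best
        new = n + step
        for k in sorted(active - {i, j}):
            d_ik = d[tuple(sorted((i, k)))]
            d_jk = d[tuple(sorted((j, k)))]
            d[(k, new)] = _lw_update(
                linkage, d_ik, d_jk, height, size[i], size[j], size[k]
            )
        size[new] = size[i] + size[j]
        active -= {i, j}
        active.add(new)
        merges[step] = (i, j, height, size[new])
    return Dendrogram(merges, list(dist.items))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


def _partition_from_merges(dend: Dendrogram, n_merges: int) -> ClusterPartition:
    n = dend.n_leaves
    uf = _UnionFind(n + len(dend.merges))
    for i in range(n_merges):
        a, b, _, _ = dend.merges[i]
        uf.union(int(a), n + i)
        uf.union(int(b), n + i)
    # label clusters 1..K in left-to-right leaf order
    labels: dict = {}
    rep_to_label: dict[int, int] = {}
    next_label = 1
    for leaf in dend.leaf_order():
        rep = uf.find(leaf)
        if rep not in rep_to_label:
            rep_to_label[rep] = next_label
            next_label += 1
        labels[dend.labels[leaf]] = rep_to_label[rep]
    return ClusterPartition(labels, K=next_label - 1)


def cut_k(dend: Dendrogram, K: int) -> ClusterPartition:
    """Partition into K clusters by removing the K-1 highest merges."""
    n = dend.n_leaves
    if not 1 <= K <= n:
        raise ValueError(f"K={K} outside [1, {n}]")
    return _partition_from_merges(dend, n - K)


def cut_height(dend: Dendrogram, dissimilarity: float) -> ClusterPartition:
    """Partition by removing merges with height strictly above the cut."""
    n_merges = int(np.sum(dend.heights <= dissimilarity + 1e-12))
    return _partition_from_merges(dend, n_merges)


def wss(partition: ClusterPartition, incidence: IncidenceMatrix) -> float:
    """Total within-cluster sum of squared distances to cluster centroids,
    computed in incidence-vector space."""
    data = incidence.data.to_numpy(dtype=float)
    items = list(incidence.data.index)
    labels = partition.label_array(items)
    total = 0.0
    for k in np.unique(labels):
        rows = data[labels == k]
        centroid = rows.mean(axis=0)
        total += float(np.sum((rows - centroid) ** 2))
    return total


def silhouette(partition: ClusterPartition, dist: DistanceMatrix) -> float:
    """Average silhouette width; singleton clusters contribute s = 0."""
    if partition.K < 2:
        raise ValueError("silhouette requires K >= 2")
    labels = partition.label_array(dist.items)
    values = dist.values
    n = len(labels)
    scores = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            scores[i] = 0.0
            continue
        a = values[i, own].sum() / (n_own - 1)
        b = np.inf
        for k in np.unique(labels):
            if k == labels[i]:
                continue
            other = labels == k
            b = min(b, values[i, other].mean())
        scores[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(scores.mean())


def select_k(
    dend: Dendrogram,
    dist: DistanceMatrix,
    incidence: IncidenceMatrix,
    k_range,
) -> pd.DataFrame:
    """Diagnostics table (K, WSS, silhouette) over tree cuts.

    Flags the elbow (maximal second difference of WSS) and local silhouette
    maxima; the choice of K stays with the caller.
    """
    ks = sorted(int(k) for k in k_range)
    rows = []
    for k in ks:
        part = cut_k(dend, k)
        rows.append(
            {
                "K": k,
                "wss": wss(part, incidence),
                "silhouette": silhouette(part, dist) if k >= 2 else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    table["is_elbow"] = False
    if len(table) >= 3:
        second_diff = np.diff(table["wss"].to_numpy(), 2)
        table.loc[int(np.argmax(second_diff)) + 1, "is_elbow"] = True
    sil = table["silhouette"].to_numpy()
    peaks = np.zeros(len(table), dtype=bool)
    for i in range(len(table)):
        left = sil[i - 1] if i > 0 else -np.inf
        right = sil[i + 1] if i < len(table) - 1 else -np.inf
        peaks[i] = np.isfinite(sil[i]) and sil[i] >= left and sil[i] >= right
    table["silhouette_peak"] = peaks
    return table


@dataclass
class ClusterPool:
    """A primary cluster with its member cells and pooled species list."""

    cluster_id: int
    cells: list
    species: set

    @property
    def n_species(self) -> int:
        return len(self.species)


def pool_clusters(
    partition: ClusterPartition, incidence: IncidenceMatrix
) -> list[ClusterPool]:
    """Union the member-cell species sets of each cluster, ordered by label."""
    pools = []
    for k in range(1, partition.K + 1):
        cells = [it for it in incidence.data.index if partition.labels[it] == k]
        species: set = set()
        for cell in cells:
            species |= incidence.species_set(cell)
        pools.append(ClusterPool(k, cells, species))
    return pools


def secondary_grouping(
    pools: list[ClusterPool],
    linkage: str = "average",
    cut_dissimilarity: float = 0.935,
) -> tuple[dict, Dendrogram]:
    """Cluster the cluster pools themselves and cut at a fixed dissimilarity.

    Returns ``(cluster_id -> grouping letter, dendrogram)``; groupings are
    lettered A, B, C, ... in leaf order.
    """
    if len(pools) < 2:
        raise ContractViolation("secondary grouping needs at least two pools")
    n = len(pools)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = jaccard_sets(
                pools[i].species, pools[j].species
            )
    dist = DistanceMatrix([p.cluster_id for p in pools], values)
    dend = agglomerate(dist, linkage)
    part = cut_height(dend, cut_dissimilarity)

    # numeric labels are already in leaf order; render them as letters
    def letter(index: int) -> str:
        out = ""
        index -= 1
        while True:
            out = chr(ord("A") + index % 26) + out
            index = index // 26 - 1
            if index < 0:
                return out

    grouping = {cid: letter(lab) for cid, lab in part.labels.items()}
    return grouping, dend
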