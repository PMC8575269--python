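"""Bipartite cluster-species network, force-directed layout and consensus.

The network view complements the dendrogram: clusters and species are nodes,
an edge links a cluster to every species in its pool, and a ForceAtlas2-style
layout (linear attraction, degree-weighted repulsion, central gravity,
adaptive speed with a jitter tolerance) makes the grouping structure visible.
The layout is a relational tool, not a pixel-faithful reproduction of any GUI
program: only determinism and relative proximities are contracted.

For a quantitative verification of the cluster groupings, the bipartite
network is projected onto a weighted cluster-cluster graph (shared-species
Jaccard similarity) whose greedy-modularity communities are compared with the
secondary-grouping labels via the adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cluster import ClusterPool
from .errors import ContractViolation

__all__ = [
    "LayoutParams",
    "ConsensusReport",
    "build_bipartite",
    "layout_force",
    "project_clusters",
    "consensus_communities",
]


@dataclass(frozen=True)
class LayoutParams:
    """Force-directed layout parameters (ForceAtlas2 vocabulary)."""

    scaling: float = 10.0
    gravity: float = 1.0
    edge_weight_influence: float = 1.0
    tolerance: float = 0.1
    approximation: float = 1.2  # Barnes-Hut theta
    max_iter: int = 300
    seed: int = 0
    barnes_hut_threshold: int = 1500

    def __post_init__(self) -> None:
        if self.scaling <= 0:
            raise ValueError("scaling must be positive")
        if self.approximation < 0:
            raise ValueError("approximation (theta) must be >= 0")


def build_bipartite(pools: list[ClusterPool]) -> nx.Graph:
    """Bipartite graph of clusters and their pooled species.

    Cluster nodes are ``("cluster", id)`` with a ``species_count`` attribute;
    species nodes are ``("species", name)``; each cluster-species edge has
    weight 1.  Node insertion order is deterministic.
    """
    if not pools:
        raise ContractViolation("no pools supplied")
    graph = nx.Graph()
    for pool in pools:
        graph.add_node(("cluster", pool.cluster_id), kind="cluster",
                       species_count=pool.n_species)
    species = sorted({sp for pool in pools for sp in pool.species})
    for sp in species:
        graph.add_node(("species", sp), kind="species")
    for pool in pools:
        for sp in sorted(pool.species):
            graph.add_edge(("cluster", pool.cluster_id), ("species", sp),
                           weight=1.0)
    for sp in species:
        graph.nodes[("species", sp)]["cluster_degree"] = graph.degree(
            ("species", sp)
        )
    return graph


# ---------------------------------------------------------------------------
# layout


class _QuadTree:
    """Barnes-Hut quadtree over 2-D points with masses."""

    __slots__ = ("cx", "cy", "half", "mass", "mx", "my", "children", "point")

    def __init__(self, cx, cy, half):
        self.cx, self.cy, self.half = cx, cy, half
        self.mass = 0.0
        self.mx = 0.0
        self.my = 0.0
        self.children = None
        self.point = None  # (x, y, mass)

    def insert(self, x, y, m, depth=0):
        if self.mass == 0.0 and self.point is None and self.children is None:
            self.point = (x, y, m)
            self.mass = m
            self.mx, self.my = x, y
            return
        if self.children is None:
            if self.half < 1e-9:  # coincident points: merge into one leaf mass
                x0, y0, m0 = self.point
                total = m0 + m
                self.point = ((x0 * m0 + x * m) / total,
                              (y0 * m0 + y * m) / total, total)
                self.mass = total
                self.mx, self.my = self.point[0], self.point[1]
                return
            self._split()
        total = self.mass + m
        self.mx = (self.mx * self.mass + x * m) / total
        self.my = (self.my * self.mass + y * m) / total
        self.mass = total
        self._child_for(x, y).insert(x, y, m, depth + 1)

    def _split(self):
        h = self.half / 2.0
        self.children = [
            _QuadTree(self.cx - h, self.cy - h, h),
            _QuadTree(self.cx + h, self.cy - h, h),
            _QuadTree(self.cx - h, self.cy + h, h),
            _QuadTree(self.cx + h, self.cy + h, h),
        ]
        x, y, m = self.point
        self.point = None
        self.mass -= m
        if self.mass <= 0:
            self.mass, self.mx, self.my = 0.0, 0.0, 0.0
        self._child_for(x, y).insert(x, y, m)
        if self.mass == 0.0:  # re-seed aggregates after moving the old point
            self.mass = m
            self.mx, self.my = x, y

    def _child_for(self, x, y):
        index = (1 if x >= self.cx else 0) + (2 if y >= self.cy else 0)
        return self.children[index]

    def force_on(self, x, y, m, theta, out):
        if self.mass == 0.0:
            return
        dx = x - self.mx
        dy = y - self.my
        dist2 = dx * dx + dy * dy
        if self.children is None or (4.0 * self.half * self.half) < theta**2 * dist2:
            if dist2 < 1e-12:
                return
            f = m * self.mass / dist2
            out[0] += f * dx
            out[1] += f * dy
            return
        for child in self.children:
            child.force_on(x, y, m, theta, out)


def _repulsion_exact(pos: np.ndarray, mass: np.ndarray) -> np.ndarray:
    diff = pos[:, None, :] - pos[None, :, :]
    dist2 = np.sum(diff**2, axis=-1)
    np.fill_diagonal(dist2, np.inf)
    coef = (mass[:, None] * mass[None, :]) / dist2
    return np.sum(coef[:, :, None] * diff, axis=1)


def _repulsion_bh(pos: np.ndarray, mass: np.ndarray, theta: float) -> np.ndarray:
    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    center = (lo + hi) / 2.0
    half = float(max(hi - lo) / 2.0 + 1e-9)
    tree = _QuadTree(center[0], center[1], half)
    for (x, y), m in zip(pos, mass):
        tree.insert(float(x), float(y), float(m))
    out = np.zeros_like(pos)
    for i, ((x, y), m) in enumerate(zip(pos, mass)):
        acc = [0.0, 0.0]
        tree.force_on(float(x), float(y), float(m), theta, acc)
        # remove self-interaction contributed by the node's own leaf
        out[i] = acc
    return out


def layout_force(
    graph: nx.Graph, params: LayoutParams | None = None
) -> tuple[dict, np.ndarray]:
    """ForceAtlas2-style force-directed layout.

    Linear attraction along edges (scaled by weight**edge_weight_influence),
    degree-weighted repulsion scaled by ``scaling``, central gravity, and the
    adaptive global speed scheme driven by node swinging; iteration stops when
    the mean displacement drops below ``tolerance``.  Exact pairwise repulsion
    is used up to ``barnes_hut_threshold`` nodes, a Barnes-Hut quadtree at
    theta = ``approximation`` beyond that.  Deterministic given the seed.

    Returns ``(positions, trace)`` where positions maps node -> (x, y) and
    trace records the mean displacement per iteration.
    """
    params = params or LayoutParams()
    nodes = list(graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ContractViolation("empty network")
    index = {node: i for i, node in enumerate(nodes)}
    degree = np.array([graph.degree(node) for node in nodes], dtype=float)
    mass = degree + 1.0
    rng = np.random.default_rng(params.seed)
    if n == 1:
        return {nodes[0]: (0.0, 0.0)}, np.zeros(0)
    pos = rng.uniform(-1.0, 1.0, size=(n, 2)) * np.sqrt(n)

    edges = np.array(
        [[index[u], index[v]] for u, v in graph.edges], dtype=int
    )
    weights = np.array(
        [graph.edges[u, v].get("weight", 1.0) for u, v in graph.edges]
    )
    w_att = weights**params.edge_weight_influence

    prev_force = np.zeros_like(pos)
    speed = 1.0
    trace = []
    for _ in range(params.max_iter):
        if n > params.barnes_hut_threshold:
            rep = _repulsion_bh(pos, mass, params.approximation)
        else:
            rep = _repulsion_exact(pos, mass)
        force = params.scaling * rep
        if len(edges):
            delta = pos[edges[:, 0]] - pos[edges[:, 1]]
            pull = w_att[:, None] * delta
            np.add.at(force, edges[:, 0], -pull)
            np.add.at(force, edges[:, 1], pull)
        dist_origin = np.linalg.norm(pos, axis=1) + 1e-9
        force -= params.gravity * mass[:, None] * pos / dist_origin[:, None]

        swing = np.linalg.norm(force - prev_force, axis=1)
        traction = 0.5 * np.linalg.norm(force + prev_force, axis=1)
        global_swing = float(np.sum(mass * swing)) + 1e-9
        global_traction = float(np.sum(mass * traction)) + 1e-9
        target_speed = params.tolerance * global_traction / global_swing
        speed = min(target_speed, 1.5 * speed, 10.0)
        node_speed = speed / (1.0 + speed * np.sqrt(swing))
        magnitude = np.linalg.norm(force, axis=1) + 1e-9
        step = np.minimum(node_speed * magnitude, 10.0)
        disp = force / magnitude[:, None] * step[:, None]
        pos = pos + disp
        prev_force = force
        mean_disp = float(np.mean(np.linalg.norm(disp, axis=1)))
        trace.append(mean_disp)
        if mean_disp < params.tolerance:
            break
    positions = {node: (float(x), float(y)) for node, (x, y) in zip(nodes, pos)}
    return positions, np.asarray(trace)


# ---------------------------------------------------------------------------
# consensus


@dataclass
class ConsensusReport:
    """Agreement between network communities and the cluster groupings."""

    projected: nx.Graph
    communities: dict  # cluster id -> community index
    reference: dict  # cluster id -> grouping label
    ari: float | None
    equivocal: list = field(default_factory=list)
    modularity: float | None = None

    @property
    def defined(self) -> bool:
        return self.ari is not None


def project_clusters(
    pools: list[ClusterPool], min_weight: float = 0.05
) -> nx.Graph:
    """Weighted cluster-cluster graph; weights are shared-species Jaccard
    similarities.

    Edges below ``min_weight`` are dropped: trace amounts of sharing (a
    handful of widespread species) otherwise let the resolution limit of
    modularity maximization absorb weakly connected single-cluster units
    into unrelated communities.
    """
    graph = nx.Graph()
    for pool in pools:
        graph.add_node(pool.cluster_id, species_count=pool.n_species)
    for i, a in enumerate(pools):
        for b in pools[i + 1:]:
            union = len(a.species | b.species)
            inter = len(a.species & b.species)
            if union and inter / union >= min_weight:
                graph.add_edge(a.cluster_id, b.cluster_id,
                               weight=inter / union)
    return graph


def consensus_communities(
    pools: list[ClusterPool], reference_grouping: dict,
    min_weight: float = 0.05,
) -> ConsensusReport:
    """Detect communities on the projected graph and compare with groupings.

    Communities come from greedy modularity maximization (deterministic for a
    fixed graph); agreement is the adjusted Rand index against the secondary
    grouping.  A single cluster node yields an undefined (flagged) report.
    """
    projected = project_clusters(pools, min_weight)
    ids = sorted(projected.nodes)
    if len(ids) < 2:
        return ConsensusReport(projected, {ids[0]: 0} if ids else {},
                               dict(reference_grouping), None)
    if projected.number_of_edges() == 0:
        comms = [{node} for node in ids]
    else:
        comms = nx.algorithms.community.greedy_modularity_communities(
            projected, weight="weight"
        )
    communities: dict = {}
    for ci, members in enumerate(sorted(comms, key=lambda c: min(c))):
        for node in members:
            communities[node] = ci
    if projected.number_of_edges() == 0:
        modularity = None
    else:
        modularity = nx.algorithms.community.modularity(
            projected, comms, weight="weight"
        )
    ref_labels = [reference_grouping[i] for i in ids]
    com_labels = [communities[i] for i in ids]
    ari = float(adjusted_rand_score(ref_labels, com_labels))

    equivocal = []
    for node in ids:
        nbrs = projected[node]
        if not nbrs:
            continue
        strongest = max(nbrs, key=lambda m: (nbrs[m]["weight"], -m))
        if reference_grouping[strongest] != reference_grouping[node]:
            equivocal.append(node)
    return ConsensusReport(projected, communities, dict(reference_grouping),
                           ari, equivocal, modularity)


def network_to_frames(graph: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables (for CSV export) of a bipartite network."""
    nodes = pd.DataFrame(
        [
            {
                "kind": kind,
                "id": str(name),
                "species_count": graph.nodes[(kind, name)].get("species_count", ""),
                "cluster_degree": graph.nodes[(kind, name)].get("cluster_degree", ""),
            }
            for kind, name in graph.nodes
        ]
    )
    edges = pd.DataFrame(
        [
            {"cluster": str(u[1]), "species": str(v[1]),
             "weight": graph.edges[u, v].get("weight", 1.0)}
            for u, v in graph.edges
        ]
    )
    return nodes, edges
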