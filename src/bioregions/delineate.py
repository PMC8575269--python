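"""Bioregion / bioprovince delineation and biogeographical indices.

Groupings from the secondary clustering become bioregions; primary clusters
become bioprovinces, except that small clusters (fewer than ``min_cells``
cells) are emitted as independent provinces, mirroring remote oceanic-island
units.  Three criteria are enforced or reported: units must not nest (cell
and province memberships are partitions), units should be geographically
contiguous under queen adjacency (edge- or corner-sharing cells, wrapping
across the antimeridian), and the grouping structure should be supported by
the network consensus.

Scattered cells are repaired by :func:`reassign_outliers`: each cell detached
from its cluster's main body is re-attached to the neighbouring province with
the most similar species pool.  Per-unit indices follow the standard
arithmetic: species richness S, genus richness G, the species/genus ratio S/G
(a diversification-rate proxy, half-up to 2 decimals) and endemism 100*E/S
(half-up to 1 decimal), with E the number of species found in no cell outside
the unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ContractViolation
from .grid import GridSpec, IncidenceMatrix

__all__ = [
    "ProvinceIndices",
    "BioScheme",
    "build_adjacency",
    "contiguity_score",
    "check_nesting",
    "reassign_outliers",
    "compute_indices",
    "indices_from_counts",
    "build_scheme",
]


def _round_half_up(value: Decimal, places: str) -> float:
    return float(value.quantize(Decimal(places), rounding=ROUND_HALF_UP))


def indices_from_counts(S: int, G: int, E: int) -> tuple[float, float]:
    """Species/genus ratio (2 dp) and endemism percentage (1 dp), half-up."""
    if S <= 0 or G <= 0:
        raise ValueError("S and G must be positive")
    if E > S:
        raise ValueError("endemic count cannot exceed richness")
    ratio = _round_half_up(Decimal(S) / Decimal(G), "0.01")
    endemism = _round_half_up(Decimal(100 * E) / Decimal(S), "0.1")
    return ratio, endemism


@dataclass
class ProvinceIndices:
    """Per-unit biodiversity indices."""

    S: int
    G: int
    E: int
    ratio: float
    endemism_pct: float

    @classmethod
    def from_counts(cls, S: int, G: int, E: int) -> "ProvinceIndices":
        ratio, endemism = indices_from_counts(S, G, E)
        return cls(S, G, E, ratio, endemism)


@dataclass
class BioScheme:
    """Hierarchical bioregion -> bioprovince structure."""

    bioregions: dict  # region label -> list of province labels
    bioprovinces: dict  # province label -> {"clusters": [...], "cells": [...]}
    independent: list = field(default_factory=list)  # province labels

    def all_units(self) -> dict:
        return dict(self.bioprovinces)

    def province_of_cell(self) -> dict:
        out = {}
        for label, info in self.bioprovinces.items():
            for cell in info["cells"]:
                out.setdefault(cell, []).append(label)
        return out

    def to_json(self) -> str:
        payload = {
            "bioregions": {
                region: {
                    prov: {
                        "clusters": sorted(self.bioprovinces[prov]["clusters"]),
                        "cells": sorted(map(list, self.bioprovinces[prov]["cells"])),
                    }
                    for prov in provinces
                }
                for region, provinces in sorted(self.bioregions.items())
            },
            "independent_provinces": sorted(self.independent),
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def build_adjacency(cells, grid: GridSpec | None = None) -> nx.Graph:
    """Queen adjacency over grid cells, wrapping columns across the
    antimeridian (rows do not wrap over the poles)."""
    grid = grid or GridSpec()
    cellset = set(cells)
    graph = nx.Graph()
    graph.add_nodes_from(cellset)
    for row, col in cellset:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nb = (row + dr, (col + dc) % grid.n_cols)
                if nb in cellset:
                    graph.add_edge((row, col), nb)
    return graph


def contiguity_score(cells, adjacency: nx.Graph) -> float:
    """Fraction of a unit's cells inside its largest connected component."""
    cells = list(cells)
    if not cells:
        raise ValueError("empty cell set")
    sub = adjacency.subgraph(cells)
    largest = max(nx.connected_components(sub), key=len)
    return len(largest) / len(cells)


def check_nesting(scheme: BioScheme) -> tuple[bool, list]:
    """True iff cells and provinces form partitions (no unit nested/shared)."""
    violations = []
    for cell, provs in scheme.province_of_cell().items():
        if len(provs) > 1:
            violations.append(("cell", cell, provs))
    seen: dict = {}
    for region, provinces in scheme.bioregions.items():
        for prov in provinces:
            if prov in seen:
                violations.append(("province", prov, [seen[prov], region]))
            seen[prov] = region
    return len(violations) == 0, violations


def _centroid(cells) -> tuple[float, float]:
    grid = GridSpec()
    pts = np.array([grid.cell_center(r, c) for r, c in cells])
    return float(pts[:, 0].mean()), float(pts[:, 1].mean())


def _great_circle(a: tuple[float, float], b: tuple[float, float]) -> float:
    lat1, lon1, lat2, lon2 = map(np.radians, (a[0], a[1], b[0], b[1]))
    h = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2 * np.arcsin(np.sqrt(np.clip(h, 0, 1))))


def reassign_outliers(
    cell_labels: dict,
    incidence: IncidenceMatrix,
    adjacency: nx.Graph | None = None,
    min_cells: int = 2,
    overrides: dict | None = None,
    max_rounds: int = 10,
) -> tuple[dict, list]:
    """Re-attach geographically detached cells to compatible neighbours.

    Iteratively, every cell outside its cluster's largest connected component
    is reassigned to the adjacent cluster whose pooled species list is most
    similar to the cell's own species set (Jaccard); ties go to the cluster
    with the nearer centroid (great-circle).  Cells with no adjacent cluster
    keep their label; after the loop, any remaining detached component is
    split off as a new unit so that every emitted unit is contiguous.
    A manual-override mapping (cell -> label) takes precedence and is applied
    first.  Every move is logged ``(cell, from, to, rationale)``.
    """
    labels = dict(cell_labels)
    audit: list[tuple] = []
    if overrides:
        for cell, target in overrides.items():
            if cell in labels and labels[cell] != target:
                audit.append((cell, labels[cell], target, "manual override"))
                labels[cell] = target
    if adjacency is None:
        adjacency = build_adjacency(list(labels), incidence.grid)

    def pool_of(lab) -> set:
        out: set = set()
        for cell, l in labels.items():
            if l == lab:
                out |= incidence.species_set(cell)
        return out

    def centroid_of(lab):
        return _centroid([c for c, l in labels.items() if l == lab])

    def reattach(cell, lab, why) -> bool:
        neighbours = {
            labels[nb]
            for nb in adjacency.neighbors(cell)
            if labels.get(nb) not in (None, lab)
        }
        if not neighbours:
            return False
        cell_species = incidence.species_set(cell)
        best = None
        for cand in sorted(neighbours, key=str):
            pool = pool_of(cand)
            union = len(cell_species | pool)
            sim = len(cell_species & pool) / union if union else 0.0
            dist = _great_circle(_centroid([cell]), centroid_of(cand))
            key = (-sim, dist, str(cand))
            if best is None or key < best[0]:
                best = (key, cand, sim, dist)
        _, cand, sim, dist = best
        audit.append(
            (cell, lab, cand,
             f"{why}; similarity={sim:.3f}, centroid_dist={dist:.3f}")
        )
        labels[cell] = cand
        return True

    for _ in range(max_rounds):
        moved = False
        for lab in sorted(set(labels.values()), key=str):
            cells = [c for c, l in labels.items() if l == lab]
            sub = adjacency.subgraph(cells)
            comps = sorted(nx.connected_components(sub), key=len, reverse=True)
            # detached fragments outside the cluster's main body
            for comp in comps[1:]:
                for cell in sorted(comp):
                    moved |= reattach(cell, lab, "detached")
            # undersized clusters with neighbours are dissolved cell by cell
            # (remote ones keep their label and become independent provinces)
            if len(cells) < min_cells:
                for cell in sorted(cells):
                    if labels[cell] == lab:
                        moved |= reattach(cell, lab, "undersized cluster")
        if not moved:
            break

    # residual detached components become units of their own
    existing = set(labels.values())
    fresh = 0
    for lab in sorted(existing, key=str):
        cells = [c for c, l in labels.items() if l == lab]
        sub = adjacency.subgraph(cells)
        comps = sorted(nx.connected_components(sub), key=lambda c: (-len(c), sorted(c)))
        for comp in comps[1:]:
            fresh += 1
            new_lab = _fresh_label(existing, fresh)
            existing.add(new_lab)
            for cell in sorted(comp):
                audit.append((cell, lab, new_lab, "residual detached component split off"))
                labels[cell] = new_lab
    return labels, audit


def _fresh_label(existing, k: int):
    numeric = [l for l in existing if isinstance(l, (int, np.integer))]
    if numeric and len(numeric) == len(existing):
        return max(numeric) + k
    base = max(
        (int(str(l).split("+")[-1]) for l in existing if str(l).split("+")[-1].isdigit()),
        default=0,
    )
    return f"split+{base + k}"


def compute_indices(
    cells,
    species_incidence: IncidenceMatrix,
    genus_incidence: IncidenceMatrix,
) -> ProvinceIndices:
    """Per-unit S, G, E and derived indices.

    S and G are unions over member cells; E counts species occurring in no
    cell outside the unit (dataset-wide denominator set).  Genus-level
    (sp/spp) records contribute to G only.
    """
    cells = [c for c in cells if c in set(species_incidence.data.index)]
    if not cells:
        raise ValueError("empty province (no cells in the incidence matrix)")
    sp_data = species_incidence.data
    inside = sp_data.loc[list(cells)]
    species = inside.columns[(inside.sum(axis=0) > 0)]
    outside_cells = [c for c in sp_data.index if c not in set(cells)]
    if outside_cells:
        outside = sp_data.loc[outside_cells, species].sum(axis=0)
        endemics = int((outside == 0).sum())
    else:
        endemics = int(len(species))
    gen_cells = [c for c in cells if c in set(genus_incidence.data.index)]
    gen_inside = genus_incidence.data.loc[gen_cells]
    genera = int((gen_inside.sum(axis=0) > 0).sum()) if gen_cells else 0
    return ProvinceIndices.from_counts(int(len(species)), genera, endemics)


def build_scheme(
    grouping: dict,
    cell_labels: dict,
    species_incidence: IncidenceMatrix,
    genus_incidence: IncidenceMatrix,
    adjacency: nx.Graph | None = None,
    min_cells: int = 2,
    overrides: dict | None = None,
) -> tuple[BioScheme, pd.DataFrame, dict]:
    """Assemble the bioregion -> bioprovince scheme and its criteria report.

    ``grouping`` maps primary-cluster ids to grouping letters (bioregions);
    ``cell_labels`` maps cells to primary-cluster ids (bioprovinces).
    Clusters with fewer than ``min_cells`` cells become independent
    provinces.  Returns the scheme, a per-unit index table and a report of
    the three delineation criteria (nesting, contiguity, network support is
    filled in by the caller).
    """
    cluster_cells: dict = {}
    for cell, lab in cell_labels.items():
        cluster_cells.setdefault(lab, []).append(cell)
    missing = [c for c in species_incidence.data.index if c not in cell_labels]
    if missing:
        raise ContractViolation(f"cells missing from partition: {missing[:5]}")
    if adjacency is None:
        adjacency = build_adjacency(list(cell_labels), species_incidence.grid)

    region_of: dict = {}
    for cid, cells in cluster_cells.items():
        region_of[cid] = grouping.get(cid)

    bioregions: dict = {}
    bioprovinces: dict = {}
    independent: list = []
    counters: dict = {}
    for cid in sorted(cluster_cells, key=str):
        cells = sorted(cluster_cells[cid])
        region = region_of[cid]
        if len(cells) < min_cells or region is None:
            label = f"I-{cid}"
            independent.append(label)
            bioprovinces[label] = {"clusters": [cid], "cells": cells}
            continue
        counters[region] = counters.get(region, 0) + 1
        label = f"{region}{counters[region]}"
        bioregions.setdefault(region, []).append(label)
        bioprovinces[label] = {"clusters": [cid], "cells": cells}
    scheme = BioScheme(bioregions, bioprovinces, independent)

    if overrides:
        _merge_overrides(scheme, overrides)

    rows = []
    for label in sorted(scheme.bioprovinces, key=str):
        info = scheme.bioprovinces[label]
        idx = compute_indices(info["cells"], species_incidence, genus_incidence)
        lat = [species_incidence.grid.cell_bounds(*c) for c in info["cells"]]
        rows.append(
            {
                "unit": label,
                "n_cells": len(info["cells"]),
                "S": idx.S,
                "G": idx.G,
                "ratio": idx.ratio,
                "E": idx.E,
                "endemism_pct": idx.endemism_pct,
                "lat_min": min(b[0] for b in lat),
                "lat_max": max(b[1] for b in lat),
                "contiguity": contiguity_score(info["cells"], adjacency),
            }
        )
    indices = pd.DataFrame(rows)
    nested_ok, violations = check_nesting(scheme)
    report = {
        "nesting_ok": nested_ok,
        "nesting_violations": violations,
        "min_contiguity": float(indices["contiguity"].min()) if len(indices) else None,
        "all_contiguous": bool((indices["contiguity"] == 1.0).all()) if len(indices) else None,
        "n_bioregions": len(scheme.bioregions),
        "n_bioprovinces": sum(len(v) for v in scheme.bioregions.values()),
        "n_independent": len(scheme.independent),
    }
    return scheme, indices, report


def _merge_overrides(scheme: BioScheme, overrides: dict) -> None:
    """Merge bioprovinces per an override mapping {target: [members...]}."""
    for target, members in overrides.items():
        merged_cells: list = []
        merged_clusters: list = []
        for member in members:
            info = scheme.bioprovinces.pop(member, None)
            if info is None:
                continue
            merged_cells.extend(info["cells"])
            merged_clusters.extend(info["clusters"])
            for region, provs in scheme.bioregions.items():
                if member in provs:
                    provs.remove(member)
            if member in scheme.independent:
                scheme.independent.remove(member)
        if merged_cells:
            scheme.bioprovinces[target] = {
                "clusters": sorted(merged_clusters, key=str),
                "cells": sorted(merged_cells),
            }
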