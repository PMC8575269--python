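"""Scheme assembly, contiguity, outlier reassignment and indices."""

import numpy as np
import pandas as pd
import pytest

from bioregions.delineate import (BioScheme, build_adjacency, build_scheme,
                                  check_nesting, compute_indices,
                                  contiguity_score, indices_from_counts,
                                  reassign_outliers)
from bioregions.grid import GridSpec, IncidenceMatrix


def test_indices_from_counts_reference_values():
    assert indices_from_counts(117, 50, 88) == (2.34, 75.2)
    assert indices_from_counts(126, 52, 82) == (2.42, 65.1)
    assert indices_from_counts(10, 10, 10) == (1.0, 100.0)


def test_indices_validate_inputs():
    with pytest.raises(ValueError):
        indices_from_counts(5, 0, 1)
    with pytest.raises(ValueError):
        indices_from_counts(5, 3, 6)


def _incidence(assignments, all_species=None):
    """assignments: {cell: set(species)} -> species-level incidence."""
    species = sorted(all_species or {s for v in assignments.values() for s in v})
    data = pd.DataFrame(
        [[1 if s in assignments[c] else 0 for s in species] for c in assignments],
        index=list(assignments), columns=species,
    )
    return IncidenceMatrix(data, "species")


def test_compute_indices_endemics_dataset_wide():
    inc = _incidence({
        (5, 5): {"Ga a", "Gb b"},
        (5, 6): {"Ga a", "Gc c"},
        (20, 40): {"Gc c", "Gd d"},
    })
    genus = IncidenceMatrix(
        pd.DataFrame(
            [[1, 1, 0, 0], [1, 0, 1, 0], [0, 0, 1, 1]],
            index=[(5, 5), (5, 6), (20, 40)], columns=["Ga", "Gb", "Gc", "Gd"],
        ), "genus",
    )
    idx = compute_indices([(5, 5), (5, 6)], inc, genus)
    assert (idx.S, idx.G) == (3, 3)
    assert idx.E == 2  # "Gc c" also occurs at (20, 40)
    assert idx.ratio == 1.0 and idx.endemism_pct == 66.7


def test_contiguity_queen_and_gaps():
    adjacency = build_adjacency([(5, 5), (6, 6), (8, 8)])
    assert contiguity_score([(5, 5)], adjacency) == 1.0
    assert contiguity_score([(5, 5), (6, 6)], adjacency) == 1.0  # diagonal
    assert contiguity_score([(5, 5), (8, 8)], adjacency) == 0.5


def test_adjacency_wraps_antimeridian():
    grid = GridSpec()
    adjacency = build_adjacency([(10, 0), (10, grid.n_cols - 1)], grid)
    assert adjacency.has_edge((10, 0), (10, grid.n_cols - 1))


def test_check_nesting():
    ok = BioScheme({"A": ["A1"]}, {"A1": {"clusters": [1], "cells": [(0, 0)]}})
    assert check_nesting(ok) == (True, [])
    bad = BioScheme(
        {"A": ["A1"], "B": ["B1"]},
        {"A1": {"clusters": [1], "cells": [(0, 0)]},
         "B1": {"clusters": [2], "cells": [(0, 0)]}},
    )
    good, violations = check_nesting(bad)
    assert not good
    assert violations[0][1] == (0, 0)


def test_reassign_moves_detached_cell_to_similar_neighbour():
    # province 1: cells around (10, 10); province 2: cells around (20, 40);
    # one cell of province 1 sits detached beside province 2 and shares its
    # species -> must move to province 2
    cells1 = [(10, 10), (10, 11)]
    cells2 = [(20, 40), (20, 41)]
    stray = (20, 42)
    sp1 = {"a", "b", "c"}
    sp2 = {"x", "y", "z"}
    inc = _incidence({**{c: sp1 for c in cells1}, **{c: sp2 for c in cells2},
                      stray: {"x", "y"}})
    labels = {**{c: 1 for c in cells1}, **{c: 2 for c in cells2}, stray: 1}
    new, audit = reassign_outliers(labels, inc)
    assert new[stray] == 2
    assert any(a[0] == stray for a in audit)
    adjacency = build_adjacency(list(new))
    for lab in set(new.values()):
        assert contiguity_score([c for c, l in new.items() if l == lab],
                                adjacency) == 1.0


def test_reassign_tie_broken_by_centroid_distance():
    # stray cell equally similar to two provinces; province 2's centroid is
    # nearer -> assigned to 2 and logged
    cells1 = [(10, 10), (10, 11), (10, 12), (11, 10), (11, 11), (11, 12)]
    cells2 = [(10, 16), (10, 17)]
    stray = (10, 14)  # adjacent to neither? make it adjacent to both fronts
    cells1 = [(10, 10), (10, 11), (10, 12), (10, 13)]
    cells2 = [(10, 15), (10, 16)]
    sp = {"s1", "s2"}
    inc = _incidence({**{c: sp for c in cells1}, **{c: sp for c in cells2},
                      stray: sp, (30, 60): {"q"}})
    labels = {**{c: 1 for c in cells1}, **{c: 2 for c in cells2},
              stray: 3, (30, 60): 3}
    new, audit = reassign_outliers(labels, inc)
    assert new[stray] == 2  # same similarity, nearer centroid
    entry = [a for a in audit if a[0] == stray][0]
    assert "similarity" in entry[3]


def test_disjunct_cells_return_to_geographic_province():
    # an antitropical species links one northern and one southern cell into
    # a single scattered cluster; each cell must be realigned with its
    # geographic neighbourhood instead
    north = [(30, 10), (30, 11), (31, 10), (31, 11)]
    south = [(5, 10), (5, 11), (6, 10), (6, 11)]
    sp_n = {f"n{i}" for i in range(6)}
    sp_s = {f"s{i}" for i in range(6)}
    disjunct = {"anti1"}
    cells = {}
    for c in north:
        cells[c] = sp_n | (disjunct if c == (30, 10) else set())
    for c in south:
        cells[c] = sp_s | (disjunct if c == (5, 10) else set())
    inc = _incidence(cells)
    labels = {c: 1 for c in north if c != (30, 10)}
    labels.update({c: 2 for c in south if c != (5, 10)})
    labels[(30, 10)] = 3
    labels[(5, 10)] = 3
    new, _ = reassign_outliers(labels, inc)
    assert new[(30, 10)] == 1
    assert new[(5, 10)] == 2


def test_build_scheme_single_cluster():
    inc = _incidence({(5, 5): {"a", "b"}, (5, 6): {"a", "c"}})
    genus = IncidenceMatrix(
        pd.DataFrame([[1], [1]], index=[(5, 5), (5, 6)], columns=["G"]), "genus"
    )
    scheme, indices, report = build_scheme(
        {1: "A"}, {(5, 5): 1, (5, 6): 1}, inc, genus
    )
    assert report["n_bioregions"] == 1 and report["n_bioprovinces"] == 1
    assert report["nesting_ok"]


def test_remote_small_cluster_becomes_independent_province():
    inc = _incidence({
        (5, 5): {"a", "b"}, (5, 6): {"a", "b"},
        (30, 60): {"z", "w"},  # far-away lone cell
    })
    genus = IncidenceMatrix(
        pd.DataFrame([[1], [1], [1]], index=[(5, 5), (5, 6), (30, 60)],
                     columns=["G"]), "genus",
    )
    labels = {(5, 5): 1, (5, 6): 1, (30, 60): 2}
    new, _ = reassign_outliers(labels, inc, min_cells=2)
    assert new[(30, 60)] == 2  # remote: nothing to attach to
    scheme, indices, report = build_scheme({1: "A", 2: "B"}, new, inc, genus,
                                           min_cells=2)
    assert scheme.independent == ["I-2"]
    assert report["n_independent"] == 1


def test_endemic_sum_bounded_by_total_species(small_results):
    total_species = small_results.filtered_incidence.data.shape[1]
    assert small_results.indices["E"].sum() <= total_species


def test_scheme_conserves_cells(small_results):
    n_cells = sum(
        len(info["cells"]) for info in small_results.scheme.bioprovinces.values()
    )
    assert n_cells == len(small_results.filtered_incidence.data)


def test_indices_match_brute_force_sets(small_results):
    inc = small_results.filtered_incidence
    gen = small_results.genus_incidence
    for _, row in small_results.indices.iterrows():
        info = small_results.scheme.bioprovinces[row["unit"]]
        species = set()
        for cell in info["cells"]:
            species |= inc.species_set(cell)
        outside = set()
        for cell in inc.data.index:
            if cell not in set(info["cells"]):
                outside |= inc.species_set(cell)
        assert row["S"] == len(species)
        assert row["E"] == len(species - outside)
        genera = set()
        for cell in info["cells"]:
            if cell in set(gen.data.index):
                genera |= gen.species_set(cell)
        assert row["G"] == len(genera)
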