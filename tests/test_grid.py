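"""Grid assignment, labels, incidence matrices and cell filtering."""

import numpy as np
import pandas as pd
import pytest

from bioregions.errors import ConfigurationError, ContractViolation
from bioregions.grid import (GridSpec, build_incidence, cell_richness,
                             filter_cells, grid_geojson, latitudinal_richness)


@pytest.fixture(scope="module")
def grid() -> GridSpec:
    return GridSpec()


def test_known_cell_label(grid):
    row, col = grid.assign(32.0, 133.0)
    assert grid.label(row, col) == "35°N130°E-30°N135°E"


def test_origin_boundary_cell(grid):
    row, col = grid.assign(0.0, 0.0)
    assert grid.cell_bounds(row, col) == (0.0, 5.0, 0.0, 5.0)
    assert grid.label(row, col) == "5°N0°E-0°N5°E"


def test_antimeridian_and_southern_cell(grid):
    row, col = grid.assign(-2.5, -177.5)
    assert grid.cell_bounds(row, col) == (-5.0, 0.0, -180.0, -175.0)


def test_north_pole_folds_into_top_row(grid):
    row, _ = grid.assign(90.0, 10.0)
    assert row == grid.n_rows - 1


def test_longitude_180_wraps(grid):
    assert grid.assign(10.0, 180.0) == grid.assign(10.0, -180.0)


def test_out_of_range_latitude_is_contract_violation(grid):
    with pytest.raises(ContractViolation):
        grid.assign(95.0, 0.0)


def test_label_roundtrip_for_every_cell(grid):
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            assert grid.parse_label(grid.label(row, col)) == (row, col)


def test_cell_size_must_divide_spans():
    with pytest.raises(ConfigurationError):
        GridSpec(cell_size=7.0)


def _records(rows):
    base = {"qualifier": "none", "count": 1}
    return pd.DataFrame([{**base, **r} for r in rows])


def test_single_record_single_cell_matrix():
    inc = build_incidence(
        _records([{"genus": "Lingula", "species_epithet": "anatina",
                   "latitude": 10.0, "longitude": 110.0}])
    )
    assert inc.data.shape == (1, 1)
    assert inc.data.iloc[0, 0] == 1


def test_genus_level_records_counted_only_at_genus_level():
    rows = _records([{"genus": "Lingula", "species_epithet": "",
                      "qualifier": "sp", "latitude": 10.0, "longitude": 110.0}])
    assert build_incidence(rows, level="species").data.empty
    genus = build_incidence(rows, level="genus")
    assert genus.data.shape == (1, 1)


def test_partition_property_occurrences_conserved(small_world):
    records, _ = small_world
    inc = build_incidence(records)
    assert int(inc.occurrence_counts.sum()) == len(records)


def test_incidence_matches_truth_occupancy(noiseless_config):
    from bioregions.synthetic import generate_world

    records, truth = generate_world(noiseless_config)
    inc = build_incidence(records)
    for cell in inc.cells:
        observed = inc.species_set(cell)
        expected = {sp for (c, sp) in truth.occupancy if c == cell}
        assert observed == expected


def test_cell_richness_row_sums():
    rows = _records(
        [
            {"genus": "A", "species_epithet": "a", "latitude": 1.0, "longitude": 1.0},
            {"genus": "B", "species_epithet": "b", "latitude": 1.0, "longitude": 1.0},
            {"genus": "A", "species_epithet": "a", "latitude": 11.0, "longitude": 1.0},
        ]
    )
    inc = build_incidence(rows)
    richness = cell_richness(inc)
    assert sorted(richness.to_list()) == [1, 2]


def test_latitudinal_bins():
    rows = _records(
        [
            {"genus": "A", "species_epithet": "a", "latitude": 2.0, "longitude": 1.0},
            {"genus": "B", "species_epithet": "b", "latitude": 3.0, "longitude": 40.0},
            {"genus": "C", "species_epithet": "c", "latitude": -33.0, "longitude": 1.0},
        ]
    )
    bins = latitudinal_richness(rows, bin_width=5.0)
    assert bins.loc[0.0] == 2
    assert bins.loc[-35.0] == 1


def test_filter_cells_threshold_is_inclusive(rng):
    taxa = [f"t{i}" for i in range(9)]
    cells = [(5, 5), (6, 6), (7, 7)]
    data = pd.DataFrame(0, index=cells, columns=taxa)
    data.loc[[(5, 5)], taxa[:7]] = 1   # exactly 7 -> survives
    data.loc[[(6, 6)], taxa[:6]] = 1   # 6 -> removed
    data.loc[[(7, 7)], taxa] = 1       # 9 -> survives
    from bioregions.grid import IncidenceMatrix

    inc = IncidenceMatrix(data, "species")
    kept = filter_cells(inc, 7)
    assert list(kept.data.index) == [(5, 5), (7, 7)]
    # columns with no surviving cell are pruned
    assert all(kept.data[c].sum() > 0 for c in kept.data.columns)


def test_filter_cells_matches_rowsum_scan_and_is_idempotent(rng):
    from bioregions.grid import IncidenceMatrix

    data = pd.DataFrame(
        rng.integers(0, 2, size=(50, 30)),
        index=[(i // 10, i % 10) for i in range(50)],
        columns=[f"s{j}" for j in range(30)],
    )
    inc = IncidenceMatrix(data, "species")
    kept = filter_cells(inc, 7)
    expected_rows = [ix for ix in data.index if data.loc[[ix]].to_numpy().sum() >= 7]
    assert list(kept.data.index) == expected_rows
    again = filter_cells(kept, 7)
    pd.testing.assert_frame_equal(kept.data, again.data)


def test_filter_cells_bad_threshold():
    inc = build_incidence(_records([
        {"genus": "A", "species_epithet": "a", "latitude": 1.0, "longitude": 1.0}
    ]))
    with pytest.raises(ConfigurationError):
        filter_cells(inc, 0)


def test_geojson_export_has_one_feature_per_cell(small_world):
    records, _ = small_world
    inc = build_incidence(records)
    geo = grid_geojson(inc)
    assert geo["type"] == "FeatureCollection"
    assert len(geo["features"]) == len(inc.data)
    feat = geo["features"][0]
    assert feat["geometry"]["type"] == "Polygon"
    assert feat["properties"]["richness"] >= 1
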