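"""Distance, agglomeration, tree cuts, K diagnostics, two-stage grouping."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from sklearn.metrics import adjusted_rand_score, silhouette_score

from bioregions.cluster import (ClusterPool, DistanceMatrix, agglomerate,
                                cut_height, cut_k, jaccard_distance,
                                jaccard_sets, pool_clusters,
                                secondary_grouping, select_k, silhouette, wss)
from bioregions.errors import ContractViolation
from bioregions.grid import IncidenceMatrix
from oracles import brute_force_agglomerate, naive_silhouette


def _incidence(rows, cells=None):
    data = pd.DataFrame(
        rows, index=cells or [(0, i) for i in range(len(rows))]
    ).astype(int)
    data.columns = [f"s{j}" for j in range(data.shape[1])]
    return IncidenceMatrix(data, "species")


def test_jaccard_known_values():
    inc = _incidence([
        [1, 1, 1, 0],  # {a,b,c}
        [0, 1, 1, 1],  # {b,c,d}
        [1, 1, 1, 0],  # identical to row 0
    ])
    dist = jaccard_distance(inc)
    assert dist.values[0, 1] == pytest.approx(0.5)
    assert dist.values[0, 2] == 0.0
    disjoint = jaccard_distance(_incidence([[1, 0], [0, 1]]))
    assert disjoint.values[0, 1] == 1.0


def test_jaccard_rejects_empty_rows():
    with pytest.raises(ContractViolation):
        jaccard_distance(_incidence([[1, 0], [0, 0]]))


def test_two_item_dendrogram():
    dist = DistanceMatrix(["a", "b"], np.array([[0.0, 0.3], [0.3, 0.0]]))
    dend = agglomerate(dist)
    assert dend.merges.shape == (1, 4)
    assert dend.heights[0] == pytest.approx(0.3)


def test_three_item_average_linkage_by_hand():
    values = np.array([
        [0.0, 0.1, 0.9],
        [0.1, 0.0, 0.9],
        [0.9, 0.9, 0.0],
    ])
    dend = agglomerate(DistanceMatrix([0, 1, 2], values), "average")
    assert list(dend.heights) == pytest.approx([0.1, 0.9])
    assert set(map(int, dend.merges[0, :2])) == {0, 1}


@pytest.mark.parametrize("link", ["average", "complete", "single"])
def test_matches_brute_force_oracle_sample(link, rng):
    for _ in range(20):
        n = int(rng.integers(3, 7))
        raw = rng.random((n, n))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 0.0)
        dend = agglomerate(DistanceMatrix(list(range(n)), values), link)
        oracle = brute_force_agglomerate(values, link)
        assert np.allclose(sorted(dend.heights), sorted(oracle), atol=1e-10)


@pytest.mark.parametrize("link", ["average", "complete", "single", "ward"])
def test_matches_scipy_linkage_heights(link, rng):
    n = 8
    points = rng.random((n, 4))
    from scipy.spatial.distance import pdist, squareform

    condensed = pdist(points)
    dend = agglomerate(DistanceMatrix(list(range(n)), squareform(condensed)), link)
    Z = scipy_linkage(condensed, method=link)
    assert np.allclose(sorted(dend.heights), sorted(Z[:, 2]), atol=1e-9)


def test_deterministic_tie_break_smallest_pair_first():
    # three items all at distance 0.5: merge (0, 1) first
    values = np.full((3, 3), 0.5)
    np.fill_diagonal(values, 0.0)
    dend = agglomerate(DistanceMatrix([0, 1, 2], values), "average")
    assert set(map(int, dend.merges[0, :2])) == {0, 1}


def test_average_linkage_monotone(rng):
    for _ in range(10):
        n = 9
        raw = rng.random((n, n))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 0.0)
        dend = agglomerate(DistanceMatrix(list(range(n)), values), "average")
        assert dend.is_monotone()


def test_cut_k_extremes_and_planted_blocks(rng):
    # planted 3-block structure
    blocks = [0, 0, 0, 1, 1, 1, 2, 2, 2]
    n = len(blocks)
    values = np.where(
        np.equal.outer(blocks, blocks), rng.uniform(0.0, 0.2, (n, n)),
        rng.uniform(0.8, 1.0, (n, n))
    )
    values = (values + values.T) / 2
    np.fill_diagonal(values, 0.0)
    dist = DistanceMatrix(list(range(n)), values)
    dend = agglomerate(dist)
    assert cut_k(dend, 1).K == 1
    assert cut_k(dend, n).K == n
    part = cut_k(dend, 3)
    labels = part.label_array(list(range(n)))
    assert adjusted_rand_score(blocks, labels) == 1.0


def test_cut_k_out_of_range():
    dist = DistanceMatrix(["a", "b"], np.array([[0.0, 0.3], [0.3, 0.0]]))
    dend = agglomerate(dist)
    with pytest.raises(ValueError):
        cut_k(dend, 3)


def test_cut_height_conventions(rng):
    n = 6
    raw = rng.random((n, n))
    values = (raw + raw.T) / 2
    np.fill_diagonal(values, 0.0)
    dend = agglomerate(DistanceMatrix(list(range(n)), values))
    assert cut_height(dend, float(dend.heights.max())).K == 1
    assert cut_height(dend, float(dend.heights.min()) - 1e-6).K == n


def test_cut_height_pool_example():
    values = np.array([
        [0.0, 0.90, 0.95],
        [0.90, 0.0, 0.95],
        [0.95, 0.95, 0.0],
    ])
    dend = agglomerate(DistanceMatrix(["p1", "p2", "p3"], values))
    assert cut_height(dend, 0.935).K == 2


def test_wss_hand_computed():
    inc = _incidence([
        [1, 1, 0, 0],
        [1, 0, 0, 0],
        [0, 0, 1, 1],
        [0, 0, 1, 0],
    ])
    from bioregions.cluster import ClusterPartition

    part = ClusterPartition(
        {(0, 0): 1, (0, 1): 1, (0, 2): 2, (0, 3): 2}, K=2
    )
    # each pair differs in one coordinate: per-cluster WSS = 2 * (0.5^2) = 0.5
    assert wss(part, inc) == pytest.approx(1.0)
    all_rows_identical = _incidence([[1, 0], [1, 0], [1, 0]])
    part0 = ClusterPartition({(0, 0): 1, (0, 1): 1, (0, 2): 1}, K=1)
    assert wss(part0, all_rows_identical) == 0.0


def test_silhouette_two_tight_pairs():
    values = np.full((4, 4), 0.9)
    values[0, 1] = values[1, 0] = 0.1
    values[2, 3] = values[3, 2] = 0.1
    np.fill_diagonal(values, 0.0)
    dist = DistanceMatrix(list(range(4)), values)
    from bioregions.cluster import ClusterPartition

    part = ClusterPartition({0: 1, 1: 1, 2: 2, 3: 2}, K=2)
    assert silhouette(part, dist) == pytest.approx(8.0 / 9.0)


def test_silhouette_equidistant_is_zero():
    values = np.full((4, 4), 0.5)
    np.fill_diagonal(values, 0.0)
    from bioregions.cluster import ClusterPartition

    part = ClusterPartition({0: 1, 1: 1, 2: 2, 3: 2}, K=2)
    assert silhouette(part, DistanceMatrix(list(range(4)), values)) == pytest.approx(0.0)


def test_silhouette_matches_oracles(rng):
    n = 12
    raw = rng.random((n, n))
    values = (raw + raw.T) / 2
    np.fill_diagonal(values, 0.0)
    labels = np.array([1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3, 3])
    from bioregions.cluster import ClusterPartition

    part = ClusterPartition(dict(enumerate(labels)), K=3)
    dist = DistanceMatrix(list(range(n)), values)
    ours = silhouette(part, dist)
    assert ours == pytest.approx(naive_silhouette(labels, values), abs=1e-12)
    assert ours == pytest.approx(
        silhouette_score(values, labels, metric="precomputed"), abs=1e-9
    )


def test_select_k_table_and_elbow(rng):
    blocks = [0] * 4 + [1] * 4 + [2] * 4
    n = len(blocks)
    points = rng.normal(size=(n, 6)) * 0.05 + np.array(blocks)[:, None] * 3.0
    data = (points > points.mean()).astype(int)
    # build a planted-block incidence directly
    rows = np.zeros((n, 9), dtype=int)
    for i, b in enumerate(blocks):
        rows[i, 3 * b:3 * b + 3] = 1
        rows[i, (3 * b + int(rng.integers(3))) % 9] = 1
    inc = _incidence(rows.tolist())
    dist = jaccard_distance(inc)
    dend = agglomerate(dist)
    table = select_k(dend, dist, inc, range(2, 6))
    assert len(table) == 4
    assert np.all(np.diff(table["wss"]) <= 1e-9)  # WSS nonincreasing in K
    best = table.loc[table["silhouette"].idxmax(), "K"]
    assert best == 3


def test_pool_clusters_unions(small_results):
    pools = pool_clusters(small_results.partition, small_results.filtered_incidence)
    for pool in pools:
        union = set()
        for cell in pool.cells:
            union |= small_results.filtered_incidence.species_set(cell)
        assert pool.species == union
    covered = {c for p in pools for c in p.cells}
    assert covered == set(small_results.filtered_incidence.data.index)


def test_secondary_grouping_disjoint_pools_stay_separate():
    pools = [
        ClusterPool(1, [(0, 0)], {"a", "b"}),
        ClusterPool(2, [(0, 1)], {"c", "d"}),
        ClusterPool(3, [(0, 2)], {"e", "f"}),
    ]
    grouping, _ = secondary_grouping(pools)
    assert len(set(grouping.values())) == 3


def test_secondary_grouping_half_shared_pools_merge():
    pools = [
        ClusterPool(1, [(0, 0)], {"a", "b", "c", "d"}),
        ClusterPool(2, [(0, 1)], {"c", "d", "e", "f"}),
    ]
    assert jaccard_sets(pools[0].species, pools[1].species) == pytest.approx(2 / 3)
    grouping, _ = secondary_grouping(pools)
    assert grouping[1] == grouping[2] == "A"


def test_two_stage_recovers_planted_regions(small_results):
    truth = small_results.truth
    grouping = small_results.grouping
    labels = small_results.partition.labels
    cells = list(labels)
    planted = [truth.cell_provinces[c] for c in cells]
    recovered = [grouping[labels[c]] for c in cells]
    assert adjusted_rand_score(planted, recovered) == 1.0
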