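# Methods

This note records the models, defaults and numerical choices behind the
package, and what the synthetic benchmark does and does not demonstrate.

## Cleaning model

A raw occurrence row is `(raw_name, latitude, longitude[, depth_m, source,
geocoded, count])`. Name parsing detects the open-nomenclature qualifiers
`aff`, `cf`, `indet`, `sp`, `spp` case-insensitively, with or without
trailing periods, anywhere in the name. Records carrying `aff`/`cf`/`indet`
are rejected (these flag uncertain identifications); `sp`/`spp` records are
kept but marked genus-level — they enter genus-level incidence and the genus
richness G, never species-level incidence, S or E. Synonym mapping is
applied after qualifier stripping, on the bare binomial; the synonym table
must be chain-free (accepted names are fixed points), which is validated at
load. Latitudes outside [−90, 90] and longitudes outside [−180, 180] are
rejected; surviving longitudes are normalized to [−180, 180) (so +180 maps
to −180). Records flagged `geocoded` (coordinates derived from a locality
name) are snapped to the nearest 0.5°, the stated precision of
gazetteer-derived coordinates. An optional land mask (shapely polygons)
rejects points strictly inside land. Exact duplicates (same name,
coordinates and source) are collapsed into one row with a summed count
rather than dropped, so occurrence totals remain auditable. Cleaning is
idempotent and conserves rows: kept + rejected = input.

## Grid

Global equal-angle grid, default 5° (the size must divide 180° and 360°).
Cells are half-open `[lower, upper)` on both axes with latitude +90 folded
into the top row, making assignment total and unambiguous — the boundary
convention is a package decision, since published grid analyses rarely state
one. Cells are identified by `(row, col)`; the human label
(`"35°N130°E-30°N135°E"`, top-left then bottom-right corner) is presentation
only and round-trips through the parser for all 36 × 72 cells.

## Rarefaction

Individual-based (Hurlbert) rarefaction treats occurrence records as
individuals — the only abundance proxy such compilations offer. The exact
hypergeometric expectation and variance are evaluated in log-space via
`gammaln`, stable to N ≈ 1e5. Strata are hemispheric 30° climatic zones
(polar/temperate/tropical per hemisphere) or latitudinal bins (default 5°).
The asymptote diagnostic is the slope of the curve over its last 10%
(species per additional occurrence), flagged "asymptotic" below a threshold
(default 0.01). Sample-based rarefaction is a possible variant that is not
implemented.

## Two-stage clustering

Jaccard dissimilarity on cell species sets (exact on binary data; cells with
fewer than `min_species = 7` species are excluded first — ≥ 7 survives).
The agglomerator is an explicit Lance–Williams implementation (average —
the default and the conventional linkage for ecological incidence data —
plus complete, single and Ward). Ties in the minimal merge distance are
broken by the lexicographically smallest cluster-id pair, for cross-platform
determinism. Average-linkage trees are monotone; this is asserted in tests.
Correctness is checked two independent ways: a brute-force agglomerator that
rescans all cluster pairs each step recomputing distances from the original
leaf matrix (min/max/mean), and, for Ward, a centroid-formula oracle on
Euclidean point sets (the Lance–Williams Ward recursion equals
√(2·nₐn_b/(nₐ+n_b)·‖cₐ−c_b‖²) only for Euclidean-embeddable input, so Ward
oracle instances are generated as random point clouds).

`cut_k(K)` removes the K−1 highest merges; `cut_height(d)` removes merges
with height strictly above d. K-selection diagnostics are computed on tree
cuts (not k-means partitions): WSS is the total within-cluster sum of
squared distances to centroids in incidence-vector space, matching the
centroid phrasing of the elbow method; the elbow is operationalized as the
K with maximal second difference of WSS, and local silhouette maxima are
flagged (singleton clusters contribute silhouette 0). The final K remains a
caller choice — on real data the bend is judged visually and robustness
checked across nearby K; on synthetic runs the default is 2 clusters per
planted province. The secondary stage clusters the K pooled species lists
with the same machinery and cuts at dissimilarity 0.935 (equivalently,
similarity 0.065), lettering groupings A, B, C, … in leaf order.

## Network verification

The bipartite cluster–species graph (edge ⇔ species in pool) is laid out by
a ForceAtlas2-style algorithm: linear attraction along edges scaled by
weight^(edge-weight influence), repulsion ∝ scaling·(deg+1)(deg+1)/distance,
central gravity ∝ (deg+1), and the adaptive global-speed scheme driven by
per-node swinging, stopping when mean displacement < tolerance. Defaults
follow the conventional parameter set (scaling 10, gravity 1, edge-weight
influence 1, tolerance 0.1, approximation θ = 1.2). Repulsion is summed
exactly (vectorized) up to 1500 nodes; beyond that a Barnes–Hut quadtree at
θ is used — at typical sizes the exact sum is both faster and the θ → 0
limit of the approximation. Coordinates are deterministic given the seed;
only relational properties (within-block vs between-block distances,
settling of the displacement trace) are meaningful, not any particular
rendering. LinLog mode and overlap prevention are not implemented.

The visual "the network confirms the clusters" argument is made testable:
clusters are projected onto a weighted graph (shared-species Jaccard
similarity), communities are detected by greedy modularity maximization,
and agreement with the secondary groupings is the adjusted Rand index.
Projected edges with similarity < 0.05 are dropped first: trace sharing (a
few widespread species) otherwise lets the well-known resolution limit of
modularity maximization absorb weakly connected single-cluster units into
unrelated communities. A cluster whose strongest projected edge leads to a
different grouping than its own is flagged "equivocal".

## Delineation

Three criteria govern the scheme: (1) units must not nest — cell and
province memberships are partitions, verified by `check_nesting`; (2) units
should be geographically contiguous — queen adjacency (edge or corner,
wrapping across the antimeridian, no wrap over the poles), scored as the
fraction of cells in the largest connected component; (3) the grouping
structure should be supported by the network consensus (reported, not
enforced).

Outlier handling mirrors how scattered clusters are treated in practice:
cells detached from their cluster's main body, and all cells of undersized
clusters (< `min_cells`, default 2) that do have neighbours, are
individually re-attached to the adjacent cluster with the most similar pool
(cell-to-pool Jaccard; ties to the nearer great-circle centroid, then the
smaller label). The loop repeats to a fixed point; any residual detached
component is then split off as its own unit, so every emitted unit is
contiguous by construction. Undersized clusters with no neighbours at all —
remote oceanic cells — keep their label and are emitted as independent
provinces. A manual-override mapping takes precedence over the heuristic and
is the sanctioned mechanism for expert merges that go beyond the three
criteria; every move is logged with its rationale.

Indices: S and G are unions over member cells; E is the number of species
occurring in no cell outside the unit (dataset-wide complement). The
diversification proxy S/G is rounded half-up to 2 decimals and endemism
100·E/S half-up to 1 decimal (decimal arithmetic, not binary floats), the
precision at which such tables are printed; the package reproduces all 21
published worked-example pairs exactly, and the endemism denominator (the
unit's own S) was verified against those printed percentages.

## Synthetic world

The generator emulates the statistical shape of the motivating compilation:
five provinces of eight 5° cells (2 × 4 blocks, ≥ 1 empty cell apart,
spread across latitudes so all climatic zones are populated), 80 species
per province drawn from a 100-genus pool (~400 species), a target mean of
375 occurrences per cell (~15,000 records), detection probability 0.9, and
noise rates qualifier 5%, `sp.` 3%, misspelling 2%, bad coordinate 1% —
each applied to an exact rounded count of records, with misspellings paired
to an emitted synonym table.

Pool semantics: a fraction `endemic_fraction` (default 0.5) of each
province's pool is constructed as strict endemics — guaranteed to occur in
no other province and flagged in the ground truth. `overlap[i, j]` (default
0.01 per ordered pair, i.e. 4% of a pool borrowed in total) is the fraction
of province i's pool sampled from province j's non-endemic natives;
endemic_fraction plus total borrowed fractions may not exceed 1. Note that
non-endemic natives that happen never to be borrowed are *de facto* unique
to their province without being flagged endemic — realized
occupancy-uniqueness therefore exceeds the endemic flag rate when overlap
is small, exactly as dataset-wide endemism percentages exceed "true"
endemism in real compilations.

Within a province, each pool species receives an occupancy probability
drawn from Beta(2, 2); presence per member cell is Bernoulli, with at least
one cell forced so every pool species is realized; abundance per presence
is geometric with mean set so the target per-cell occurrence mean is met;
detection thins counts binomially. Coordinates are uniform inside the cell.
One master seed feeds named substreams (`species`, `occupancy`,
`positions`, `noise`, `layout`, …) so stages can be regenerated
independently and identical seeds give byte-identical output.

What the benchmark does *not* emulate: coastline geometry and realistic
shelf shapes, bathymetry, latitudinal diversity gradients, phylogenetic
structure among species, and spatially autocorrelated sampling effort.
Passing the recovery tests therefore shows that the pipeline's inference is
correct when its assumptions hold (block-structured provinces, modest
sharing), not that any particular real-world scheme is right.

## Problem sizes and runtime choices

Unit tests use a 3-province world (~1,000 records); the acceptance suite
and `scripts/acceptance.py` run the full default world (5 provinces,
~13,000 raw records per seed) over 20 and 10 seeds respectively, 100 random
instances per linkage for the brute-force agglomerator comparison, and
10,000 Monte-Carlo resamples per rarefaction check — sizes chosen so the
whole verification runs in a few minutes on one CPU while keeping the
Monte-Carlo standard errors small (3·SE ≈ 0.05 species).

## Known limitations

- The elbow is a discrete operationalization of a visual judgment; on
  near-flat WSS profiles the flagged K is weakly determined, which is why K
  stays caller-chosen.
- Greedy modularity (with the 0.05 projection floor) is still subject to
  resolution effects on very small cluster graphs.
- The outlier heuristic optimizes contiguity locally; expert merges (e.g.
  combining adjacent clusters into one named province) require the override
  mechanism.
- Independent-province status is purely size-and-isolation based
  (`min_cells`); no attempt is made to model island biogeography.
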