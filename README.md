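# bioregions

Quantitative bioregionalization of marine occurrence data.

Global compilations of georeferenced taxon occurrences — assembled from
literature, museum records and aggregators such as GBIF/OBIS — are the raw
material for delineating **bioregions** and **bioprovinces**: hierarchical
units of faunal similarity. This package implements the full analysis chain
for such a study, originally developed around the global distribution of
living brachiopods (~400 species in ~100 genera, ~15,000 cleaned
occurrences), as a tested, reusable library:

1. **Cleaning** — open-nomenclature qualifiers (`aff.`, `cf.`, `indet.`) are
   rejected; `sp.`/`spp.` records are retained for genus-level analysis only;
   misspellings are reconciled through a synonym table; coordinates are
   validated (|lat| ≤ 90, |lon| ≤ 180, longitudes normalized to
   [−180, 180)); exact duplicates are collapsed with a count.
2. **Gridding** — occurrences are binned into 5° latitude/longitude cells
   (half-open intervals, +90° folded into the top row); binary cell × taxon
   incidence matrices are built at species and genus level, and per-cell
   richness is mapped (GeoJSON export).
3. **Rarefaction** — individual-based (Hurlbert) expected richness
   E[S_n] = Σᵢ (1 − C(N−Nᵢ, n)/C(N, n)), per hemispheric climatic zone or 5°
   latitudinal bin, with a terminal-slope asymptote diagnostic for sampling
   completeness.
4. **Two-stage clustering** — cells with ≥ 7 species are compared by Jaccard
   dissimilarity d = 1 − |A∩B|/|A∪B| and clustered agglomeratively
   (average linkage by default, deterministic tie-breaking); elbow (WSS) and
   silhouette diagnostics inform the caller-chosen primary K; the K cluster
   pools are clustered again and cut at a fixed dissimilarity (0.935) to
   yield the final groupings.
5. **Network verification** — a bipartite cluster–species network with a
   ForceAtlas2-style layout (scaling 10, gravity 1, edge-weight influence 1,
   tolerance 0.1, Barnes–Hut approximation 1.2), plus a quantitative
   consensus check: greedy-modularity communities on the Jaccard-weighted
   cluster projection are compared to the groupings by adjusted Rand index.
6. **Delineation** — groupings become bioregions and clusters bioprovinces
   under three criteria (no nesting, geographic contiguity under queen
   adjacency with antimeridian wrap, network support); scattered cells are
   reassigned to the most similar adjacent province; small remote clusters
   are emitted as independent provinces. Per-unit indices: species richness
   S, genus richness G, the diversification-rate proxy S/G (half-up, 2 dp)
   and endemism 100·E/S (half-up, 1 dp), with E the number of species found
   nowhere outside the unit.

Because comparable occurrence compilations are rarely deposited with
coordinates, the package ships a first-class **synthetic world generator**:
provinces planted as rectangular blocks of shelf cells, species pools with a
controllable endemic fraction and cross-province sharing, Beta(2,2) × 
geometric occupancy/abundance skew, imperfect detection, and raw-data noise
(qualifiers, genus-level records, misspellings with a paired synonym table,
out-of-range coordinates) — with full ground truth, so that every stage of
the pipeline is testable end to end.

## Worked example

```python
from bioregions import BioregionalizationModel

model = BioregionalizationModel.from_synthetic(seed=1)   # default world
results = model.fit()
print(results.summary())
```

prints

```
Bioregionalization results
============================================================
input records             13139
records kept              12351  (rejected 788)
occurrences (weighted)    12351
occupied cells               40
cells clustered (>= 7 species)   40
species / genera            379 / 99
primary clusters (K)         10  [average linkage]
groupings (cut 0.935)          5
bioregions                    5
bioprovinces                  7  (+0 independent)
nesting criterion          pass
min unit contiguity       1.000
network consensus ARI     1.000
planted-province ARI      1.000
============================================================
unit indices (S, G, S/G, E, endemism%):
  A1         S=80   G=58   ratio=1.38  E=72   endemism=90.0%
  B1         S=77   G=55   ratio=1.4   E=28   endemism=36.4%
  ...
```

Reading this: of 13,139 raw synthetic records, 788 were rejected by the
cleaning rules (qualifiers and bad coordinates). The 12,351 kept occurrences
of 379 species occupy 40 grid cells, all with ≥ 7 species. The primary cut
at K = 10 followed by the secondary cut at dissimilarity 0.935 yields 5
groupings, which the delineation turns into 5 bioregions with 7 contiguous
bioprovinces; both the network consensus and the comparison against the
planted provinces give an adjusted Rand index of 1.0 — the planted structure
is recovered exactly. Per-unit lines show richness, the S/G
diversification proxy and endemism; e.g. unit A1 holds 80 species in 58
genera (S/G = 1.38) of which 72 (90.0%) occur nowhere else.

`results.save(outdir)` writes every export (cleaned records, rejection log,
incidence matrices, GeoJSON richness grid, rarefaction curves, Newick
dendrograms, partitions, network tables, layout coordinates, scheme JSON,
index table, criteria report, manifest). The same run is available from the
shell:

```sh
bioregions run --synthetic --seed 1 --out out/
bioregions simulate --seed 1 --out sim/          # raw world + ground truth
bioregions clean sim/occurrences.csv --synonyms sim/synonyms.csv --out cleaned/
```

Real data enter through `BioregionalizationModel.from_csv("occurrences.csv",
"synonyms.csv")`; the expected columns are `raw_name, latitude, longitude`
plus optional `depth_m, source, geocoded, count`.

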