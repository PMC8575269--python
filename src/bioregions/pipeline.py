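"""End-to-end bioregionalization, exposed as a Model / Results pair.

:class:`BioregionalizationModel` is constructed from raw occurrence data (or
a synthetic world configuration) plus the analysis settings; ``fit()`` runs
the full chain — clean → grid → rarefy → primary clustering → pooling →
secondary grouping → network consensus → delineation — and returns a
:class:`BioregionalizationResults` carrying every intermediate artifact, the
final scheme with per-unit indices, diagnostics and a ``summary()`` table.
Runs are deterministic: a single master seed feeds named substreams, and
re-running with the same inputs and seed writes byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import delineate as _delineate
from . import grid as _grid
from . import io as _io
from . import network as _network
from . import rarefaction as _rarefaction
from . import synthetic as _synthetic
from .errors import ConfigurationError

__all__ = ["RunConfig", "BioregionalizationModel", "BioregionalizationResults",
           "run_pipeline", "derive_seed"]


def derive_seed(seed: int, name: str) -> int:
    """Stable per-stage integer seed below 2**31."""
    return (int(seed) * 1000003 ^ zlib.crc32(name.encode("utf-8"))) & 0x7FFFFFFF


@dataclass(frozen=True)
class RunConfig:
    """Settings of one pipeline run.

    Exactly one of ``occurrences`` (path to a raw CSV/TSV table) or
    ``synthetic`` (a :class:`~bioregions.synthetic.WorldConfig`) must be set.
    """

    occurrences: str | None = None
    synonyms: str | None = None
    synthetic: _synthetic.WorldConfig | None = None
    cell_size: float = 5.0
    min_species: int = 7
    linkage: str = "average"
    n_clusters: int | None = None
    k_range: tuple[int, int] = (2, 30)
    secondary_cut: float = 0.935
    min_cells: int = 2
    layout: _network.LayoutParams = field(default_factory=_network.LayoutParams)
    rarefy: bool = True
    k_diagnostics: bool = False
    overrides: dict | None = None
    seed: int = 0

    def validate(self) -> None:
        if (self.occurrences is None) == (self.synthetic is None):
            raise ConfigurationError(
                "supply exactly one of occurrences path or synthetic config"
            )
        if self.min_species < 1:
            raise ConfigurationError("min_species must be >= 1")
        if not 0 <= self.secondary_cut <= 1:
            raise ConfigurationError("secondary_cut must lie in [0, 1]")
        if self.linkage not in _cluster.LINKAGES:
            raise ConfigurationError(f"linkage must be one of {_cluster.LINKAGES}")


@dataclass
class BioregionalizationResults:
    """Artifacts of one fitted bioregionalization."""

    config: RunConfig
    raw_records: pd.DataFrame
    records: pd.DataFrame
    rejection_log: _io.RejectionLog
    species_incidence: _grid.IncidenceMatrix
    genus_incidence: _grid.IncidenceMatrix
    filtered_incidence: _grid.IncidenceMatrix
    rarefaction_curves: dict
    distance: _cluster.DistanceMatrix
    dendrogram: _cluster.Dendrogram
    k_table: pd.DataFrame | None
    partition: _cluster.ClusterPartition
    pools: list
    grouping: dict
    secondary_dendrogram: _cluster.Dendrogram
    network: object
    layout: dict
    layout_trace: np.ndarray
    consensus: _network.ConsensusReport
    cell_labels: dict
    reassignment_log: list
    scheme: _delineate.BioScheme
    indices: pd.DataFrame
    criteria_report: dict
    truth: _synthetic.GroundTruth | None
    manifest: dict

    # -- evaluation ---------------------------------------------------------

    def final_cell_regions(self) -> dict:
        """Final unit label of every clustered cell (bioregion letter where
        available, else the independent-province label)."""
        out = {}
        prov_region = {}
        for region, provs in self.scheme.bioregions.items():
            for prov in provs:
                prov_region[prov] = region
        for label, info in self.scheme.bioprovinces.items():
            unit = prov_region.get(label, label)
            for cell in info["cells"]:
                out[cell] = unit
        return out

    def recovery_ari(self) -> float | None:
        """Adjusted Rand index between final units and planted provinces."""
        if self.truth is None:
            return None
        from sklearn.metrics import adjusted_rand_score

        regions = self.final_cell_regions()
        cells = [c for c in regions if c in self.truth.cell_provinces]
        if not cells:
            return None
        return float(
            adjusted_rand_score(
                [self.truth.cell_provinces[c] for c in cells],
                [regions[c] for c in cells],
            )
        )

    def summary(self) -> str:
        m = self.manifest
        lines = [
            "Bioregionalization results",
            "=" * 60,
            f"input records          {m['n_raw']:>8}",
            f"records kept           {m['n_kept']:>8}  (rejected {m['n_rejected']})",
            f"occurrences (weighted) {m['n_occurrences']:>8}",
            f"occupied cells         {m['n_cells']:>8}",
            f"cells clustered (>= {self.config.min_species} species) "
            f"{m['n_filtered_cells']:>4}",
            f"species / genera       {m['n_species']:>8} / {m['n_genera']}",
            f"primary clusters (K)   {m['K']:>8}  [{self.config.linkage} linkage]",
            f"groupings (cut {self.config.secondary_cut:g})   "
            f"{m['n_groupings']:>8}",
            f"bioregions             {m['n_bioregions']:>8}",
            f"bioprovinces           {m['n_bioprovinces']:>8}"
            f"  (+{m['n_independent']} independent)",
            f"nesting criterion      {'pass' if self.criteria_report['nesting_ok'] else 'FAIL':>8}",
            f"min unit contiguity    {self.criteria_report['min_contiguity']:>8.3f}",
        ]
        if self.consensus.ari is not None:
            lines.append(f"network consensus ARI  {self.consensus.ari:>8.3f}")
        ari = self.recovery_ari()
        if ari is not None:
            lines.append(f"planted-province ARI   {ari:>8.3f}")
        lines.append("=" * 60)
        lines.append("unit indices (S, G, S/G, E, endemism%):")
        for _, row in self.indices.iterrows():
            lines.append(
                f"  {row['unit']:<10} S={row['S']:<4} G={row['G']:<4} "
                f"ratio={row['ratio']:<5} E={row['E']:<4} "
                f"endemism={row['endemism_pct']}%"
            )
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, outdir) -> None:
        """Write every export (CSV/JSON/Newick/GeoJSON) into ``outdir``."""
        import os

        os.makedirs(outdir, exist_ok=True)

        def path(name):
            return os.path.join(outdir, name)

        _io.write_occurrences(self.records, path("cleaned.csv"))
        self.rejection_log.to_csv(path("rejections.csv"))
        self.species_incidence.to_csv(path("incidence_species.csv"))
        self.genus_incidence.to_csv(path("incidence_genus.csv"))
        _grid.write_geojson(self.species_incidence, path("grid_richness.geojson"))
        _rarefaction.curves_to_frame(self.rarefaction_curves).to_csv(
            path("rarefaction.csv"), index=False
        )
        with open(path("dendrogram_primary.newick"), "w") as fh:
            fh.write(self.dendrogram.to_newick() + "\n")
        self.dendrogram.to_frame().to_csv(path("merges_primary.csv"), index=False)
        with open(path("dendrogram_secondary.newick"), "w") as fh:
            fh.write(self.secondary_dendrogram.to_newick() + "\n")
        if self.k_table is not None:
            self.k_table.to_csv(path("k_diagnostics.csv"), index=False)
        part = pd.DataFrame(
            [
                {"row": r, "col": c, "cluster": self.partition.labels[(r, c)],
                 "final": self.cell_labels[(r, c)]}
                for (r, c) in sorted(self.partition.labels)
            ]
        )
        part.to_csv(path("partition.csv"), index=False)
        pd.DataFrame(
            [{"cluster": cid, "grouping": g} for cid, g in sorted(
                self.grouping.items(), key=lambda kv: str(kv[0]))]
        ).to_csv(path("groupings.csv"), index=False)
        nodes, edges = _network.network_to_frames(self.network)
        nodes.to_csv(path("network_nodes.csv"), index=False)
        edges.to_csv(path("network_edges.csv"), index=False)
        import networkx as nx

        flat = nx.relabel_nodes(
            self.network, {n: f"{n[0]}:{n[1]}" for n in self.network.nodes}
        )
        nx.write_graphml(flat, path("network.graphml"))
        with open(path("province_footprints.geojson"), "w") as fh:
            json.dump(self._province_geojson(), fh, sort_keys=True)
        pd.DataFrame(
            [
                {"kind": k, "id": str(v), "x": xy[0], "y": xy[1]}
                for (k, v), xy in self.layout.items()
            ]
        ).to_csv(path("layout.csv"), index=False)
        with open(path("scheme.json"), "w") as fh:
            fh.write(self.scheme.to_json() + "\n")
        self.indices.to_csv(path("indices.csv"), index=False)
        with open(path("criteria_report.json"), "w") as fh:
            json.dump(_jsonable(self.criteria_report), fh, sort_keys=True, indent=1)
        pd.DataFrame(
            self.reassignment_log, columns=["cell", "from", "to", "rationale"]
        ).assign(cell=lambda d: d["cell"].astype(str),
                 **{"from": lambda d: d["from"].astype(str),
                    "to": lambda d: d["to"].astype(str)}).to_csv(
            path("reassignment_log.csv"), index=False
        )
        with open(path("manifest.json"), "w") as fh:
            json.dump(_jsonable(self.manifest), fh, sort_keys=True, indent=1)

    def _province_geojson(self) -> dict:
        grid = self.species_incidence.grid
        features = []
        for label in sorted(self.scheme.bioprovinces, key=str):
            for cell in sorted(self.scheme.bioprovinces[label]["cells"]):
                lat_min, lat_max, lon_min, lon_max = grid.cell_bounds(*cell)
                ring = [[lon_min, lat_min], [lon_max, lat_min],
                        [lon_max, lat_max], [lon_min, lat_max],
                        [lon_min, lat_min]]
                features.append({
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {"unit": label, "row": cell[0],
                                   "col": cell[1]},
                })
        return {"type": "FeatureCollection", "features": features}

    # -- plotting -----------------------------------------------------------

    def plot_rarefaction(self, ax=None):
        """Rarefaction curves per stratum (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for key in sorted(self.rarefaction_curves):
            curve = self.rarefaction_curves[key]
            ax.plot(curve.sizes, curve.expected, label=str(key))
        ax.set_xlabel("occurrences subsampled")
        ax.set_ylabel("expected species richness")
        ax.legend(fontsize="small")
        return ax

    def plot_network(self, ax=None):
        """Layout scatter; cluster nodes sized by species count."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for (kind, name), (x, y) in self.layout.items():
            if kind == "species":
                ax.plot(x, y, ".", color="0.7", ms=3)
        for (kind, name), (x, y) in self.layout.items():
            if kind == "cluster":
                size = self.network.nodes[(kind, name)]["species_count"]
                ax.plot(x, y, "o", ms=4 + 0.2 * size)
                ax.annotate(str(name), (x, y), fontsize=7)
        ax.set_aspect("equal")
        return ax


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj, key=str) if True] if isinstance(
            obj, set) else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


class BioregionalizationModel:
    """Two-stage Jaccard bioregionalization of occurrence data.

    Parameters mirror :class:`RunConfig`; construct via ``from_csv`` /
    ``from_dataframe`` / ``from_synthetic`` and call :meth:`fit`.
    """

    def __init__(self, config: RunConfig, raw_records: pd.DataFrame | None = None,
                 synonyms: _io.SynonymTable | None = None,
                 truth: _synthetic.GroundTruth | None = None):
        config.validate()
        self.config = config
        self._raw = raw_records
        self._synonyms = synonyms
        self._truth = truth

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_csv(cls, path, synonyms_path=None, **settings):
        config = RunConfig(occurrences=str(path),
                           synonyms=str(synonyms_path) if synonyms_path else None,
                           **settings)
        raw = _io.read_occurrences(path)
        synonyms = (
            _io.SynonymTable.from_csv(synonyms_path) if synonyms_path else None
        )
        return cls(config, raw, synonyms)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       synonyms: _io.SynonymTable | None = None, **settings):
        config = RunConfig(occurrences="<dataframe>", **settings)
        return cls(config, frame, synonyms)

    @classmethod
    def from_synthetic(cls, world: _synthetic.WorldConfig | None = None,
                       seed: int | None = None, **settings):
        world = world or _synthetic.WorldConfig()
        if seed is not None:
            world = replace(world, seed=derive_seed(seed, "world"))
            settings.setdefault("seed", seed)
        # the primary K stays a caller choice; on synthetic worlds default to
        # two clusters per planted province
        settings.setdefault("n_clusters", 2 * world.n_provinces)
        config = RunConfig(synthetic=world, **settings)
        return cls(config)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> BioregionalizationResults:
        config = self.config
        truth = self._truth
        synonyms = self._synonyms
        if config.synthetic is not None:
            clean, truth = _synthetic.generate_world(config.synthetic)
            raw, synonyms, _ = _synthetic.corrupt_records(
                clean, config.synthetic.noise, derive_seed(config.synthetic.seed,
                                                           "corruption")
            )
        else:
            raw = self._raw

        records, rejections = _io.clean_records(raw, synonyms)

        grid = _grid.GridSpec(cell_size=config.cell_size)
        sp_inc = _grid.build_incidence(records, grid, level="species")
        gen_inc = _grid.build_incidence(records, grid, level="genus")
        filtered = _grid.filter_cells(sp_inc, config.min_species)

        curves = (
            _rarefaction.rarefaction_by_stratum(records, "climatic_zone")
            if config.rarefy
            else {}
        )

        dist = _cluster.jaccard_distance(filtered)
        dend = _cluster.agglomerate(dist, config.linkage)
        n_cells = len(filtered.data)
        k_table = None
        if config.n_clusters is not None:
            K = int(config.n_clusters)
        else:
            lo, hi = config.k_range
            ks = range(max(2, lo), min(hi, n_cells - 1) + 1)
            k_table = _cluster.select_k(dend, dist, filtered, ks)
            K = int(k_table.loc[k_table["is_elbow"], "K"].iloc[0])
        if config.k_diagnostics and k_table is None:
            lo, hi = config.k_range
            ks = range(max(2, lo), min(hi, n_cells - 1) + 1)
            k_table = _cluster.select_k(dend, dist, filtered, ks)
        K = min(K, n_cells)
        partition = _cluster.cut_k(dend, K)
        pools = _cluster.pool_clusters(partition, filtered)
        grouping, sec_dend = _cluster.secondary_grouping(
            pools, config.linkage, config.secondary_cut
        )

        net = _network.build_bipartite(pools)
        layout_params = replace(config.layout, seed=derive_seed(config.seed, "layout"))
        layout, trace = _network.layout_force(net, layout_params)
        consensus = _network.consensus_communities(pools, grouping)

        adjacency = _delineate.build_adjacency(list(partition.labels), grid)
        cell_labels, audit = _delineate.reassign_outliers(
            partition.labels, filtered, adjacency,
            min_cells=config.min_cells, overrides=config.overrides,
        )
        scheme, indices, report = _delineate.build_scheme(
            grouping, cell_labels, filtered, gen_inc, adjacency,
            min_cells=config.min_cells,
        )
        report["network_consensus_ari"] = consensus.ari
        report["network_supported"] = (
            consensus.ari is not None and consensus.ari >= 0.9
        )
        report["equivocal_clusters"] = consensus.equivocal

        manifest = {
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "n_raw": int(len(raw)),
            "n_rejected": int(len(rejections)),
            "n_kept": int(len(records)),
            "n_occurrences": int(records["count"].sum()) if len(records) else 0,
            "n_cells": int(len(sp_inc.data)),
            "n_filtered_cells": int(n_cells),
            "n_species": int(sp_inc.data.shape[1]),
            "n_genera": int(gen_inc.data.shape[1]),
            "K": int(K),
            "n_groupings": len(set(grouping.values())),
            "n_bioregions": report["n_bioregions"],
            "n_bioprovinces": report["n_bioprovinces"],
            "n_independent": report["n_independent"],
            "rejection_reasons": {
                str(k): int(v) for k, v in rejections.reasons().items()
            },
        }
        return BioregionalizationResults(
            config=config,
            raw_records=raw,
            records=records,
            rejection_log=rejections,
            species_incidence=sp_inc,
            genus_incidence=gen_inc,
            filtered_incidence=filtered,
            rarefaction_curves=curves,
            distance=dist,
            dendrogram=dend,
            k_table=k_table,
            partition=partition,
            pools=pools,
            grouping=grouping,
            secondary_dendrogram=sec_dend,
            network=net,
            layout=layout,
            layout_trace=trace,
            consensus=consensus,
            cell_labels=cell_labels,
            reassignment_log=audit,
            scheme=scheme,
            indices=indices,
            criteria_report=report,
            truth=truth,
            manifest=manifest,
        )


def _config_hash(config: RunConfig) -> str:
    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if hasattr(obj, "__dict__"):
            return vars(obj)
        return str(obj)

    payload = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir=None) -> BioregionalizationResults:
    """Fit the model described by ``config``; write exports when ``outdir``
    is given.  Returns the results object."""
    if config.occurrences and config.occurrences != "<dataframe>":
        model = BioregionalizationModel.from_csv(
            config.occurrences, config.synonyms,
            **{k: v for k, v in asdict(config).items()
               if k not in ("occurrences", "synonyms", "synthetic", "layout")},
        )
        model = BioregionalizationModel(config, model._raw, model._synonyms)
    else:
        model = BioregionalizationModel(config)
    results = model.fit()
    if outdir is not None:
        results.save(outdir)
    return results
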