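"""Synthetic occurrence worlds with planted biogeographical structure.

The generator emulates the statistical shape of a global compilation of
living-brachiopod occurrences: a few hundred species in a ~100-genus pool,
on the order of 15,000 georeferenced records, species pools structured into
provinces (rectangular blocks of 5-degree shelf cells) with a controllable
endemic fraction and cross-province sharing, skewed within-cell occupancy
and abundance, imperfect detection, and raw-data noise (open-nomenclature
qualifiers, genus-level records, misspellings paired with a synonym table,
and out-of-range coordinates) to exercise the cleaning stage.

Every draw is taken from named substreams of a single master seed, so a
given configuration is byte-reproducible and individual stages can be
regenerated independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .grid import GridSpec
from .io import COLUMNS, SynonymTable

__all__ = [
    "WorldConfig",
    "NoiseConfig",
    "GroundTruth",
    "generate_world",
    "corrupt_records",
    "substream",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, stably named child stream of a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                               spawn_key=(zlib.crc32(name.encode("utf-8")),))
    )


@dataclass(frozen=True)
class NoiseConfig:
    """Rates of raw-data corruption applied by :func:`corrupt_records`.

    Each rate is the exact (rounded-count) proportion of records perturbed:
    ``qualifier_rate`` rewrites names with aff./cf./indet., ``sp_rate``
    rewrites them as "Genus sp.", ``misspelling_rate`` injects a one-character
    typo paired with a synonym-table entry, ``bad_coord_rate`` pushes a
    coordinate out of range.  The perturbation sets are disjoint.
    """

    qualifier_rate: float = 0.05
    sp_rate: float = 0.03
    misspelling_rate: float = 0.02
    bad_coord_rate: float = 0.01

    def validate(self) -> None:
        rates = (self.qualifier_rate, self.sp_rate, self.misspelling_rate,
                 self.bad_coord_rate)
        if any(not 0 <= r <= 1 for r in rates):
            raise ConfigurationError("noise rates must lie in [0, 1]")
        if sum(rates) > 1:
            raise ConfigurationError("noise rates must sum to <= 1")

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class WorldConfig:
    """Configuration of a planted-province occurrence world.

    ``overlap`` is either a scalar (applied to every ordered province pair)
    or a full matrix; entry ``[i, j]`` is the fraction of province *i*'s
    species pool borrowed from province *j*'s non-endemic natives.
    ``occurrences_per_cell`` is the target mean occurrence count per member
    cell; within-cell skew comes from Beta(2,2) per-species occupancy
    probabilities and geometric per-presence abundances.
    """

    n_provinces: int = 5
    cells_per_province: int = 8
    species_per_province: int = 80
    endemic_fraction: float = 0.5
    overlap: float | np.ndarray = 0.01
    genus_pool_size: int = 100
    occurrences_per_cell: float = 375.0
    detection_prob: float = 0.9
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0
    grid: GridSpec = field(default_factory=GridSpec)

    def overlap_matrix(self) -> np.ndarray:
        n = self.n_provinces
        if np.isscalar(self.overlap):
            mat = np.full((n, n), float(self.overlap))
        else:
            mat = np.asarray(self.overlap, dtype=float)
            if mat.shape != (n, n):
                raise ConfigurationError("overlap matrix has wrong shape")
        np.fill_diagonal(mat, 0.0)
        return mat

    def validate(self) -> None:
        for name in ("n_provinces", "cells_per_province", "species_per_province",
                     "genus_pool_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0 <= self.endemic_fraction <= 1:
            raise ConfigurationError("endemic_fraction must lie in [0, 1]")
        if not 0 < self.detection_prob <= 1:
            raise ConfigurationError("detection_prob must lie in (0, 1]")
        if self.occurrences_per_cell <= 0:
            raise ConfigurationError("occurrences_per_cell must be > 0")
        mat = self.overlap_matrix()
        if np.any(mat < 0) or np.any(mat > 1):
            raise ConfigurationError("overlap entries must lie in [0, 1]")
        for i in range(self.n_provinces):
            if self.endemic_fraction + mat[i].sum() > 1 + 1e-9:
                raise ConfigurationError(
                    "endemic_fraction + shared fractions exceed 1 for province "
                    f"{i}"
                )
        self.noise.validate()
        _province_blocks(self)  # raises if the blocks do not fit the grid


def _block_shape(cells: int) -> tuple[int, int]:
    rows = max(1, int(np.floor(np.sqrt(cells))))
    cols = int(np.ceil(cells / rows))
    return rows, cols


def _province_blocks(config: WorldConfig) -> list[list[tuple[int, int]]]:
    """Rectangular cell blocks, >= 1 empty cell apart, spread across latitudes."""
    grid = config.grid
    brows, bcols = _block_shape(config.cells_per_province)
    n = config.n_provinces
    dr = max(brows + 1, (grid.n_rows - 4 - brows) // max(1, n))
    dc = max(bcols + 1, (grid.n_cols - 4 - bcols) // max(1, n))
    blocks = []
    for p in range(n):
        r0 = 2 + p * dr
        c0 = 2 + p * dc
        if r0 + brows > grid.n_rows or c0 + bcols > grid.n_cols:
            raise ConfigurationError(
                "provinces do not fit on the grid; reduce n_provinces or "
                "cells_per_province"
            )
        cells = [
            (r0 + r, c0 + c)
            for r in range(brows)
            for c in range(bcols)
        ][: config.cells_per_province]
        blocks.append(cells)
    return blocks


@dataclass
class GroundTruth:
    """Planted labels emitted alongside a synthetic world."""

    cell_provinces: dict  # (row, col) -> province index
    species_province: dict  # binomial -> province of origin
    species_endemic: dict  # binomial -> bool
    pools: dict  # province index -> ordered list of binomials
    occupancy: dict  # ((row, col), binomial) -> detected occurrence count
    expected_clean_count: int

    def cells_of(self, province: int) -> list[tuple[int, int]]:
        return [c for c, p in self.cell_provinces.items() if p == province]

    def endemism_by_province(self) -> dict:
        """Fraction of each province pool flagged endemic (pool-relative)."""
        out = {}
        for p, pool in self.pools.items():
            out[p] = float(np.mean([self.species_endemic[s] for s in pool]))
        return out

    def to_csvs(self, cells_path, species_path) -> None:
        pd.DataFrame(
            [
                {"row": r, "col": c, "province": p}
                for (r, c), p in sorted(self.cell_provinces.items())
            ]
        ).to_csv(cells_path, index=False)
        pd.DataFrame(
            [
                {
                    "species": s,
                    "province": self.species_province[s],
                    "endemic": self.species_endemic[s],
                }
                for s in sorted(self.species_province)
            ]
        ).to_csv(species_path, index=False)


def _species_name(genus: str, index: int) -> str:
    return f"{genus} species{index:04d}"


def generate_world(config: WorldConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate clean occurrence records plus ground truth for a planted world.

    Deterministic given ``config.seed``.  Provinces occupy disjoint,
    internally contiguous rectangular blocks of grid cells; each province's
    pool is its endemic and non-endemic natives plus draws from other
    provinces' non-endemic natives per the overlap matrix; occurrences sit at
    uniform-random coordinates inside member cells.
    """
    config.validate()
    grid = config.grid
    blocks = _province_blocks(config)
    overlap = config.overlap_matrix()
    n_prov, n_sp = config.n_provinces, config.species_per_province

    rng_sp = substream(config.seed, "species")
    genera = [f"Genus{i + 1:03d}" for i in range(config.genus_pool_size)]

    n_end = int(round(config.endemic_fraction * n_sp))
    n_share = np.round(overlap * n_sp).astype(int)
    natives: list[list[str]] = []
    nonendemic_natives: list[list[str]] = []
    species_province: dict[str, int] = {}
    species_endemic: dict[str, bool] = {}
    counter = 0
    for p in range(n_prov):
        n_own = n_sp - int(n_share[p].sum())
        if n_own < n_end:
            raise ConfigurationError("overlap leaves no room for endemics")
        own = []
        for k in range(n_own):
            counter += 1
            genus = genera[int(rng_sp.integers(len(genera)))]
            name = _species_name(genus, counter)
            own.append(name)
            species_province[name] = p
            species_endemic[name] = k < n_end
        natives.append(own)
        nonendemic_natives.append(own[n_end:])

    pools: dict[int, list[str]] = {}
    for p in range(n_prov):
        pool = list(natives[p])
        for q in range(n_prov):
            k = int(n_share[p, q])
            if k == 0 or q == p:
                continue
            candidates = nonendemic_natives[q]
            if k > len(candidates):
                raise ConfigurationError(
                    f"province {q} has too few non-endemic natives to share"
                )
            picks = rng_sp.choice(len(candidates), size=k, replace=False)
            pool.extend(candidates[i] for i in sorted(picks))
        pools[p] = pool

    cell_provinces = {cell: p for p, cells in enumerate(blocks) for cell in cells}

    # occupancy and abundance
    rng_occ = substream(config.seed, "occupancy")
    mean_abund = config.occurrences_per_cell / (len(pools[0]) * 0.5)
    p_geom = min(1.0, 1.0 / max(mean_abund, 1.0))
    occupancy: dict[tuple, int] = {}
    for p in range(n_prov):
        cells = blocks[p]
        for name in pools[p]:
            q = rng_occ.beta(2.0, 2.0)
            present = rng_occ.random(len(cells)) < q
            if not present.any():
                present[int(rng_occ.integers(len(cells)))] = True
            for cell, here in zip(cells, present):
                if not here:
                    continue
                count = int(rng_occ.geometric(p_geom))
                if config.detection_prob < 1.0:
                    count = int(rng_occ.binomial(count, config.detection_prob))
                if count > 0:
                    occupancy[(cell, name)] = occupancy.get((cell, name), 0) + count

    rng_pos = substream(config.seed, "positions")
    rows = []
    for (cell, name), count in occupancy.items():
        lat_min, lat_max, lon_min, lon_max = grid.cell_bounds(*cell)
        genus, epithet = name.split(" ", 1)
        for _ in range(count):
            lat = float(rng_pos.uniform(lat_min, lat_max))
            lon = float(rng_pos.uniform(lon_min, lon_max))
            rows.append(
                {
                    "raw_name": name,
                    "genus": genus,
                    "species_epithet": epithet,
                    "qualifier": "none",
                    "latitude": lat,
                    "longitude": lon,
                    "depth_m": float(np.round(rng_pos.uniform(5.0, 200.0), 1)),
                    "source": "synthetic",
                    "geocoded": False,
                    "count": 1,
                }
            )
    records = pd.DataFrame(rows, columns=COLUMNS)
    truth = GroundTruth(
        cell_provinces=cell_provinces,
        species_province=species_province,
        species_endemic=species_endemic,
        pools=pools,
        occupancy=occupancy,
        expected_clean_count=int(sum(occupancy.values())),
    )
    return records, truth


_TYPO_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def _misspell(word: str, rng: np.random.Generator) -> str:
    # typo only at letter positions so the result cannot collide with a real
    # numbered binomial
    positions = [i for i, ch in enumerate(word) if ch.isalpha()]
    if not positions:
        return word + "x"
    i = positions[int(rng.integers(len(positions)))]
    old = word[i]
    choices = [c for c in _TYPO_ALPHABET if c != old.lower()]
    new = choices[int(rng.integers(len(choices)))]
    return word[:i] + new + word[i + 1:]


def corrupt_records(
    records: pd.DataFrame, noise: NoiseConfig, seed: int
) -> tuple[pd.DataFrame, SynonymTable, pd.DataFrame]:
    """Apply raw-data noise to clean records.

    Exactly ``round(rate * n)`` records receive each perturbation type
    (disjoint sets, deterministic per seed).  Returns the raw table (name and
    coordinate columns only, as a field compilation would look), a synonym
    table mapping each injected misspelling to its accepted binomial, and a
    perturbation log with one row per perturbed record.
    """
    noise.validate()
    n = len(records)
    raw = records.copy().reset_index(drop=True)
    rng = substream(seed, "noise")
    perm = rng.permutation(n)
    sizes = {
        "qualifier": int(round(noise.qualifier_rate * n)),
        "sp": int(round(noise.sp_rate * n)),
        "misspelling": int(round(noise.misspelling_rate * n)),
        "bad_coord": int(round(noise.bad_coord_rate * n)),
    }
    log_rows = []
    synonyms: dict[str, str] = {}
    start = 0
    for kind, size in sizes.items():
        idx = perm[start:start + size]
        start += size
        for i in idx:
            genus = raw.at[i, "genus"]
            epithet = raw.at[i, "species_epithet"]
            if kind == "qualifier":
                q = ("aff", "cf", "indet")[int(rng.integers(3))]
                raw.at[i, "raw_name"] = f"{genus} {q}. {epithet}"
            elif kind == "sp":
                raw.at[i, "raw_name"] = f"{genus} sp."
            elif kind == "misspelling":
                bad = _misspell(str(epithet), rng)
                if bad == epithet:  # single-letter epithets cannot collide
                    bad = epithet + "x"
                raw.at[i, "raw_name"] = f"{genus} {bad}"
                synonyms[f"{genus} {bad}"] = f"{genus} {epithet}"
            elif kind == "bad_coord":
                if rng.random() < 0.5:
                    raw.at[i, "latitude"] = float(rng.uniform(90.5, 179.5)) * (
                        1 if rng.random() < 0.5 else -1
                    )
                else:
                    raw.at[i, "longitude"] = float(rng.uniform(180.5, 359.5)) * (
                        1 if rng.random() < 0.5 else -1
                    )
            log_rows.append({"row": int(i), "kind": kind})
    raw = raw.loc[:, ["raw_name", "latitude", "longitude", "depth_m", "source",
                      "geocoded", "count"]]
    log = pd.DataFrame(log_rows, columns=["row", "kind"])
    return raw, SynonymTable(synonyms), log


def default_world(seed: int = 0, **overrides) -> WorldConfig:
    """The package's reference study conditions with a given master seed."""
    return replace(WorldConfig(), seed=seed, **overrides)
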