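"""Equal-angle gridding of occurrence records and incidence-matrix construction.

Occurrences are binned into cells of a global latitude/longitude grid
(5 degrees by default).  Cells use half-open intervals ``[lower, upper)`` on
both axes, with latitude +90 folded into the topmost row so that every valid
coordinate maps to exactly one cell.  Cells are identified internally by
``(row, col)`` integer indices; the human-readable label style
(``"35N130E-30N135E"`` rendered with degree signs) is presentation only.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractViolation

__all__ = [
    "GridSpec",
    "normalize_longitude",
    "IncidenceMatrix",
    "build_incidence",
    "cell_richness",
    "latitudinal_richness",
    "filter_cells",
    "grid_geojson",
]

_LABEL_RE = re.compile(
    r"^(?P<lat1>\d+(?:\.\d+)?)°(?P<h1>[NS])(?P<lon1>\d+(?:\.\d+)?)°(?P<g1>[EW])"
    r"-(?P<lat2>\d+(?:\.\d+)?)°(?P<h2>[NS])(?P<lon2>\d+(?:\.\d+)?)°(?P<g2>[EW])$"
)


def normalize_longitude(lon):
    """Map longitudes onto ``[-180, 180)``; +180 wraps to -180."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def _fmt(value: float, pos: str, neg: str) -> str:
    hemi = pos if value >= 0 else neg
    return f"{abs(value):g}°{hemi}"


@dataclass(frozen=True)
class GridSpec:
    """Global equal-angle grid with half-open cells.

    Parameters
    ----------
    cell_size : float
        Cell edge in degrees.  Must divide both 180 and 360 evenly.
    """

    cell_size: float = 5.0
    lat_origin: float = -90.0
    lon_origin: float = -180.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        for span in (180.0, 360.0):
            if abs(round(span / self.cell_size) * self.cell_size - span) > 1e-9:
                raise ConfigurationError(
                    f"cell_size {self.cell_size} does not divide {span} evenly"
                )

    @property
    def n_rows(self) -> int:
        return int(round(180.0 / self.cell_size))

    @property
    def n_cols(self) -> int:
        return int(round(360.0 / self.cell_size))

    def assign(self, latitude, longitude):
        """Vectorized cell assignment ``(lat, lon) -> (row, col)``.

        Raises :class:`ContractViolation` for out-of-range latitudes: cleaning
        must happen upstream.
        """
        lat = np.asarray(latitude, dtype=float)
        lon = np.asarray(longitude, dtype=float)
        if np.any(np.abs(lat) > 90.0):
            raise ContractViolation("latitude outside [-90, 90]; clean records first")
        if np.any(~np.isfinite(lon)):
            raise ContractViolation("non-finite longitude")
        row = np.floor((lat - self.lat_origin) / self.cell_size).astype(int)
        row = np.minimum(row, self.n_rows - 1)  # fold +90 into top row
        col = np.floor(
            (normalize_longitude(lon) - self.lon_origin) / self.cell_size
        ).astype(int)
        if lat.ndim == 0:
            return int(row), int(col)
        return row, col

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """Return ``(lat_min, lat_max, lon_min, lon_max)`` of a cell."""
        lat_min = self.lat_origin + row * self.cell_size
        lon_min = self.lon_origin + col * self.cell_size
        return lat_min, lat_min + self.cell_size, lon_min, lon_min + self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lat_min, lat_max, lon_min, lon_max = self.cell_bounds(row, col)
        return (lat_min + lat_max) / 2.0, (lon_min + lon_max) / 2.0

    def label(self, row: int, col: int) -> str:
        """Human label: top-left corner (lat-max, lon-min) then bottom-right."""
        lat_min, lat_max, lon_min, lon_max = self.cell_bounds(row, col)
        return (
            f"{_fmt(lat_max, 'N', 'S')}{_fmt(lon_min, 'E', 'W')}"
            f"-{_fmt(lat_min, 'N', 'S')}{_fmt(lon_max, 'E', 'W')}"
        )

    def parse_label(self, label: str) -> tuple[int, int]:
        m = _LABEL_RE.match(label)
        if m is None:
            raise ValueError(f"unparseable cell label: {label!r}")
        lat_min = float(m["lat2"]) * (1 if m["h2"] == "N" else -1)
        lon_min = float(m["lon1"]) * (1 if m["g1"] == "E" else -1)
        row = int(round((lat_min - self.lat_origin) / self.cell_size))
        col = int(round((lon_min - self.lon_origin) / self.cell_size))
        return row, col


@dataclass
class IncidenceMatrix:
    """Binary cell-by-taxon presence matrix.

    ``data`` is a pandas DataFrame with an index of ``(row, col)`` cell tuples
    (row-major order) and alphabetically ordered taxon columns; entries are
    0/1 ints.  ``level`` is ``"species"`` or ``"genus"``.
    """

    data: pd.DataFrame
    level: str
    grid: GridSpec = field(default_factory=GridSpec)
    occurrence_counts: pd.Series | None = None

    @property
    def cells(self) -> list[tuple[int, int]]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    def species_set(self, cell: tuple[int, int]) -> set[str]:
        rowvals = self.data.loc[[cell]].iloc[0]
        return set(rowvals.index[rowvals.to_numpy() > 0])

    def richness(self) -> pd.Series:
        return self.data.sum(axis=1)

    def cell_labels(self) -> list[str]:
        return [self.grid.label(r, c) for r, c in self.data.index]

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.index = pd.Index(self.cell_labels(), name="cell")
        out.to_csv(path)


def _taxon_names(records: pd.DataFrame, level: str) -> pd.Series:
    if level == "species":
        mask = (records["qualifier"].isin(["none"])) & (
            records["species_epithet"].astype(str) != ""
        )
        sub = records.loc[mask]
        return sub["genus"].astype(str) + " " + sub["species_epithet"].astype(str)
    if level == "genus":
        return records["genus"].astype(str)
    raise ConfigurationError(f"unknown incidence level: {level!r}")


def build_incidence(
    records: pd.DataFrame, grid: GridSpec | None = None, level: str = "species"
) -> IncidenceMatrix:
    """Build a binary incidence matrix from cleaned records.

    Genus-level (``sp``/``spp``) records are excluded from the species-level
    matrix but do count toward the genus-level one.  Cells are ordered
    row-major, taxa alphabetically; taxa that end up with no cell are dropped.
    """
    grid = grid or GridSpec()
    if len(records) == 0:
        return IncidenceMatrix(pd.DataFrame(), level, grid, pd.Series(dtype=int))
    names = _taxon_names(records, level)
    rows, cols = grid.assign(
        records["latitude"].to_numpy(), records["longitude"].to_numpy()
    )
    cell_index = pd.MultiIndex.from_arrays([rows, cols], names=["row", "col"])
    per_row = (
        records["count"].to_numpy(dtype=int)
        if "count" in records.columns
        else np.ones(len(records), dtype=int)
    )
    counts = (
        pd.Series(per_row, index=cell_index).groupby(level=[0, 1]).sum().sort_index()
    )
    counts.index = [tuple(ix) for ix in counts.index]
    sub = names.dropna()
    if len(sub) == 0:
        return IncidenceMatrix(pd.DataFrame(), level, grid, counts)
    pos = records.index.get_indexer(sub.index)
    frame = pd.DataFrame(
        {
            "cell": [
                (int(r), int(c))
                for r, c in zip(np.asarray(rows)[pos], np.asarray(cols)[pos])
            ],
            "taxon": sub.to_numpy(),
        }
    )
    pivot = (
        frame.assign(v=1)
        .pivot_table(index="cell", columns="taxon", values="v", aggfunc="max", fill_value=0)
        .astype(int)
    )
    pivot = pivot.sort_index(axis=1)
    pivot = pivot.reindex(sorted(pivot.index), axis=0)
    pivot = pivot.loc[:, pivot.sum(axis=0) > 0]
    return IncidenceMatrix(pivot, level, grid, counts)


def cell_richness(incidence: IncidenceMatrix) -> pd.Series:
    """Per-cell taxon richness (row sums of the incidence matrix)."""
    return incidence.richness()


def latitudinal_richness(
    records: pd.DataFrame, bin_width: float = 5.0, level: str = "species"
) -> pd.Series:
    """Taxon richness totalled over latitudinal bins of ``bin_width`` degrees.

    Bins are half-open ``[lower, upper)`` with +90 folded into the top bin;
    the index carries the lower bin edge.
    """
    names = _taxon_names(records, level)
    lat = records.loc[names.index, "latitude"].to_numpy(dtype=float)
    edges = np.floor((lat + 90.0) / bin_width).astype(int)
    edges = np.minimum(edges, int(round(180.0 / bin_width)) - 1)
    lower = edges * bin_width - 90.0
    out = (
        pd.DataFrame({"bin": lower, "taxon": names.to_numpy()})
        .groupby("bin")["taxon"]
        .nunique()
        .sort_index()
    )
    out.name = f"{level}_richness"
    return out


def filter_cells(incidence: IncidenceMatrix, min_species: int = 7) -> IncidenceMatrix:
    """Drop cells with richness below ``min_species`` (>= survives), re-prune taxa."""
    if min_species < 1:
        raise ConfigurationError("min_species must be >= 1")
    keep = incidence.richness() >= min_species
    data = incidence.data.loc[keep]
    data = data.loc[:, data.sum(axis=0) > 0]
    counts = (
        incidence.occurrence_counts.loc[data.index]
        if incidence.occurrence_counts is not None
        else None
    )
    return IncidenceMatrix(data, incidence.level, incidence.grid, counts)


def grid_geojson(incidence: IncidenceMatrix) -> dict:
    """GeoJSON FeatureCollection of occupied cells with richness properties."""
    richness = incidence.richness()
    features = []
    for cell in incidence.cells:
        lat_min, lat_max, lon_min, lon_max = incidence.grid.cell_bounds(*cell)
        ring = [
            [lon_min, lat_min],
            [lon_max, lat_min],
            [lon_max, lat_max],
            [lon_min, lat_max],
            [lon_min, lat_min],
        ]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "row": cell[0],
                    "col": cell[1],
                    "label": incidence.grid.label(*cell),
                    "richness": int(richness.loc[[cell]].iloc[0]),
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(incidence: IncidenceMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(grid_geojson(incidence), fh, sort_keys=True)
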