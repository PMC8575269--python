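"""Parsing, validation and cleaning of raw occurrence tables.

Implements the standard hygiene steps for literature- and aggregator-derived
marine occurrence data: open-nomenclature qualifiers (``aff.``, ``cf.``,
``indet.``) are rejected, genus-level records (``sp.``/``spp.``) are retained
but flagged, misspellings are reconciled through a synonym table, coordinates
are validated and normalized, and exact duplicate rows are collapsed with a
count rather than silently dropped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NameParseError, SchemaError
from .grid import normalize_longitude

__all__ = [
    "OccurrenceRecord",
    "SynonymTable",
    "RejectionLog",
    "dms_to_decimal",
    "parse_name",
    "standardize_name",
    "clean_records",
    "read_occurrences",
    "write_occurrences",
    "records_to_frame",
]

#: qualifiers that disqualify a record from any analysis
REJECT_QUALIFIERS = frozenset({"aff", "cf", "indet"})
#: qualifiers retained for genus-level analysis only
GENUS_QUALIFIERS = frozenset({"sp", "spp"})
ALL_QUALIFIERS = REJECT_QUALIFIERS | GENUS_QUALIFIERS

#: columns a raw occurrence table must provide
REQUIRED_COLUMNS = ("raw_name", "latitude", "longitude")

COLUMNS = [
    "raw_name",
    "genus",
    "species_epithet",
    "qualifier",
    "latitude",
    "longitude",
    "depth_m",
    "source",
    "geocoded",
    "count",
]


@dataclass
class OccurrenceRecord:
    """One cleaned (or raw) georeferenced taxon observation."""

    raw_name: str
    genus: str
    species_epithet: str
    qualifier: str
    latitude: float
    longitude: float
    depth_m: float | None = None
    source: str = ""
    geocoded: bool = False
    count: int = 1


class SynonymTable(dict):
    """Mapping of raw / invalid binomials to accepted names.

    Accepted names must be fixed points of the mapping (no chains); this is
    enforced at construction.
    """

    def __init__(self, mapping=None):
        super().__init__(mapping or {})
        for raw, accepted in self.items():
            if accepted in self and self[accepted] != accepted:
                raise SchemaError(
                    f"synonym chain: {raw!r} -> {accepted!r} -> {self[accepted]!r}"
                )

    def resolve(self, name: str) -> str:
        return self.get(name, name)

    @classmethod
    def from_csv(cls, path) -> "SynonymTable":
        frame = pd.read_csv(path)
        if not {"raw", "accepted"} <= set(frame.columns):
            raise SchemaError("synonym table needs 'raw' and 'accepted' columns")
        return cls(dict(zip(frame["raw"].astype(str), frame["accepted"].astype(str))))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["raw", "accepted"])
            for raw in sorted(self):
                writer.writerow([raw, self[raw]])


@dataclass
class RejectionLog:
    """Per-record rejection bookkeeping; kept + rejected = input."""

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "raw_name", "reason"])
    )

    def __len__(self) -> int:
        return len(self.entries)

    def reasons(self) -> pd.Series:
        return self.entries["reason"].value_counts()

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def dms_to_decimal(degrees: float, minutes: float = 0.0, seconds: float = 0.0,
                   hemisphere: str = "N") -> float:
    """Convert degree-minute-second coordinates to signed decimal degrees.

    ``S`` and ``W`` hemispheres yield negative values.
    """
    if not 0 <= minutes < 60:
        raise ValueError(f"minutes out of range: {minutes}")
    if not 0 <= seconds < 60:
        raise ValueError(f"seconds out of range: {seconds}")
    hemisphere = str(hemisphere).strip().upper()
    if hemisphere not in {"N", "S", "E", "W"}:
        raise ValueError(f"unknown hemisphere: {hemisphere!r}")
    value = abs(float(degrees)) + minutes / 60.0 + seconds / 3600.0
    return -value if hemisphere in {"S", "W"} else value


def parse_name(raw_name: str) -> tuple[str, str, str]:
    """Split a raw taxon name into ``(genus, epithet, qualifier)``.

    Qualifier tokens (aff, cf, indet, sp, spp) are detected case-insensitively
    with or without trailing periods, wherever they sit in the name.
    """
    if raw_name is None or not str(raw_name).strip():
        raise NameParseError("empty taxon name")
    tokens = str(raw_name).replace(" ", " ").split()
    qualifier = "none"
    plain: list[str] = []
    for tok in tokens:
        bare = tok.rstrip(".").lower()
        if bare in ALL_QUALIFIERS:
            qualifier = bare
        else:
            plain.append(tok.strip())
    if not plain:
        raise NameParseError(f"no genus in name: {raw_name!r}")
    genus = plain[0].strip().capitalize()
    epithet = plain[1].lower() if len(plain) > 1 else ""
    if qualifier in GENUS_QUALIFIERS:
        epithet = ""
    return genus, epithet, qualifier


def standardize_name(
    raw_name: str, synonyms: SynonymTable | None = None
) -> tuple[str, str, str]:
    """Parse a raw name and apply the synonym mapping after qualifier stripping."""
    genus, epithet, qualifier = parse_name(raw_name)
    if synonyms:
        key = f"{genus} {epithet}".strip()
        accepted = synonyms.resolve(key)
        if accepted != key:
            parts = accepted.split()
            genus = parts[0].capitalize()
            epithet = parts[1].lower() if len(parts) > 1 else ""
    return genus, epithet, qualifier


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.reset_index(drop=True).copy()
    return records_to_frame(records)


def records_to_frame(records) -> pd.DataFrame:
    """Convert an iterable of :class:`OccurrenceRecord` to the standard frame."""
    rows = []
    for rec in records:
        rows.append(
            {
                "raw_name": rec.raw_name,
                "genus": rec.genus,
                "species_epithet": rec.species_epithet,
                "qualifier": rec.qualifier,
                "latitude": rec.latitude,
                "longitude": rec.longitude,
                "depth_m": rec.depth_m,
                "source": rec.source,
                "geocoded": rec.geocoded,
                "count": rec.count,
            }
        )
    return pd.DataFrame(rows, columns=COLUMNS)


def clean_records(
    raw_records,
    synonyms: SynonymTable | None = None,
    land_mask=None,
    collapse_duplicates: bool = True,
    geocode_resolution: float = 0.5,
) -> tuple[pd.DataFrame, RejectionLog]:
    """Clean a raw occurrence table into analysis-ready records.

    Rules, in order: names are parsed and reconciled against ``synonyms``;
    records with qualifiers ``aff``/``cf``/``indet`` are rejected (reason
    ``qualifier``) while ``sp``/``spp`` are retained and flagged genus-level;
    latitudes outside [-90, 90] or longitudes outside [-180, 180] are rejected
    (``coordinate_out_of_range``); longitudes are then normalized to
    ``[-180, 180)``; geocoded records are snapped to the nearest
    ``geocode_resolution`` degrees; points strictly inside ``land_mask``
    polygons (shapely geometries, optional) are rejected (``on_land``).
    Exact duplicates (name + coordinates + source) are collapsed with a count.

    Returns the kept records and a :class:`RejectionLog`;
    ``kept rows (pre-collapse) + rejected = input rows``.
    """
    frame = _as_frame(raw_records)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if "source" not in frame.columns:
        frame["source"] = ""
    if "depth_m" not in frame.columns:
        frame["depth_m"] = np.nan
    if "geocoded" not in frame.columns:
        frame["geocoded"] = False

    rejected: list[dict] = []
    kept_rows: list[dict] = []
    for idx, row in frame.iterrows():
        raw_name = row["raw_name"]
        try:
            genus, epithet, qualifier = standardize_name(raw_name, synonyms)
        except NameParseError:
            rejected.append({"row": idx, "raw_name": raw_name, "reason": "unparseable"})
            continue
        if qualifier in REJECT_QUALIFIERS:
            rejected.append({"row": idx, "raw_name": raw_name, "reason": "qualifier"})
            continue
        try:
            lat = float(row["latitude"])
            lon = float(row["longitude"])
        except (TypeError, ValueError):
            rejected.append({"row": idx, "raw_name": raw_name, "reason": "unparseable"})
            continue
        if not np.isfinite(lat) or not np.isfinite(lon) or abs(lat) > 90 or abs(lon) > 180:
            rejected.append(
                {"row": idx, "raw_name": raw_name, "reason": "coordinate_out_of_range"}
            )
            continue
        lon = float(normalize_longitude(lon))
        geocoded = bool(row["geocoded"])
        if geocoded:
            lat = round(lat / geocode_resolution) * geocode_resolution
            lat = min(max(lat, -90.0), 90.0)
            lon = float(normalize_longitude(round(lon / geocode_resolution) * geocode_resolution))
        if land_mask is not None and _on_land(lat, lon, land_mask):
            rejected.append({"row": idx, "raw_name": raw_name, "reason": "on_land"})
            continue
        depth = row["depth_m"]
        depth = float(depth) if pd.notna(depth) else np.nan
        kept_rows.append(
            {
                "raw_name": raw_name,
                "genus": genus,
                "species_epithet": epithet,
                "qualifier": qualifier if qualifier in GENUS_QUALIFIERS else "none",
                "latitude": lat,
                "longitude": lon,
                "depth_m": depth,
                "source": str(row["source"]) if pd.notna(row["source"]) else "",
                "geocoded": geocoded,
                "count": int(row["count"]) if "count" in row and pd.notna(row.get("count")) else 1,
            }
        )
    kept = pd.DataFrame(kept_rows, columns=COLUMNS)
    log = RejectionLog(pd.DataFrame(rejected, columns=["row", "raw_name", "reason"]))
    if collapse_duplicates and len(kept):
        keys = ["genus", "species_epithet", "qualifier", "latitude", "longitude", "source"]
        kept = (
            kept.groupby(keys, as_index=False, sort=False)
            .agg(
                raw_name=("raw_name", "first"),
                depth_m=("depth_m", "first"),
                geocoded=("geocoded", "first"),
                count=("count", "sum"),
            )
            .loc[:, COLUMNS]
        )
    return kept.reset_index(drop=True), log


def _on_land(lat: float, lon: float, land_mask) -> bool:
    from shapely.geometry import Point

    point = Point(lon, lat)
    geoms = getattr(land_mask, "geoms", None)
    if geoms is None:
        geoms = land_mask if isinstance(land_mask, (list, tuple)) else [land_mask]
    return any(geom.contains(point) for geom in geoms)


def _sniff_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") > head.count(",") else ","


def read_occurrences(path) -> pd.DataFrame:
    """Read a CSV/TSV occurrence table (delimiter auto-detected, UTF-8)."""
    frame = pd.read_csv(path, sep=_sniff_delimiter(path))
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    return frame


def write_occurrences(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)
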