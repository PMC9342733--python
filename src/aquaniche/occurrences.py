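"""Occurrence-record ingestion, taxon-name suggestion, and coordinate cleaning.

The cleaning stage removes the classic contaminants of aggregated occurrence
databases before niche fitting: invalid or placeholder coordinates, records
whose coordinates contradict their country code, marine points (this is a
freshwater tool), and isolated spatial outliers. Each rejected record carries
the name of the rule that rejected it, so the partition of the input into
retained and flagged records is fully auditable.

Rules run in a fixed order (validity, zero-zero, equal lat/lon, country, sea,
outlier); a record stops at its first failing rule, and the outlier statistics
are computed on records that survived the earlier rules.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .exceptions import AdapterDisabledError, ConfigurationError
from .raster import AbioticLayer

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class OccurrenceRecord:
    species: str
    lon: float
    lat: float
    country_code: str | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def with_flag(self, flag: str) -> "OccurrenceRecord":
        return replace(self, flags=self.flags | {flag})


@dataclass(frozen=True)
class CleaningConfig:
    """Toggles for the coordinate-cleaning rules; defaults enable the full set."""

    remove_sea: bool = True
    zero_zero: bool = True
    equal_latlon: bool = True
    country_check: bool = True
    outlier: bool = True
    outlier_multiplier: float = 5.0
    #: Minimum conspecific records before the outlier rule activates.
    outlier_min_records: int = 7

    def __post_init__(self) -> None:
        if self.outlier_multiplier <= 0:
            raise ValueError("outlier_multiplier must be positive")


def damerau_levenshtein(a: str, b: str) -> int:
    """Restricted Damerau-Levenshtein (optimal string alignment) distance.

    Counts insertions, deletions, substitutions, and transpositions of
    adjacent characters; case-sensitive (callers lowercase for taxon matching).
    """
    la, lb = len(a), len(b)
    d = np.zeros((la + 1, lb + 1), dtype=np.int64)
    d[:, 0] = np.arange(la + 1)
    d[0, :] = np.arange(lb + 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i, j] = min(d[i - 1, j] + 1, d[i, j - 1] + 1, d[i - 1, j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d[i, j] = min(d[i, j], d[i - 2, j - 2] + 1)
    return int(d[la, lb])


def suggest_taxon_name(
    query: str, checklist: Sequence[str], max_distance: int = 2
) -> tuple[str, int] | None:
    """Closest checklist binomial within ``max_distance`` edits, or None.

    Matching is case-insensitive; an exact match returns distance 0. Ties are
    broken by checklist order.
    """
    if not checklist:
        raise ValueError("checklist must be non-empty")
    if not query:
        raise ValueError("query must be non-empty")
    q = query.lower()
    best: tuple[str, int] | None = None
    for name in checklist:
        dist = damerau_levenshtein(q, name.lower())
        if best is None or dist < best[1]:
            best = (name, dist)
        if dist == 0:
            break
    assert best is not None
    return best if best[1] <= max_distance else None


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km on a sphere of radius 6371 km (vectorized)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def _valid_coords(r: OccurrenceRecord) -> bool:
    return (
        isinstance(r.lon, (int, float))
        and isinstance(r.lat, (int, float))
        and math.isfinite(r.lon)
        and math.isfinite(r.lat)
        and -180.0 <= r.lon <= 180.0
        and -90.0 <= r.lat <= 90.0
    )


def _outlier_mask(records: list[OccurrenceRecord], cfg: CleaningConfig) -> np.ndarray:
    """Per-species isolated-point detection on mean pairwise great-circle distance.

    A record is an outlier when its mean distance to conspecifics exceeds
    Q3 + multiplier * IQR of the per-record mean distances. Species with fewer
    than ``outlier_min_records`` records are never flagged.
    """
    mask = np.zeros(len(records), dtype=bool)
    by_species: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_species.setdefault(r.species, []).append(i)
    for idxs in by_species.values():
        if len(idxs) < cfg.outlier_min_records:
            continue
        lons = np.array([records[i].lon for i in idxs])
        lats = np.array([records[i].lat for i in idxs])
        dists = haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
        # mean distance to the OTHER records (exclude self-distance zero)
        mean_d = dists.sum(axis=1) / (len(idxs) - 1)
        q1, q3 = np.percentile(mean_d, [25, 75])
        thr = q3 + cfg.outlier_multiplier * (q3 - q1)
        for k, i in enumerate(idxs):
            if mean_d[k] > thr:
                mask[i] = True
    return mask


def clean_occurrences(
    records: Iterable[OccurrenceRecord],
    land_mask: AbioticLayer | None = None,
    cfg: CleaningConfig | None = None,
    country_polygons: Mapping[str, object] | None = None,
) -> tuple[list[OccurrenceRecord], list[OccurrenceRecord]]:
    """Partition records into (retained, flagged) under the configured rules.

    Parameters
    ----------
    land_mask : AbioticLayer, optional
        Raster with value 0 over sea; required when ``cfg.remove_sea``.
    country_polygons : mapping of ISO-2 code to shapely geometry, optional
        When provided and ``cfg.country_check``, a record whose coordinates
        fall outside its declared country's geometry is flagged ``country``.
        Without polygons the rule is inert (no reference data to test against).

    Returns
    -------
    (retained, flagged)
        Every input record appears in exactly one list; flagged records carry
        at least one rule label. Input order is preserved within each list.
    """
    cfg = cfg or CleaningConfig()
    records = list(records)
    if cfg.remove_sea and land_mask is None:
        raise ConfigurationError("remove_sea is enabled but no land mask was provided")

    retained: list[OccurrenceRecord] = []
    flagged: list[OccurrenceRecord] = []

    def _sea(r: OccurrenceRecord) -> bool:
        v = land_mask.sample(r.lon, r.lat)  # type: ignore[union-attr]
        return v == 0.0

    def _country(r: OccurrenceRecord) -> bool:
        if not country_polygons or not r.country_code:
            return False
        geom = country_polygons.get(r.country_code.upper())
        if geom is None:
            return False
        from shapely.geometry import Point

        return not geom.covers(Point(r.lon, r.lat))

    point_rules: list[tuple[str, Callable[[OccurrenceRecord], bool], bool]] = [
        ("invalid_coords", lambda r: not _valid_coords(r), True),
        ("zero_zero", lambda r: r.lon == 0.0 and r.lat == 0.0, cfg.zero_zero),
        ("equal_latlon", lambda r: r.lon == r.lat, cfg.equal_latlon),
        ("country", _country, cfg.country_check),
        ("sea", _sea, cfg.remove_sea),
    ]

    surviving: list[OccurrenceRecord] = []
    for r in records:
        flag = None
        for name, rule, enabled in point_rules:
            if enabled and rule(r):
                flag = name
                break
        if flag is None:
            surviving.append(r)
        else:
            flagged.append(r.with_flag(flag))

    if cfg.outlier and surviving:
        outliers = _outlier_mask(surviving, cfg)
        for r, is_out in zip(surviving, outliers):
            if is_out:
                flagged.append(r.with_flag("outlier"))
            else:
                retained.append(r)
    else:
        retained = surviving

    logger.info(
        "clean_occurrences: retained %d, flagged %d of %d records",
        len(retained), len(flagged), len(records),
    )
    return retained, flagged


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def read_occurrences_csv(path: str | Path) -> list[OccurrenceRecord]:
    """Read the occurrence CSV dialect (species, decimalLongitude, decimalLatitude[, countryCode])."""
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"species", "decimalLongitude", "decimalLatitude"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"occurrence CSV must have columns {sorted(required)}")
        for row in reader:
            try:
                lon = float(row["decimalLongitude"])
                lat = float(row["decimalLatitude"])
            except (TypeError, ValueError):
                lon, lat = float("nan"), float("nan")
            records.append(
                OccurrenceRecord(
                    species=row["species"],
                    lon=lon,
                    lat=lat,
                    country_code=row.get("countryCode") or None,
                )
            )
    return records


def write_occurrences_csv(records: Iterable[OccurrenceRecord], path: str | Path) -> None:
    """Write records in the input dialect plus a semicolon-separated flags column."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "decimalLongitude", "decimalLatitude", "countryCode", "flags"])
        for r in records:
            writer.writerow([r.species, r.lon, r.lat, r.country_code or "", ";".join(sorted(r.flags))])


# ---------------------------------------------------------------------------
# Optional network adapter (never used by tests; disabled by default)
# ---------------------------------------------------------------------------

def fetch_gbif(
    species: str,
    enabled: bool = False,
    _request: Callable[[str], list[dict]] | None = None,
) -> list[OccurrenceRecord]:
    """Fetch occurrence records for a species from GBIF (optional adapter).

    Network access must be explicitly enabled; the offline pipeline reads
    occurrence CSVs instead. ``_request`` is an injection point that maps a
    species name to a list of raw record dicts (used for testing the mapping
    without any network).
    """
    if not enabled:
        raise AdapterDisabledError(
            "GBIF adapter is disabled; pass enabled=True to allow network access"
        )
    if _request is None:  # pragma: no cover - real network path
        import json
        import urllib.parse
        import urllib.request

        def _request(sp: str) -> list[dict]:
            url = (
                "https://api.gbif.org/v1/occurrence/search?limit=300&scientificName="
                + urllib.parse.quote(sp)
            )
            with urllib.request.urlopen(url, timeout=60) as resp:
                return json.load(resp).get("results", [])

    out = []
    for raw in _request(species):
        lon = raw.get("decimalLongitude")
        lat = raw.get("decimalLatitude")
        rec = OccurrenceRecord(
            species=raw.get("species", species),
            lon=float(lon) if lon is not None else float("nan"),
            lat=float(lat) if lat is not None else float("nan"),
            country_code=raw.get("countryCode"),
        )
        if lon is None or lat is None:
            rec = rec.with_flag("invalid_coords")
        out.append(rec)
    return out
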