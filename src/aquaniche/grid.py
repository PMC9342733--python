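"""Geographic discretization: extent clamping, snapping, presence gridding, raster aggregation.

All coordinates are decimal degrees in WGS84. The lattice is anchored at the
global corner (-180, -90), so for a 30-arcminute grid every cell centre has a
fractional degree part of 0.25 or 0.75 regardless of the working extent.
Cell intervals are half-open ``[boundary, boundary + resolution)`` on both
axes; extent minima are inclusive and maxima exclusive, except the global
maxima (180 degrees E, 90 degrees N) which are inclusive so the last row and
column of a world grid remain addressable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import ExtentError, FormatError

if TYPE_CHECKING:  # pragma: no cover
    from .occurrences import OccurrenceRecord
    from .raster import AbioticLayer

logger = logging.getLogger(__name__)

#: Anchor of the global lattice: cell boundaries sit at integer multiples of
#: the resolution measured from this corner.
_ANCHOR_LON = -180.0
_ANCHOR_LAT = -90.0


class CellId(NamedTuple):
    """Centre coordinates of one grid cell; uniquely identifies the cell."""

    lon_centre: float
    lat_centre: float


@dataclass(frozen=True)
class GridSpec:
    """Discretization contract: resolution, extent clamp, cell-centre convention.

    Parameters
    ----------
    resolution_arcmin : int
        Grid resolution, 10 or 30 arcminutes (~18 or ~55 km at the equator).
    lat_min, lat_max, lon_min, lon_max : float
        Working extent in degrees. The defaults clamp to 56S-60N and
        145W-180E, the joint coverage of the global environmental layers the
        tool consumes.
    """

    resolution_arcmin: int = 30
    lat_min: float = -56.0
    lat_max: float = 60.0
    lon_min: float = -145.0
    lon_max: float = 180.0

    def __post_init__(self) -> None:
        if self.resolution_arcmin not in (10, 30):
            raise ValueError(
                f"resolution_arcmin must be 10 or 30, got {self.resolution_arcmin}"
            )
        if not (self.lat_min < self.lat_max and self.lon_min < self.lon_max):
            raise ValueError("extent minima must be strictly below maxima")
        if self.lat_min < -90 or self.lat_max > 90 or self.lon_min < -180 or self.lon_max > 180:
            raise ValueError("extent must lie within [-180, 180] x [-90, 90]")

    @property
    def resolution_deg(self) -> float:
        return self.resolution_arcmin / 60.0

    def contains(self, lon: float, lat: float) -> bool:
        """Half-open extent membership; global maxima are inclusive."""
        lon_ok = self.lon_min <= lon < self.lon_max or (self.lon_max == 180.0 and lon == 180.0)
        lat_ok = self.lat_min <= lat < self.lat_max or (self.lat_max == 90.0 and lat == 90.0)
        return lon_ok and lat_ok


def _snap_axis(value: float, anchor: float, res: float) -> float:
    idx = math.floor((value - anchor) / res)
    return anchor + (idx + 0.5) * res


def snap_to_cell(lon: float, lat: float, grid: GridSpec) -> CellId:
    """Snap a point to the centre of the unique cell containing it.

    The cell is the half-open interval ``[b, b + res)`` on each axis, with
    boundaries at multiples of the resolution from (-180, -90).

    Raises
    ------
    ExtentError
        If the point falls outside the grid extent.
    """
    if not grid.contains(lon, lat):
        raise ExtentError(
            f"point (lon={lon}, lat={lat}) outside grid extent "
            f"[{grid.lon_min}, {grid.lon_max}] x [{grid.lat_min}, {grid.lat_max}]"
        )
    res = grid.resolution_deg
    # Points exactly on the inclusive global maxima belong to the last cell.
    lon_eff = min(lon, 180.0 - res / 2) if lon == 180.0 else lon
    lat_eff = min(lat, 90.0 - res / 2) if lat == 90.0 else lat
    return CellId(
        lon_centre=round(_snap_axis(lon_eff, _ANCHOR_LON, res), 10),
        lat_centre=round(_snap_axis(lat_eff, _ANCHOR_LAT, res), 10),
    )


def snap_area_to_cell(
    lat_range: Sequence[float], lon_range: Sequence[float], grid: GridSpec
) -> CellId:
    """Snap a rectangular area to a single cell via its centroid.

    The centroid (midpoint of each range) is snapped with :func:`snap_to_cell`;
    an area spanning several cells therefore resolves to the cell holding its
    centre of mass.
    """
    lat_lo, lat_hi = lat_range
    lon_lo, lon_hi = lon_range
    if not (lat_lo < lat_hi and lon_lo < lon_hi):
        raise ValueError("area ranges must be non-degenerate and ordered (min, max)")
    return snap_to_cell((lon_lo + lon_hi) / 2.0, (lat_lo + lat_hi) / 2.0, grid)


def clamp_extent(
    records: Iterable["OccurrenceRecord"], grid: GridSpec
) -> list["OccurrenceRecord"]:
    """Drop occurrence records outside the grid extent; log how many were removed."""
    records = list(records)
    kept = [r for r in records if grid.contains(r.lon, r.lat)]
    removed = len(records) - len(kept)
    if removed:
        logger.info("clamp_extent: removed %d of %d records outside extent", removed, len(records))
    return kept


def grid_presences(records: Iterable["OccurrenceRecord"], grid: GridSpec) -> pd.DataFrame:
    """Collapse occurrence records to one presence row per (species, cell).

    Returns a presence table with columns ``species, lon_centre, lat_centre``
    (absence is implicit by omission). Presence/absence recording per cell
    neutralizes uneven sampling effort across regions.
    """
    rows = []
    for r in records:
        cell = snap_to_cell(r.lon, r.lat, grid)
        rows.append((r.species, cell.lon_centre, cell.lat_centre))
    table = pd.DataFrame(rows, columns=["species", "lon_centre", "lat_centre"])
    table = table.drop_duplicates(ignore_index=True)
    return table


def cell_indices(lons: np.ndarray, lats: np.ndarray, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized lattice indices (i_lon, i_lat) for arrays of coordinates."""
    res = grid.resolution_deg
    i_lon = np.floor((np.asarray(lons) - _ANCHOR_LON) / res).astype(np.int64)
    i_lat = np.floor((np.asarray(lats) - _ANCHOR_LAT) / res).astype(np.int64)
    return i_lon, i_lat


def aggregate_raster(
    layer: "AbioticLayer",
    grid: GridSpec,
    cells: Sequence[CellId] | None = None,
) -> pd.Series:
    """Mean of non-missing source pixels per grid cell, by pixel-centre membership.

    A pixel belongs to the cell whose half-open interval contains its centre;
    no area-weighting is applied. Cells with zero valid pixels are missing
    (NaN). When ``cells`` is given, only those cells are returned (in order);
    otherwise every cell touched by the raster within the extent is returned.

    Raises
    ------
    FormatError
        If the raster is not in WGS84 or is coarser than the grid.
    """
    if layer.crs_epsg != 4326:
        raise FormatError(f"raster CRS EPSG:{layer.crs_epsg} is not WGS84 (EPSG:4326)")
    if layer.pixel_deg > grid.resolution_deg + 1e-12:
        raise FormatError(
            f"raster pixel size {layer.pixel_deg} deg coarser than grid "
            f"resolution {grid.resolution_deg} deg"
        )
    lon_c, lat_c = np.meshgrid(layer.lon_centres, layer.lat_centres)
    values = layer.values.astype(float)
    valid = ~np.isnan(values)
    if layer.nodata is not None:
        valid &= values != layer.nodata

    i_lon, i_lat = cell_indices(lon_c.ravel(), lat_c.ravel(), grid)
    res = grid.resolution_deg
    centre_lon = np.round(_ANCHOR_LON + (i_lon + 0.5) * res, 10)
    centre_lat = np.round(_ANCHOR_LAT + (i_lat + 0.5) * res, 10)

    df = pd.DataFrame(
        {
            "lon_centre": centre_lon,
            "lat_centre": centre_lat,
            "value": values.ravel(),
            "valid": valid.ravel(),
        }
    )
    df = df[df["valid"]]
    means = df.groupby(["lon_centre", "lat_centre"])["value"].mean()

    if cells is None:
        in_extent = [
            (lo, la) for lo, la in means.index if grid.contains(lo, la)
        ]
        return means.loc[in_extent]
    idx = pd.MultiIndex.from_tuples(
        [(c.lon_centre, c.lat_centre) for c in cells], names=["lon_centre", "lat_centre"]
    )
    return means.reindex(idx)
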