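"""Abiotic variable catalog, photoperiod model, and per-cell environment matrix.

The catalog holds the 19 abiotic variables the tool considers for freshwater
aquaculture: 16 sourced from global raster layers (temperature, precipitation,
soil pH, slope, solar radiation, vapor pressure, elevation, river flow) and 3
photoperiod summaries computed from latitude alone. Units are kept exactly as
the source layers deliver them (e.g. degC*10); the niche stage standardizes,
so rescaling here would be redundant and would break bit-parity with the
source rasters.

Day length uses the CBM (Forsythe et al.) closed-form photoperiod model with
daylength coefficient p = 0.8333 degrees, i.e. sunrise/sunset when the top of
the solar disk is apparently level with the horizon, including refraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError
from .grid import CellId, GridSpec, aggregate_raster
from .raster import AbioticLayer

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AbioticVariable:
    id: str
    name: str
    unit: str
    source_kind: str  # "raster" | "computed"


#: Fixed catalog order; all environment matrices use exactly these columns.
CATALOG: tuple[AbioticVariable, ...] = (
    AbioticVariable("annual_mean_temp", "Annual upstream air temperature", "degC*10", "raster"),
    AbioticVariable("max_temp_warmest_month", "Maximum air temperature of the warmest month", "degC*10", "raster"),
    AbioticVariable("min_temp_coldest_month", "Minimum air temperature of the coldest month", "degC*10", "raster"),
    AbioticVariable("temp_annual_range", "Upstream air temperature annual range", "degC*10", "raster"),
    AbioticVariable("mean_temp_driest_quarter", "Mean air temperature of the driest quarter", "degC*10", "raster"),
    AbioticVariable("soil_ph", "pH of the soil", "pH*10", "raster"),
    AbioticVariable("annual_precipitation", "Annual upstream precipitation", "mm", "raster"),
    AbioticVariable("precipitation_wettest_month", "Upstream precipitation of wettest month", "mm", "raster"),
    AbioticVariable("precipitation_driest_month", "Upstream precipitation of driest month", "mm", "raster"),
    AbioticVariable("slope_avg", "Slope average", "[deg]*100", "raster"),
    AbioticVariable("solar_radiation", "Annual average solar radiation", "kJ.m-2.day-1", "raster"),
    AbioticVariable("vapor_pressure", "Annual average water vapor pressure", "kPa", "raster"),
    AbioticVariable("daylength_min", "Minimum daylength", "hours", "computed"),
    AbioticVariable("daylength_max", "Maximum daylength", "hours", "computed"),
    AbioticVariable("daylength_range", "Daylength range", "hours", "computed"),
    AbioticVariable("elevation_avg", "Average elevation", "m", "raster"),
    AbioticVariable("flow_avg", "Average annual flow", "m3.s-1", "raster"),
    AbioticVariable("flow_max", "Maximum annual flow", "m3.s-1", "raster"),
    AbioticVariable("flow_min", "Minimum annual flow", "m3.s-1", "raster"),
)

VARIABLE_IDS: tuple[str, ...] = tuple(v.id for v in CATALOG)
RASTER_VARIABLE_IDS: tuple[str, ...] = tuple(v.id for v in CATALOG if v.source_kind == "raster")
COMPUTED_VARIABLE_IDS: tuple[str, ...] = tuple(v.id for v in CATALOG if v.source_kind == "computed")

#: CBM daylength coefficient in degrees: apparent sunrise/sunset including
#: atmospheric refraction (the cited photoperiod package's default).
DAYLENGTH_P = 0.8333


def daylength(lat: float, day_of_year: int) -> float:
    """Day length in hours from latitude and day of year (CBM model).

    Polar day and night are handled by clamping the hour-angle cosine to
    [-1, 1], yielding exactly 24 h and 0 h respectively.
    """
    if not 1 <= day_of_year <= 365:
        raise ValueError(f"day_of_year must be in 1..365, got {day_of_year}")
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} outside [-90, 90]")
    theta = 0.2163108 + 2.0 * math.atan(0.9671396 * math.tan(0.00860 * (day_of_year - 186)))
    phi = math.asin(0.39795 * math.cos(theta))  # solar declination, radians
    lat_r = math.radians(lat)
    num = math.sin(math.radians(DAYLENGTH_P)) + math.sin(lat_r) * math.sin(phi)
    den = math.cos(lat_r) * math.cos(phi)
    x = num / den if den != 0.0 else math.copysign(math.inf, num)
    x = min(1.0, max(-1.0, x))
    return 24.0 - (24.0 / math.pi) * math.acos(x)


def daylength_summary(lat: float) -> tuple[float, float, float]:
    """(min, max, range) of daily day length over a 365-day year at a latitude."""
    days = [daylength(lat, d) for d in range(1, 366)]
    lo, hi = min(days), max(days)
    return lo, hi, hi - lo


def build_env_matrix(
    presences: pd.DataFrame,
    layers: Iterable[AbioticLayer],
    grid: GridSpec,
) -> "EnvMatrix":
    """Assemble the per-cell abiotic matrix for one species.

    Raster variables are the per-cell means of source pixels
    (:func:`~aquaniche.grid.aggregate_raster`); the photoperiod variables are
    evaluated at each cell's centre latitude and attributed to the whole cell.
    Rows (cells) with any missing raster value are dropped and the drop count
    logged — there is no imputation.
    """
    species = presences["species"].unique()
    if len(species) != 1:
        raise DataError(f"expected presences of a single species, got {list(species)}")
    if presences.empty:
        raise DataError("presence table is empty")
    layer_map = {l.variable_id: l for l in layers}
    missing = [v for v in RASTER_VARIABLE_IDS if v not in layer_map]
    if missing:
        raise ConfigurationError(f"no layer provided for raster variables: {missing}")

    cells = [CellId(lo, la) for lo, la in zip(presences["lon_centre"], presences["lat_centre"])]
    data = pd.DataFrame(
        {
            "lon_centre": presences["lon_centre"].to_numpy(),
            "lat_centre": presences["lat_centre"].to_numpy(),
        }
    )
    for vid in RASTER_VARIABLE_IDS:
        data[vid] = aggregate_raster(layer_map[vid], grid, cells=cells).to_numpy()

    dl = np.array([daylength_summary(la) for la in data["lat_centre"]])
    data["daylength_min"] = dl[:, 0]
    data["daylength_max"] = dl[:, 1]
    data["daylength_range"] = dl[:, 2]
    data = data[["lon_centre", "lat_centre", *VARIABLE_IDS]]

    complete = data[list(VARIABLE_IDS)].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "build_env_matrix(%s): dropped %d of %d cells with missing abiotic data",
            species[0], n_dropped, len(data),
        )
    return EnvMatrix(species=str(species[0]), data=data[complete].reset_index(drop=True), n_dropped=n_dropped)


@dataclass
class EnvMatrix:
    """Per-presence-cell values of the catalog variables for one species."""

    species: str
    data: pd.DataFrame  # columns: lon_centre, lat_centre, then VARIABLE_IDS
    n_dropped: int = 0

    @property
    def values(self) -> np.ndarray:
        return self.data[list(VARIABLE_IDS)].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "species", self.species)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EnvMatrix":
        df = pd.read_csv(path)
        species = df["species"].unique()
        if len(species) != 1:
            raise DataError("environment matrix CSV must contain a single species")
        return cls(species=str(species[0]), data=df.drop(columns=["species"]))


def site_environment(
    cell: CellId,
    layers: Iterable[AbioticLayer],
    grid: GridSpec,
) -> dict[str, float]:
    """Abiotic vector for one cell, extracted exactly as for presence cells.

    Raises
    ------
    DataError
        If any raster variable is missing over the cell.
    """
    presences = pd.DataFrame(
        {"species": ["_site"], "lon_centre": [cell.lon_centre], "lat_centre": [cell.lat_centre]}
    )
    env = build_env_matrix(presences, layers, grid)
    if len(env) == 0:
        raise DataError(f"cell {cell} has missing abiotic data in at least one layer")
    row = env.data.iloc[0]
    return {vid: float(row[vid]) for vid in VARIABLE_IDS}


def validate_direct_values(values: Mapping[str, float]) -> dict[str, float]:
    """Check a user-supplied variable->value mapping covers the full catalog."""
    missing = [v for v in VARIABLE_IDS if v not in values]
    if missing:
        raise ValueError(f"direct site query is missing variables: {missing}")
    return {v: float(values[v]) for v in VARIABLE_IDS}
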