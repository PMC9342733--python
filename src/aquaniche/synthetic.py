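"""Synthetic rasters, land masks, and occurrence clouds with known ground truth.

Everything downstream of data download can be exercised offline: rasters are
simple deterministic fields (constants, gradients, sinusoids), and occurrence
records are drawn from explicit niches (boxes or Gaussians in raw variable
units) over those rasters. Because the true niche is known by construction,
recovery of the niche boundary, inclusion verdicts, and intersection volumes
can all be checked against ground truth. The fields are contract-exercising,
not Earth-mimicking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .environment import (
    RASTER_VARIABLE_IDS,
    VARIABLE_IDS,
    EnvMatrix,
    build_env_matrix,
)
from .exceptions import DataError
from .grid import CellId, GridSpec, aggregate_raster
from .niche import derive_seed
from .occurrences import OccurrenceRecord
from .raster import AbioticLayer

# Field spec forms: ("constant", v) | ("gradient_lon", slope, intercept)
# | ("gradient_lat", slope, intercept) | ("sinusoidal", amplitude, period_deg, offset)
FieldSpec = tuple


@dataclass(frozen=True)
class NicheSpec:
    """A known niche in raw variable units: box bounds or Gaussian (mean, sd)."""

    species: str
    kind: str  # "box" | "gaussian"
    #: box: variable -> (lo, hi); gaussian: variable -> (mean, sd)
    params: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("box", "gaussian"):
            raise ValueError(f"unknown niche kind {self.kind!r}")
        for var, (a, b) in self.params.items():
            if self.kind == "box" and a > b:
                raise ValueError(f"box bounds for {var} must be ordered")
            if self.kind == "gaussian" and b <= 0:
                raise ValueError(f"gaussian sd for {var} must be positive")


def _field_values(spec: FieldSpec, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    kind = spec[0]
    if kind == "constant":
        return np.full_like(lon, float(spec[1]))
    if kind == "gradient_lon":
        return spec[1] * lon + spec[2]
    if kind == "gradient_lat":
        return spec[1] * lat + spec[2]
    if kind == "sinusoidal":
        amplitude, period, offset = spec[1], spec[2], spec[3]
        return offset + amplitude * np.sin(2 * np.pi * lon / period)
    raise ValueError(f"unknown field spec kind {kind!r}")


def default_field_specs() -> dict[str, FieldSpec]:
    """A full raster-variable spec set: constants at plausible magnitudes."""
    defaults = {
        "annual_mean_temp": ("constant", 150.0),
        "max_temp_warmest_month": ("constant", 280.0),
        "min_temp_coldest_month": ("constant", 20.0),
        "temp_annual_range": ("constant", 260.0),
        "mean_temp_driest_quarter": ("constant", 120.0),
        "soil_ph": ("constant", 65.0),
        "annual_precipitation": ("constant", 900.0),
        "precipitation_wettest_month": ("constant", 180.0),
        "precipitation_driest_month": ("constant", 20.0),
        "slope_avg": ("constant", 150.0),
        "solar_radiation": ("constant", 15000.0),
        "vapor_pressure": ("constant", 1.2),
        "elevation_avg": ("constant", 300.0),
        "flow_avg": ("constant", 50.0),
        "flow_max": ("constant", 120.0),
        "flow_min": ("constant", 10.0),
    }
    assert set(defaults) == set(RASTER_VARIABLE_IDS)
    return defaults


def make_rasters(
    grid: GridSpec,
    pixel_arcmin: float,
    field_specs: Mapping[str, FieldSpec] | None = None,
    seed: int = 0,
    sea_fraction: float = 0.0,
) -> tuple[list[AbioticLayer], AbioticLayer]:
    """Deterministic rasters for every raster variable, plus a land mask.

    Pixels are ``pixel_arcmin`` wide (must be finer than the grid) and cover
    the grid extent exactly. The land mask assigns sea (value 0) to a random
    ``sea_fraction`` of pixels, drawn from the seed.
    """
    if pixel_arcmin >= grid.resolution_arcmin:
        raise ValueError("raster pixels must be finer than the grid resolution")
    specs = dict(default_field_specs())
    if field_specs:
        unknown = set(field_specs) - set(RASTER_VARIABLE_IDS)
        if unknown:
            raise ValueError(f"field specs for non-raster variables: {sorted(unknown)}")
        specs.update(field_specs)

    px = pixel_arcmin / 60.0
    ncols = int(round((grid.lon_max - grid.lon_min) / px))
    nrows = int(round((grid.lat_max - grid.lat_min) / px))
    lon_c = grid.lon_min + (np.arange(ncols) + 0.5) * px
    lat_c = grid.lat_max - (np.arange(nrows) + 0.5) * px
    lon_g, lat_g = np.meshgrid(lon_c, lat_c)

    layers = [
        AbioticLayer(
            variable_id=vid,
            values=_field_values(specs[vid], lon_g, lat_g),
            lon_min=grid.lon_min,
            lat_max=grid.lat_max,
            pixel_deg=px,
            nodata=-9999.0,
        )
        for vid in RASTER_VARIABLE_IDS
    ]

    rng = np.random.default_rng(derive_seed(seed, "land_mask"))
    land = (rng.uniform(size=(nrows, ncols)) >= sea_fraction).astype(float)
    mask = AbioticLayer(
        variable_id="land_mask", values=land, lon_min=grid.lon_min,
        lat_max=grid.lat_max, pixel_deg=px, nodata=None,
    )
    return layers, mask


def _all_cells(grid: GridSpec) -> list[CellId]:
    res = grid.resolution_deg
    lons = np.arange(grid.lon_min + res / 2, grid.lon_max, res)
    lats = np.arange(grid.lat_min + res / 2, grid.lat_max, res)
    return [CellId(round(lo, 10), round(la, 10)) for la in lats for lo in lons]


def cell_environments(
    layers: Sequence[AbioticLayer], grid: GridSpec, land_mask: AbioticLayer | None = None
) -> pd.DataFrame:
    """Abiotic vectors of every (land) cell in the extent; used for niche sampling."""
    cells = _all_cells(grid)
    if land_mask is not None:
        land_frac = aggregate_raster(land_mask, grid, cells=cells)
        cells = [c for c, f in zip(cells, land_frac) if f == 1.0]
    if not cells:
        raise DataError("no land cells in the extent")
    presences = pd.DataFrame(
        {
            "species": "_all",
            "lon_centre": [c.lon_centre for c in cells],
            "lat_centre": [c.lat_centre for c in cells],
        }
    )
    return build_env_matrix(presences, layers, grid).data


def make_occurrences(
    niche: NicheSpec,
    layers: Sequence[AbioticLayer],
    grid: GridSpec,
    n: int,
    seed: int = 0,
    land_mask: AbioticLayer | None = None,
    cell_env: pd.DataFrame | None = None,
) -> list[OccurrenceRecord]:
    """Draw n occurrence records from cells satisfying a known niche.

    Box niches accept a cell iff every bounded variable lies inside its
    bounds; Gaussian niches weight cells by the product of per-variable
    normal densities. Cells are drawn with replacement and each record is
    jittered uniformly within its cell, so presence gridding recovers exactly
    the sampled cells. The cell-choice stream depends only on the seed; the
    jitter stream also depends on the species name.
    """
    env = cell_env if cell_env is not None else cell_environments(layers, grid, land_mask)
    values = env[list(VARIABLE_IDS)]

    if niche.kind == "box":
        ok = np.ones(len(env), dtype=bool)
        for var, (lo, hi) in niche.params.items():
            ok &= (values[var] >= lo).to_numpy() & (values[var] <= hi).to_numpy()
        weights = ok.astype(float)
    else:
        weights = np.ones(len(env))
        for var, (mu, sd) in niche.params.items():
            z = (values[var].to_numpy() - mu) / sd
            weights *= np.exp(-0.5 * z**2)
    if weights.sum() == 0:
        raise DataError(f"no grid cell satisfies the niche of {niche.species}")
    weights = weights / weights.sum()

    cell_rng = np.random.default_rng(derive_seed(seed, "cells"))
    jitter_rng = np.random.default_rng(derive_seed(seed, "jitter", niche.species))
    idx = cell_rng.choice(len(env), size=n, replace=True, p=weights)
    half = grid.resolution_deg / 2.0
    records = []
    for i in idx:
        lon_c = float(env["lon_centre"].iloc[i])
        lat_c = float(env["lat_centre"].iloc[i])
        # strict interior jitter keeps the record inside the half-open cell
        dlon, dlat = jitter_rng.uniform(-half, half, size=2) * 0.999
        records.append(OccurrenceRecord(species=niche.species, lon=lon_c + dlon, lat=lat_c + dlat))
    return records


def inject_contamination(
    records: Sequence[OccurrenceRecord],
    grid: GridSpec,
    fraction: float = 0.05,
    seed: int = 0,
    sea_points: Sequence[tuple[float, float]] = (),
) -> tuple[list[OccurrenceRecord], pd.DataFrame]:
    """Append known-bad records for cleaning tests; returns (records, labels).

    Injects (0, 0) placeholder points, optional sea points at the given
    coordinates, and one far-away outlier per species. The label table names
    the expected flag of every injected record (clean records get "").
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    rng = np.random.default_rng(derive_seed(seed, "contamination"))
    out = list(records)
    labels = [""] * len(records)
    species = sorted({r.species for r in records})
    n_zero = max(1, int(fraction * len(records)) - len(sea_points) - len(species))
    for _ in range(n_zero):
        out.append(OccurrenceRecord(species=str(rng.choice(species)), lon=0.0, lat=0.0))
        labels.append("zero_zero")
    for lon, lat in sea_points:
        out.append(OccurrenceRecord(species=str(rng.choice(species)), lon=lon, lat=lat))
        labels.append("sea")
    for sp in species:
        mine = [r for r in records if r.species == sp]
        mean_lon = float(np.mean([r.lon for r in mine]))
        # ~180 degrees away: several thousand km from any clustered cloud
        far_lon = ((mean_lon + 180.0 + 180.0) % 360.0) - 180.0
        far_lat = min(grid.lat_max - 1.0, 55.0)
        out.append(OccurrenceRecord(species=sp, lon=far_lon, lat=far_lat))
        labels.append("outlier")
    label_df = pd.DataFrame(
        {
            "species": [r.species for r in out],
            "lon": [r.lon for r in out],
            "lat": [r.lat for r in out],
            "expected_flag": labels,
        }
    )
    return out, label_df


# ---------------------------------------------------------------------------
# Canonical two-species overlapping-box fixture
# ---------------------------------------------------------------------------

@dataclass
class TwoSpeciesFixture:
    """Two box-niche species with a known geographic/abiotic overlap band."""

    grid: GridSpec
    layers: list[AbioticLayer]
    land_mask: AbioticLayer
    niches: tuple[NicheSpec, NicheSpec]
    matrices: list[EnvMatrix]
    inside_site: tuple[float, float]   # (lon, lat) inside the overlap
    outside_site: tuple[float, float]  # (lon, lat) outside both niches


def two_species_fixture(seed: int = 0, n_records: int = 400) -> TwoSpeciesFixture:
    """Build the standard overlapping-box test world.

    Extent lon 0-20, lat 0-15 at 30 arcmin. Temperature and precipitation
    increase linearly with longitude, elevation with latitude; all other
    raster fields are constant. Species A tolerates temperatures placing it in
    lon [1, 8], species B in lon [6, 13]; the analytic overlap is the lon
    [6, 8] band. The inside site sits at the overlap centre, the outside site
    near lon 18, outside both niches.
    """
    from .grid import grid_presences

    grid = GridSpec(resolution_arcmin=30, lat_min=0.0, lat_max=15.0, lon_min=0.0, lon_max=20.0)
    field_specs = {
        "annual_mean_temp": ("gradient_lon", 10.0, 100.0),       # 100..300
        "annual_precipitation": ("gradient_lon", 40.0, 500.0),   # 500..1300
        "elevation_avg": ("gradient_lat", 60.0, 0.0),            # 0..900
    }
    layers, mask = make_rasters(grid, pixel_arcmin=10, field_specs=field_specs, seed=seed)

    # temp = 100 + 10*lon  =>  lon in [1, 8] <-> temp in [110, 180]
    niche_a = NicheSpec("Species alpha", "box", {"annual_mean_temp": (110.0, 180.0)})
    niche_b = NicheSpec("Species beta", "box", {"annual_mean_temp": (160.0, 230.0)})

    env = cell_environments(layers, grid, mask)
    matrices = []
    for niche in (niche_a, niche_b):
        recs = make_occurrences(
            niche, layers, grid, n=n_records,
            seed=derive_seed(seed, "occ", niche.species), cell_env=env,
        )
        presences = grid_presences(recs, grid)
        matrices.append(build_env_matrix(presences, layers, grid))

    return TwoSpeciesFixture(
        grid=grid, layers=layers, land_mask=mask,
        niches=(niche_a, niche_b), matrices=matrices,
        inside_site=(7.25, 7.25), outside_site=(18.25, 7.25),
    )
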