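"""User-facing workflows: site suitability, polyculture ranking, density profiles.

These functions answer the practical questions: can this species be farmed at
this site (site abiotic vector inside its niche hypervolume), which species
combinations share abiotic space (non-null intersection, ranked by volume),
and what conditions are commonly observed across the species of interest
(per-variable density profiles with modes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .environment import (
    CATALOG,
    VARIABLE_IDS,
    EnvMatrix,
    site_environment,
    validate_direct_values,
)
from .exceptions import DataError
from .grid import CellId, GridSpec, snap_area_to_cell, snap_to_cell
from .model import NicheSuitabilityModel, NicheSuitabilityResults
from .raster import AbioticLayer


# ---------------------------------------------------------------------------
# Site queries and suitability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteQuery:
    """A farming-site query: a location (point or area) or direct variable values.

    Direct values describe a regulated farming system (e.g. heated water)
    whose conditions differ from the local environment; they must cover the
    full variable catalog.
    """

    mode: str  # "location" | "direct"
    lon: float | None = None
    lat: float | None = None
    lat_range: tuple[float, float] | None = None
    lon_range: tuple[float, float] | None = None
    values: Mapping[str, float] | None = None

    @classmethod
    def at_point(cls, lon: float, lat: float) -> "SiteQuery":
        return cls(mode="location", lon=lon, lat=lat)

    @classmethod
    def in_area(cls, lat_range: Sequence[float], lon_range: Sequence[float]) -> "SiteQuery":
        return cls(mode="location", lat_range=tuple(lat_range), lon_range=tuple(lon_range))

    @classmethod
    def from_values(cls, values: Mapping[str, float]) -> "SiteQuery":
        return cls(mode="direct", values=dict(values))

    def resolve_cell(self, grid: GridSpec) -> CellId:
        if self.mode != "location":
            raise ValueError("direct-mode queries have no location to snap")
        if self.lat_range is not None and self.lon_range is not None:
            return snap_area_to_cell(self.lat_range, self.lon_range, grid)
        if self.lon is None or self.lat is None:
            raise ValueError("location query needs a point or an area")
        return snap_to_cell(self.lon, self.lat, grid)


@dataclass
class SuitabilityReport:
    """Per-species and intersection inclusion verdicts for one site."""

    site: SiteQuery
    cell: CellId | None
    site_values: dict[str, float]
    projection: np.ndarray
    species_verdicts: dict[str, bool]
    intersection_verdict: bool | None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"species": sp, "included": ok} for sp, ok in self.species_verdicts.items()
        ]
        if self.intersection_verdict is not None:
            rows.append({"species": "<intersection>", "included": self.intersection_verdict})
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.site.mode,
                "cell": list(self.cell) if self.cell else None,
                "site_values": self.site_values,
                "projection": [float(x) for x in self.projection],
                "species": {k: bool(v) for k, v in self.species_verdicts.items()},
                "intersection": self.intersection_verdict,
            },
            indent=2,
        )


def assess_site(
    query: SiteQuery,
    results: NicheSuitabilityResults,
    layers: Iterable[AbioticLayer] | None = None,
    grid: GridSpec | None = None,
) -> SuitabilityReport:
    """Test whether a site falls inside each species' niche and their intersection.

    Location mode snaps the query to a grid cell and extracts its abiotic
    vector exactly as presence cells were extracted (raster means plus
    photoperiod at the cell centre); direct mode uses the supplied values.
    The intersection verdict is the logical AND of the member-wise inclusion
    tests, so it can never be true while a per-species verdict is false.
    """
    cell = None
    if query.mode == "direct":
        values = validate_direct_values(query.values or {})
    else:
        if layers is None or grid is None:
            raise ValueError("location-mode assessment requires layers and a grid")
        cell = query.resolve_cell(grid)
        values = site_environment(cell, layers, grid)

    point = results.project_values(values)
    verdicts = {
        sp: results.hypervolumes[sp].includes(point) for sp in results.species
    }
    inter_verdict = all(verdicts.values()) if len(verdicts) >= 2 else None
    return SuitabilityReport(
        site=query, cell=cell, site_values=values, projection=point,
        species_verdicts=verdicts, intersection_verdict=inter_verdict,
    )


# ---------------------------------------------------------------------------
# Polyculture combination ranking
# ---------------------------------------------------------------------------

@dataclass
class CombinationRanking:
    """Species combinations ranked by intersection hypervolume (descending).

    ``feasible`` means a non-null intersection: the combination shares some
    abiotic space. Larger volumes indicate co-farming remains possible across
    a wider range of conditions. Ties are broken lexicographically on the
    joined species names; skipped combinations (too little data) are listed
    with the reason instead of being dropped silently.
    """

    table: pd.DataFrame  # columns: species (tuple), volume, volume_se, feasible
    skipped: list[tuple[tuple[str, ...], str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["species"] = out["species"].map(lambda t: " + ".join(t))
        return out


MAX_RANKING_SPECIES = 20


def rank_combinations(
    env_matrices: Sequence[EnvMatrix],
    sizes: Iterable[int] | None = None,
    nu: float = 0.01,
    gamma: float = 0.5,
    n_mc_samples: int = 10_000,
    box_margin: float = 0.5,
    seed: int = 0,
    allow_large: bool = False,
) -> CombinationRanking:
    """Enumerate species subsets and rank them by intersection volume.

    Each subset is refitted in its own pooled PCA space (intersection is only
    defined within one shared reduced space), then the members' hypervolumes
    are intersected. ``sizes`` defaults to pairs through the full set.
    """
    matrices = {m.species: m for m in env_matrices}
    names = sorted(matrices)
    if len(names) < 2:
        raise DataError("ranking needs at least two species")
    if len(names) > MAX_RANKING_SPECIES and not allow_large:
        raise DataError(
            f"{len(names)} species exceeds the {MAX_RANKING_SPECIES}-species guardrail; "
            "pass allow_large=True to override"
        )
    sizes = sorted(set(sizes)) if sizes is not None else list(range(2, len(names) + 1))
    if any(s < 2 or s > len(names) for s in sizes):
        raise ValueError(f"sizes must lie in 2..{len(names)}")

    rows = []
    skipped: list[tuple[tuple[str, ...], str]] = []
    for size in sizes:
        for combo in combinations(names, size):
            try:
                model = NicheSuitabilityModel(
                    [matrices[s] for s in combo],
                    nu=nu, gamma=gamma, n_mc_samples=n_mc_samples,
                    box_margin=box_margin, seed=seed,
                )
                res = model.fit()
                inter = res.intersection()
            except DataError as exc:
                skipped.append((combo, str(exc)))
                continue
            rows.append(
                {
                    "species": combo,
                    "volume": inter.volume,
                    "volume_se": inter.volume_se,
                    "feasible": inter.volume > 0.0,
                }
            )
    table = pd.DataFrame(rows, columns=["species", "volume", "volume_se", "feasible"])
    table["_tie"] = table["species"].map(lambda t: " + ".join(t))
    table = (
        table.sort_values(["volume", "_tie"], ascending=[False, True])
        .drop(columns="_tie")
        .reset_index(drop=True)
    )
    return CombinationRanking(table=table, skipped=skipped)


# ---------------------------------------------------------------------------
# Density profiles of commonly observed conditions
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Per-species density curves of one abiotic variable on a shared grid."""

    variable_id: str
    grid: np.ndarray
    curves: dict[str, np.ndarray]        # species -> density values
    modes: dict[str, float]              # species -> argmax of density
    degenerate: dict[str, bool]          # species -> zero-variance flag


def density_profiles(
    matrices: Sequence[EnvMatrix],
    variables: Sequence[str] | None = None,
    grid_size: int = 256,
) -> list[DensityProfile]:
    """Gaussian-KDE density of each variable per species, on a pooled grid.

    Densities are computed on the raw (unstandardized) values — the point is
    to read off actual rearing conditions. The evaluation grid spans the
    pooled range of all species, expanded by 10% on each side; the bandwidth
    is Silverman's rule. A zero-variance sample is flagged degenerate and its
    point mass reported as the mode.
    """
    if not matrices:
        raise DataError("at least one environment matrix is required")
    variables = list(variables) if variables is not None else list(VARIABLE_IDS)
    unknown = set(variables) - set(VARIABLE_IDS)
    if unknown:
        raise ValueError(f"unknown variables: {sorted(unknown)}")

    profiles = []
    for vid in variables:
        pooled = np.concatenate([m.data[vid].to_numpy(dtype=float) for m in matrices])
        lo, hi = float(np.min(pooled)), float(np.max(pooled))
        span = hi - lo
        kdes = {}
        max_bw = 0.0
        for m in matrices:
            x = m.data[vid].to_numpy(dtype=float)
            if np.std(x) > 0.0 and len(x) >= 2:
                kdes[m.species] = gaussian_kde(x, bw_method="silverman")
                max_bw = max(max_bw, float(np.sqrt(kdes[m.species].covariance[0, 0])))
        # pad at least 10% of the pooled span, and enough bandwidths that the
        # curves integrate to ~1 over the evaluation grid
        pad = max(0.1 * span if span > 0 else max(1.0, abs(lo)) * 0.1, 4.0 * max_bw)
        grid = np.linspace(lo - pad, hi + pad, grid_size)
        curves: dict[str, np.ndarray] = {}
        modes: dict[str, float] = {}
        degenerate: dict[str, bool] = {}
        for m in matrices:
            x = m.data[vid].to_numpy(dtype=float)
            if m.species not in kdes:
                curves[m.species] = np.zeros_like(grid)
                modes[m.species] = float(x[0])
                degenerate[m.species] = True
                continue
            dens = kdes[m.species](grid)
            curves[m.species] = dens
            modes[m.species] = float(grid[int(np.argmax(dens))])
            degenerate[m.species] = False
        profiles.append(
            DensityProfile(variable_id=vid, grid=grid, curves=curves, modes=modes, degenerate=degenerate)
        )
    return profiles


def overlay_report(
    profiles: Sequence[DensityProfile],
    site_values: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Long-format (species, variable, value, density) table plus site markers.

    Site markers get ``density = NaN`` and ``species = "<site>"``; a site value
    missing for some profiled variable is omitted with a warning in the log.
    """
    import logging

    rows = []
    for prof in profiles:
        for sp, dens in prof.curves.items():
            rows.append(
                pd.DataFrame(
                    {
                        "species": sp,
                        "variable": prof.variable_id,
                        "value": prof.grid,
                        "density": dens,
                    }
                )
            )
        if site_values is not None:
            if prof.variable_id in site_values:
                rows.append(
                    pd.DataFrame(
                        {
                            "species": ["<site>"],
                            "variable": [prof.variable_id],
                            "value": [float(site_values[prof.variable_id])],
                            "density": [np.nan],
                        }
                    )
                )
            else:
                logging.getLogger(__name__).warning(
                    "overlay_report: site value missing for %s; marker omitted", prof.variable_id
                )
    return pd.concat(rows, ignore_index=True)


def render_profiles(
    profiles: Sequence[DensityProfile],
    path: str | Path,
    site_values: Mapping[str, float] | None = None,
) -> None:
    """Render density curves (one panel per variable) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(profiles)
    ncols = min(3, n)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False)
    names = {v.id: v for v in CATALOG}
    for ax, prof in zip(axes.ravel(), profiles):
        for sp, dens in prof.curves.items():
            ax.plot(prof.grid, dens, label=sp)
        if site_values and prof.variable_id in site_values:
            ax.axvline(site_values[prof.variable_id], color="red", linestyle="--")
        var = names[prof.variable_id]
        ax.set_title(f"{var.name} [{var.unit}]", fontsize=9)
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    axes.ravel()[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
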