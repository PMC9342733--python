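"""Model/Results surface tying the pipeline together.

``NicheSuitabilityModel`` is constructed from one environment matrix per
species and fits, in one shared reduced space: a pooled standardized PCA with
Guttman-Kaiser retention, a one-class-SVM hypervolume per species, and (on
demand) their n-way intersection. The returned ``NicheSuitabilityResults``
carries the estimates and diagnostics and exposes the user-facing questions:
is this site suitable for each species, is it inside the shared niche, and
how large is the shared abiotic space.

Hypervolumes that will be intersected must live in one reduced space, so the
PCA is fitted on the pooled, jointly standardized matrices of all species in
the model rather than per species.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .environment import VARIABLE_IDS, EnvMatrix
from .exceptions import DataError
from .niche import (
    DimWarning,
    Hypervolume,
    HypervolumeIntersection,
    PcaModel,
    check_dimensionality,
    derive_seed,
    fit_hypervolume,
    fit_pca,
    intersect_n,
)


@dataclass(frozen=True)
class NicheParams:
    nu: float = 0.01
    gamma: float = 0.5
    n_mc_samples: int = 10_000
    box_margin: float = 0.5
    seed: int = 0


class NicheSuitabilityModel:
    """Joint niche model for one or more species.

    Parameters
    ----------
    env_matrices : sequence of EnvMatrix
        One per species; at least 3 presence cells each.
    nu, gamma : float
        One-class SVM parameters (expected training-point rejection rate and
        RBF kernel width on standardized scores).
    n_mc_samples : int
        Uniform samples per Monte-Carlo volume estimate.
    box_margin : float
        Bounding-box expansion per side, in standardized score units.
    seed : int
        Root seed; every stochastic step derives a child stream from it and
        the species names, so fits are reproducible and order-independent.
    """

    def __init__(
        self,
        env_matrices: Sequence[EnvMatrix],
        nu: float = 0.01,
        gamma: float = 0.5,
        n_mc_samples: int = 10_000,
        box_margin: float = 0.5,
        seed: int = 0,
    ) -> None:
        if not env_matrices:
            raise DataError("at least one environment matrix is required")
        names = [m.species for m in env_matrices]
        if len(set(names)) != len(names):
            raise DataError(f"duplicate species in model: {names}")
        self.env_matrices = list(env_matrices)
        self.params = NicheParams(nu, gamma, n_mc_samples, box_margin, seed)

    @classmethod
    def from_dataframes(
        cls, frames: Mapping[str, pd.DataFrame], **params
    ) -> "NicheSuitabilityModel":
        """Build from {species: DataFrame with the catalog variable columns}."""
        mats = []
        for sp, df in frames.items():
            data = df.copy()
            for col in ("lon_centre", "lat_centre"):
                if col not in data:
                    data[col] = np.nan
            mats.append(EnvMatrix(species=sp, data=data))
        return cls(mats, **params)

    def fit(self) -> "NicheSuitabilityResults":
        """Fit pooled PCA, per-species hypervolumes, and dimensionality diagnostics."""
        p = self.params
        pooled = pd.concat(
            [m.data[list(VARIABLE_IDS)] for m in self.env_matrices], ignore_index=True
        )
        pca, _ = fit_pca(pooled, VARIABLE_IDS)

        hypervolumes: dict[str, Hypervolume] = {}
        scores: dict[str, np.ndarray] = {}
        warnings: dict[str, DimWarning] = {}
        for m in self.env_matrices:
            sp_scores = pca.transform(m.data[list(VARIABLE_IDS)].to_numpy(dtype=float))
            scores[m.species] = sp_scores
            warnings[m.species] = check_dimensionality(len(m), pca.retained)
            hypervolumes[m.species] = fit_hypervolume(
                sp_scores,
                nu=p.nu, gamma=p.gamma, n_mc_samples=p.n_mc_samples,
                box_margin=p.box_margin,
                seed=derive_seed(p.seed, "hypervolume", m.species),
            )
        return NicheSuitabilityResults(
            model=self, pca=pca, hypervolumes=hypervolumes,
            scores=scores, dim_warnings=warnings,
        )


@dataclass
class NicheSuitabilityResults:
    """Fitted niches in a shared reduced space, with diagnostics and queries."""

    model: NicheSuitabilityModel
    pca: PcaModel
    hypervolumes: dict[str, Hypervolume]
    scores: dict[str, np.ndarray]
    dim_warnings: dict[str, DimWarning]
    _intersection: HypervolumeIntersection | None = field(default=None, repr=False)

    @property
    def species(self) -> list[str]:
        return list(self.hypervolumes)

    def intersection(self) -> HypervolumeIntersection:
        """n-way intersection of all species' hypervolumes (cached; n >= 2)."""
        if self._intersection is None:
            p = self.model.params
            self._intersection = intersect_n(
                [self.hypervolumes[s] for s in self.species],
                n_mc_samples=p.n_mc_samples,
                seed=derive_seed(p.seed, "intersection", *sorted(self.species)),
            )
        return self._intersection

    def project_values(self, values: Mapping[str, float]) -> np.ndarray:
        return self.pca.project_values(values)

    def includes(self, species: str, values: Mapping[str, float]) -> bool:
        """Is a raw-unit abiotic vector inside one species' hypervolume?"""
        return self.hypervolumes[species].includes(self.project_values(values))

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        p = self.model.params
        buf = io.StringIO()
        buf.write("Niche suitability model\n")
        buf.write("=" * 70 + "\n")
        buf.write(
            f"Variables: {len(self.pca.variable_ids)} (dropped: "
            f"{list(self.pca.dropped_variables) or 'none'})\n"
        )
        eig = ", ".join(f"{v:.3f}" for v in self.pca.eigenvalues[: min(6, len(self.pca.eigenvalues))])
        buf.write(f"PCA eigenvalues (leading): {eig}\n")
        buf.write(f"Retained components (Guttman-Kaiser): {self.pca.retained}\n")
        buf.write(f"SVM nu={p.nu} gamma={p.gamma}  MC samples={p.n_mc_samples}  seed={p.seed}\n\n")
        rows = []
        for sp in self.species:
            hv = self.hypervolumes[sp]
            w = self.dim_warnings[sp]
            rows.append(
                {
                    "species": sp,
                    "n_cells": w.n_occurrences,
                    "dims": hv.dim,
                    "volume": round(hv.volume, 4),
                    "dim_warning": "yes" if w.triggered else "no",
                }
            )
        buf.write(pd.DataFrame(rows).to_string(index=False))
        buf.write("\n")
        if len(self.species) >= 2:
            inter = self.intersection()
            verdict = "NULL (no shared abiotic space)" if inter.is_null else "non-null"
            buf.write(
                f"\nIntersection volume: {inter.volume:.4f} (SE {inter.volume_se:.4f}) "
                f"-> {verdict}\n"
            )
        return buf.getvalue()
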