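"""Niche hypervolume machinery: standardized PCA, one-class-SVM boundary, Monte-Carlo volume.

The realised niche of a species is represented as a hypervolume in a reduced
environmental space. The reduction is a PCA on the correlation matrix of the
abiotic variables (standardization removes the wildly different units), with
components retained by the Guttman-Kaiser criterion (eigenvalue > 1). The
boundary in the reduced space is a one-class SVM with an RBF kernel, which
behaves well in the moderately high dimensions that remain after reduction.

Volume is estimated by rejection sampling: uniform points are drawn in the
score bounding box expanded by a fixed margin, and the accepted fraction
scales the box volume. The accepted points are retained; they give the
intersection machinery a cloud at a known density and make every estimate
reproducible from the stored seed.

Boundary accuracy degrades once the dimensionality approaches the information
content of the sample; the conventional guard is to warn when the number of
dimensions exceeds the natural log of the number of occurrences.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import OneClassSVM

from .exceptions import DataError, DegenerateBoundaryError

logger = logging.getLogger(__name__)

DEFAULT_NU = 0.01
DEFAULT_GAMMA = 0.5
DEFAULT_N_MC_SAMPLES = 10_000
DEFAULT_BOX_MARGIN = 0.5


def derive_seed(seed: int, *tokens: object) -> int:
    """Deterministic child seed (< 2^31) from a root seed and string tokens.

    Every stochastic operation derives its own stream this way, so results
    are reproducible regardless of execution order.
    """
    h = hashlib.blake2b(digest_size=8)
    h.update(str(int(seed)).encode())
    for t in tokens:
        h.update(b"\x1f")
        h.update(str(t).encode())
    return int.from_bytes(h.digest(), "big") % (2**31)


# ---------------------------------------------------------------------------
# PCA on the correlation matrix with Guttman-Kaiser retention
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    """Standardization parameters plus correlation-matrix eigenstructure.

    ``loadings`` columns are orthonormal eigenvectors ordered by decreasing
    eigenvalue; ``retained`` components (eigenvalue > 1, minimum 1) define the
    shared reduced space all hypervolumes live in.
    """

    variable_ids: tuple[str, ...]
    mean: np.ndarray
    std: np.ndarray
    loadings: np.ndarray      # (p, p)
    eigenvalues: np.ndarray   # length p, non-increasing
    retained: int
    dropped_variables: tuple[str, ...] = ()
    #: Column order of the matrices this model was fitted on, before the
    #: zero-variance drop; transform accepts either width.
    input_variable_ids: tuple[str, ...] = ()

    def standardize(self, raw: np.ndarray) -> np.ndarray:
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        if self.input_variable_ids and raw.shape[1] == len(self.input_variable_ids) != len(
            self.variable_ids
        ):
            keep = [i for i, v in enumerate(self.input_variable_ids) if v in set(self.variable_ids)]
            raw = raw[:, keep]
        if raw.shape[1] != len(self.variable_ids):
            raise ValueError(
                f"expected {len(self.variable_ids)} (or {len(self.input_variable_ids)}) "
                f"columns, got {raw.shape[1]}"
            )
        return (raw - self.mean) / self.std

    def transform(self, raw: np.ndarray) -> np.ndarray:
        """Project raw-unit rows into the retained reduced space."""
        return self.standardize(raw) @ self.loadings[:, : self.retained]

    def project_values(self, values: Mapping[str, float]) -> np.ndarray:
        """Project a variable->value mapping (must cover ``variable_ids``)."""
        vec = np.array([values[v] for v in self.variable_ids], dtype=float)
        return self.transform(vec)[0]


def fit_pca(
    data: pd.DataFrame | np.ndarray,
    variable_ids: Sequence[str] | None = None,
) -> tuple[PcaModel, np.ndarray]:
    """Standardized (correlation-matrix) PCA with Guttman-Kaiser retention.

    Zero-variance columns are dropped (logged) before standardization. Returns
    the model and the scores of the input rows, truncated to the retained
    components. At least one component is always retained.
    """
    if isinstance(data, pd.DataFrame):
        variable_ids = tuple(data.columns) if variable_ids is None else tuple(variable_ids)
        X = data[list(variable_ids)].to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        if variable_ids is None:
            variable_ids = tuple(f"x{i}" for i in range(X.shape[1]))
        variable_ids = tuple(variable_ids)
    input_ids = variable_ids
    if X.ndim != 2 or X.shape[0] < 3:
        raise DataError(f"PCA needs at least 3 rows, got shape {X.shape}")
    if np.isnan(X).any():
        raise DataError("PCA input contains missing values; drop incomplete rows first")

    std = X.std(axis=0, ddof=1)
    # relative tolerance: float aggregation can leave ~1-ulp jitter on a
    # constant field, which must not survive standardization
    keep = std > 1e-10 * np.maximum(np.abs(X.mean(axis=0)), 1.0)
    dropped = tuple(v for v, k in zip(variable_ids, keep) if not k)
    if dropped:
        logger.info("fit_pca: dropped zero-variance variables: %s", list(dropped))
    variable_ids = tuple(v for v, k in zip(variable_ids, keep) if k)
    X = X[:, keep]
    if X.shape[1] == 0:
        raise DataError("all variables have zero variance")

    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    Z = (X - mean) / std
    corr = (Z.T @ Z) / (X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # Sign convention: largest-magnitude loading of each component positive.
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]

    retained = max(1, int(np.sum(eigval > 1.0)))
    model = PcaModel(
        variable_ids=variable_ids,
        mean=mean,
        std=std,
        loadings=eigvec,
        eigenvalues=eigval,
        retained=retained,
        dropped_variables=dropped,
        input_variable_ids=input_ids,
    )
    return model, Z @ eigvec[:, :retained]


@dataclass(frozen=True)
class DimWarning:
    """Dimensionality guard: triggered when dims exceed ln(occurrences)."""

    n_occurrences: int
    n_dims: int
    threshold: float
    triggered: bool

    def __str__(self) -> str:
        verdict = "EXCEEDS" if self.triggered else "within"
        return (
            f"{self.n_dims} dims {verdict} ln({self.n_occurrences}) = {self.threshold:.2f}"
        )


def check_dimensionality(n_occurrences: int, n_dims: int) -> DimWarning:
    """Warn when the reduced dimensionality exceeds ln(occurrence count)."""
    if n_occurrences <= 0 or n_dims <= 0:
        raise ValueError("n_occurrences and n_dims must be positive")
    threshold = math.log(n_occurrences)
    return DimWarning(
        n_occurrences=n_occurrences,
        n_dims=n_dims,
        threshold=threshold,
        triggered=n_dims > threshold,
    )


# ---------------------------------------------------------------------------
# One-class-SVM hypervolume with Monte-Carlo volume
# ---------------------------------------------------------------------------

@dataclass
class Hypervolume:
    """A fitted niche boundary with its Monte-Carlo point cloud and volume.

    The SVM is fitted on internally standardized scores (per-axis mean/sd of
    the training sample); ``support_vectors`` and the decision function live
    in that internal space, while the point cloud, bounding box, and volume
    are reported in the original (shared reduced) space. The decision function
    is evaluated here from the stored support vectors, so a serialized and
    reloaded hypervolume reproduces inclusion decisions bit-exactly.
    """

    dim: int
    nu: float
    gamma: float
    box_margin: float
    rng_seed: int
    scale_mean: np.ndarray        # (dim,) internal standardization
    scale_sd: np.ndarray          # (dim,)
    support_vectors: np.ndarray   # (n_sv, dim), internal space
    dual_coefs: np.ndarray        # (n_sv,)
    intercept: float
    box_lo: np.ndarray            # (dim,) sampling box, original space
    box_hi: np.ndarray
    random_points: np.ndarray     # (n_acc, dim), original space
    point_density: float          # points per unit volume
    volume: float
    n_mc_samples: int = DEFAULT_N_MC_SAMPLES

    def decision(self, points: np.ndarray) -> np.ndarray:
        """RBF one-class decision values at points in the original space."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] != self.dim:
            raise ValueError(f"points have dim {pts.shape[1]}, hypervolume has dim {self.dim}")
        z = (pts - self.scale_mean) / self.scale_sd
        d2 = (
            np.sum(z**2, axis=1)[:, None]
            - 2.0 * z @ self.support_vectors.T
            + np.sum(self.support_vectors**2, axis=1)[None, :]
        )
        return np.exp(-self.gamma * np.clip(d2, 0.0, None)) @ self.dual_coefs + self.intercept

    def includes(self, point: np.ndarray) -> bool:
        """Inclusion test: decision function >= 0 at the point."""
        return bool(self.decision(np.atleast_2d(point))[0] >= 0.0)

    def includes_many(self, points: np.ndarray) -> np.ndarray:
        return self.decision(points) >= 0.0


def fit_hypervolume(
    scores: np.ndarray,
    nu: float = DEFAULT_NU,
    gamma: float = DEFAULT_GAMMA,
    n_mc_samples: int = DEFAULT_N_MC_SAMPLES,
    box_margin: float = DEFAULT_BOX_MARGIN,
    seed: int = 0,
) -> Hypervolume:
    """Fit a one-class-SVM hypervolume to reduced-space scores.

    The scores are standardized per axis before the SVM fit (the RBF width
    ``gamma`` then acts on comparable scales); ``box_margin`` expands the
    standardized bounding box on each side before uniform sampling. The volume
    is box volume times acceptance fraction, mapped back to the original
    score space through the standardization Jacobian.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.ndim != 2 or X.shape[0] < X.shape[1] + 1:
        raise DataError(
            f"hypervolume fit needs at least dim+1 points, got {X.shape[0]} in dim {X.shape[1]}"
        )
    dim = X.shape[1]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / sd

    svm = OneClassSVM(nu=nu, gamma=gamma).fit(Z)
    sv = svm.support_vectors_.astype(float)
    coefs = svm.dual_coef_.ravel().astype(float)
    intercept = float(svm.intercept_[0])

    z_lo = Z.min(axis=0) - box_margin
    z_hi = Z.max(axis=0) + box_margin
    box_lo = mean + z_lo * sd
    box_hi = mean + z_hi * sd
    box_volume = float(np.prod(box_hi - box_lo))

    rng = np.random.default_rng(seed)
    samples_z = rng.uniform(z_lo, z_hi, size=(n_mc_samples, dim))
    hv = Hypervolume(
        dim=dim, nu=nu, gamma=gamma, box_margin=box_margin, rng_seed=seed,
        scale_mean=mean, scale_sd=sd,
        support_vectors=sv, dual_coefs=coefs, intercept=intercept,
        box_lo=box_lo, box_hi=box_hi,
        random_points=np.empty((0, dim)), point_density=float("nan"), volume=0.0,
        n_mc_samples=n_mc_samples,
    )
    samples = mean + samples_z * sd
    accepted = samples[hv.includes_many(samples)]
    if len(accepted) == 0:
        raise DegenerateBoundaryError(
            "all Monte-Carlo samples rejected; raise gamma or box_margin, or check the scores"
        )
    volume = box_volume * len(accepted) / n_mc_samples
    hv.random_points = accepted
    hv.volume = volume
    hv.point_density = len(accepted) / volume
    return hv


# ---------------------------------------------------------------------------
# n-way intersection
# ---------------------------------------------------------------------------

@dataclass
class HypervolumeIntersection:
    """Monte-Carlo intersection of n hypervolumes sharing one reduced space.

    ``volume == 0`` with an empty point cloud is the null-intersection
    verdict: the species have no shared abiotic space and co-farming is
    infeasible under the fitted niches. Inclusion is evaluated member-wise
    (a point is in the intersection iff every member includes it).
    """

    dim: int
    members: tuple[Hypervolume, ...]
    random_points: np.ndarray
    point_density: float
    volume: float
    volume_se: float
    rng_seed: int
    n_mc_samples: int

    @property
    def is_null(self) -> bool:
        return self.volume == 0.0

    def includes(self, point: np.ndarray) -> bool:
        return all(m.includes(point) for m in self.members)

    def includes_many(self, points: np.ndarray) -> np.ndarray:
        mask = np.ones(len(np.atleast_2d(points)), dtype=bool)
        for m in self.members:
            mask &= m.includes_many(points)
        return mask


def intersect_n(
    hvs: Sequence[Hypervolume],
    n_mc_samples: int = DEFAULT_N_MC_SAMPLES,
    seed: int = 0,
) -> HypervolumeIntersection:
    """Estimate the joint hypervolume of n >= 2 species by rejection sampling.

    Uniform points are drawn in the intersection of the members' sampling
    boxes; a point is accepted iff every member's decision function admits it.
    An empty box or zero acceptances yields volume 0 with an empty point set.
    """
    hvs = list(hvs)
    if len(hvs) < 2:
        raise ValueError("intersection requires at least 2 hypervolumes")
    dims = {hv.dim for hv in hvs}
    if len(dims) != 1:
        raise ValueError(f"hypervolumes have mismatched dims {sorted(dims)}; fit them in one shared PCA space")
    dim = dims.pop()

    lo = np.max([hv.box_lo for hv in hvs], axis=0)
    hi = np.min([hv.box_hi for hv in hvs], axis=0)
    if np.any(hi <= lo):
        return HypervolumeIntersection(
            dim=dim, members=tuple(hvs), random_points=np.empty((0, dim)),
            point_density=float("nan"), volume=0.0, volume_se=0.0,
            rng_seed=seed, n_mc_samples=n_mc_samples,
        )
    box_volume = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    samples = rng.uniform(lo, hi, size=(n_mc_samples, dim))
    mask = np.ones(n_mc_samples, dtype=bool)
    for hv in hvs:
        mask &= hv.includes_many(samples)
    accepted = samples[mask]
    p = len(accepted) / n_mc_samples
    volume = box_volume * p
    se = box_volume * math.sqrt(p * (1.0 - p) / n_mc_samples)
    return HypervolumeIntersection(
        dim=dim, members=tuple(hvs), random_points=accepted,
        point_density=(len(accepted) / volume) if volume > 0 else float("nan"),
        volume=volume, volume_se=se, rng_seed=seed, n_mc_samples=n_mc_samples,
    )


def mc_volume_se(hv: Hypervolume) -> float:
    """Binomial standard error of a hypervolume's Monte-Carlo volume estimate."""
    box_volume = float(np.prod(hv.box_hi - hv.box_lo))
    p = len(hv.random_points) / hv.n_mc_samples
    return box_volume * math.sqrt(p * (1.0 - p) / hv.n_mc_samples)


# ---------------------------------------------------------------------------
# Serialization: JSON header + CSV point cloud
# ---------------------------------------------------------------------------

def save_hypervolume(hv: Hypervolume, directory: str | Path, name: str) -> None:
    """Write ``<name>.json`` (parameters, full-precision) and ``<name>_points.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = {
        "dim": hv.dim, "nu": hv.nu, "gamma": hv.gamma,
        "box_margin": hv.box_margin, "rng_seed": hv.rng_seed,
        "n_mc_samples": hv.n_mc_samples,
        "volume": hv.volume, "point_density": hv.point_density,
        "intercept": hv.intercept,
        "scale_mean": hv.scale_mean.tolist(), "scale_sd": hv.scale_sd.tolist(),
        "box_lo": hv.box_lo.tolist(), "box_hi": hv.box_hi.tolist(),
        "dual_coefs": hv.dual_coefs.tolist(),
        "support_vectors": hv.support_vectors.tolist(),
    }
    (directory / f"{name}.json").write_text(json.dumps(header))
    pd.DataFrame(hv.random_points, columns=[f"pc{i+1}" for i in range(hv.dim)]).to_csv(
        directory / f"{name}_points.csv", index=False, float_format="%.17g"
    )


def load_hypervolume(directory: str | Path, name: str) -> Hypervolume:
    directory = Path(directory)
    header = json.loads((directory / f"{name}.json").read_text())
    points = pd.read_csv(
        directory / f"{name}_points.csv", float_precision="round_trip"
    ).to_numpy(dtype=float)
    if points.size == 0:
        points = points.reshape(0, header["dim"])
    return Hypervolume(
        dim=header["dim"], nu=header["nu"], gamma=header["gamma"],
        box_margin=header["box_margin"], rng_seed=header["rng_seed"],
        n_mc_samples=header["n_mc_samples"],
        scale_mean=np.array(header["scale_mean"]), scale_sd=np.array(header["scale_sd"]),
        support_vectors=np.array(header["support_vectors"]),
        dual_coefs=np.array(header["dual_coefs"]), intercept=header["intercept"],
        box_lo=np.array(header["box_lo"]), box_hi=np.array(header["box_hi"]),
        random_points=points, point_density=header["point_density"], volume=header["volume"],
    )
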