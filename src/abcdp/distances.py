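"""Distances between datasets: kernel MMD, weighted L2 on summaries, clipping.

The default distance is the (biased, V-statistic) empirical maximum mean
discrepancy under a bounded kernel.  With a kernel bounded by ``B_k`` the
root-MMD between any two datasets is at most ``2*sqrt(B_k)`` and replacing a
single record of an ``N``-point dataset moves it by at most ``2*sqrt(B_k)/N``
— the global sensitivity that calibrates the Laplace noise in
:mod:`abcdp.privacy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataSet",
    "KernelSpec",
    "DistanceSpec",
    "as_dataset",
    "gaussian_kernel",
    "mmd2_biased",
    "mmd_distance",
    "median_heuristic_bandwidth",
    "weighted_l2_distance",
    "clip_distance",
]


@dataclass(frozen=True)
class DataSet:
    """An ordered collection of fixed-dimension numeric records.

    The privacy unit is one row: two datasets are *neighbours* when they
    differ in a single row.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
        if pts.ndim != 2 or pts.shape[0] < 1:
            raise ValueError("DataSet requires an N x d matrix with N >= 1")
        if not np.all(np.isfinite(pts)):
            raise ValueError("DataSet entries must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    @classmethod
    def from_csv(cls, path: str | Path, header: bool = False) -> "DataSet":
        df = pd.read_csv(path, header=0 if header else None)
        return cls(df.to_numpy(dtype=float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.points).to_csv(path, index=False, header=False)


def as_dataset(data: "DataSet | np.ndarray | Sequence") -> DataSet:
    """Coerce an array-like (N,) or (N, d) into a :class:`DataSet`."""
    if isinstance(data, DataSet):
        return data
    return DataSet(np.asarray(data, dtype=float))


@dataclass(frozen=True)
class KernelSpec:
    """A bounded positive-definite kernel; only the Gaussian family ships.

    ``bound`` is B_k = sup k(x, y); for the Gaussian kernel it is 1 for every
    bandwidth.
    """

    bandwidth: float
    family: str = "gaussian"
    bound: float = 1.0

    def __post_init__(self) -> None:
        if self.family != "gaussian":
            raise ValueError(f"unsupported kernel family: {self.family!r}")
        if not (self.bandwidth > 0 and np.isfinite(self.bandwidth)):
            raise ValueError("kernel bandwidth must be a positive finite real")
        if self.family == "gaussian" and self.bound != 1.0:
            raise ValueError("gaussian kernel has bound B_k = 1")


def gaussian_kernel(x, y, bandwidth: float):
    """Gaussian kernel k(x, y) = exp(-||x - y||^2 / (2 l^2)).

    Accepts single d-vectors or broadcastable arrays of vectors; the value
    lies in (0, 1] and equals 1 iff x == y.
    """
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sq = np.sum((np.atleast_1d(x) - np.atleast_1d(y)) ** 2, axis=-1)
    return np.exp(-sq / (2.0 * bandwidth**2))


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    if A.shape[1] == 1:
        D = A[:, 0][:, None] - B[:, 0][None, :]
        np.square(D, out=D)
        return D
    # ||a-b||^2 via the GEMM expansion; clip tiny negatives from cancellation
    aa = np.einsum("ij,ij->i", A, A)
    bb = np.einsum("ij,ij->i", B, B)
    D = aa[:, None] + bb[None, :]
    D -= 2.0 * (A @ B.T)
    np.maximum(D, 0.0, out=D)
    return D


def _gram_mean(A: np.ndarray, B: np.ndarray, bandwidth: float) -> float:
    D = _sq_dists(A, B)
    D *= -1.0 / (2.0 * bandwidth**2)
    np.exp(D, out=D)
    return float(D.mean())


def mmd2_biased(X, Y, kernel: KernelSpec) -> float:
    """Biased (V-statistic) squared-MMD estimator.

    MMD^2(X_m, Y_n) = (1/m^2) Σ k(x_i, x_j) + (1/n^2) Σ k(y_i, y_j)
                      − (2/mn) Σ k(x_i, y_j),
    diagonal terms included, so the value is the squared RKHS norm of the
    difference of the two empirical mean embeddings and is never negative.
    """
    X, Y = as_dataset(X), as_dataset(Y)
    if X.dim != Y.dim:
        raise ValueError(f"dimension mismatch: {X.dim} != {Y.dim}")
    bw = kernel.bandwidth
    v = (
        _gram_mean(X.points, X.points, bw)
        + _gram_mean(Y.points, Y.points, bw)
        - 2.0 * _gram_mean(X.points, Y.points, bw)
    )
    # cancellation guard: exact value is >= 0
    return 0.0 if -1e-12 < v < 0.0 else v


def mmd_distance(X, Y, kernel: KernelSpec) -> float:
    """Root-MMD distance: sqrt of :func:`mmd2_biased`, bounded by 2*sqrt(B_k)."""
    return float(np.sqrt(max(mmd2_biased(X, Y, kernel), 0.0)))


def median_heuristic_bandwidth(
    pseudo_datasets: Iterable, cap: int = 1000, rng: np.random.Generator | None = None
) -> float:
    """Median pairwise Euclidean distance over pooled pseudo-data points.

    Computed on simulated (public) data only, so it costs no privacy budget.
    When the pool exceeds ``cap`` points a seeded subsample bounds the O(n^2)
    pair enumeration.  A zero median falls back to the smallest nonzero
    distance; fully degenerate input (all points identical) is an error.
    """
    pooled = np.vstack([as_dataset(d).points for d in pseudo_datasets])
    if pooled.shape[0] < 2:
        raise ValueError("median heuristic needs at least 2 pooled points")
    if pooled.shape[0] > cap:
        rng = np.random.default_rng(0) if rng is None else rng
        idx = rng.choice(pooled.shape[0], size=cap, replace=False)
        pooled = pooled[idx]
    from scipy.spatial.distance import pdist

    d = pdist(pooled)
    if not np.any(d > 0):
        raise ValueError("degenerate input: all pooled points identical")
    med = float(np.median(d))
    if med == 0.0:
        med = float(d[d > 0].min())
    return med


def weighted_l2_distance(s1, s2, weights) -> float:
    """sqrt(Σ_j w_j (s1_j − s2_j)^2) between two summary-statistic vectors."""
    s1 = np.asarray(s1, dtype=float).ravel()
    s2 = np.asarray(s2, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if s1.shape != s2.shape or s1.shape != w.shape:
        raise ValueError("summary vectors and weights must have equal length")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    return float(np.sqrt(np.sum(w * (s1 - s2) ** 2)))


def clip_distance(rho: float, C: float) -> float:
    """min(rho, C): imposes an artificial sensitivity bound C on a distance."""
    if not C > 0:
        raise ValueError("clip bound C must be positive")
    return min(float(rho), float(C))


@dataclass(frozen=True)
class DistanceSpec:
    """Which distance to run and the sensitivity the privacy accounting uses.

    kind='mmd' uses the root-MMD with ``kernel``; its sensitivity is derived
    from the private dataset size (2*sqrt(B_k)/N).  kind='weighted_l2'
    compares flattened summary vectors with ``weights`` (default all-ones);
    it has no derivable sensitivity, so ``sensitivity`` must be supplied
    explicitly (after clipping, if ``clip`` is set).
    """

    kind: str = "mmd"
    kernel: KernelSpec | None = None
    weights: np.ndarray | None = None
    clip: float | None = None
    sensitivity: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("mmd", "weighted_l2"):
            raise ValueError(f"unknown distance kind: {self.kind!r}")
        if self.kind == "mmd" and self.kernel is None:
            raise ValueError("mmd distance requires a KernelSpec")
        if self.clip is not None and not self.clip > 0:
            raise ValueError("clip bound must be positive")
        if self.sensitivity is not None and not (
            self.sensitivity > 0 and np.isfinite(self.sensitivity)
        ):
            raise ValueError("sensitivity must be positive and finite")
        if self.weights is not None:
            object.__setattr__(
                self, "weights", np.asarray(self.weights, dtype=float).ravel()
            )

    def delta_rho(self, n_private: int) -> float:
        """Global sensitivity Δρ for a private dataset of ``n_private`` rows."""
        if self.sensitivity is not None:
            return self.sensitivity
        if self.kind == "mmd":
            from .privacy import mmd_sensitivity

            return mmd_sensitivity(n_private, self.kernel.bound)
        raise ValueError(
            "no derivable sensitivity for kind='weighted_l2'; "
            "set DistanceSpec.sensitivity explicitly"
        )

    def __call__(self, observed, pseudo) -> float:
        """Distance ρ(observed, pseudo), clipped if a clip bound is set."""
        return self.bind(observed)(pseudo)

    def bind(self, observed) -> "BoundDistance":
        """Fix the observed dataset; caches its self-Gram term for MMD."""
        return BoundDistance(self, as_dataset(observed))


class BoundDistance:
    """A distance with the observed dataset fixed (one call per pseudo-dataset)."""

    def __init__(self, spec: DistanceSpec, observed: DataSet):
        self.spec = spec
        self.observed = observed
        if spec.kind == "mmd":
            self._xx = _gram_mean(
                observed.points, observed.points, spec.kernel.bandwidth
            )

    def __call__(self, pseudo) -> float:
        spec = self.spec
        pseudo = as_dataset(pseudo)
        if spec.kind == "mmd":
            if pseudo.dim != self.observed.dim:
                raise ValueError("dimension mismatch between observed and pseudo data")
            bw = spec.kernel.bandwidth
            v = (
                self._xx
                + _gram_mean(pseudo.points, pseudo.points, bw)
                - 2.0 * _gram_mean(self.observed.points, pseudo.points, bw)
            )
            rho = float(np.sqrt(max(v, 0.0)))
        else:
            s1 = self.observed.points.ravel()
            s2 = pseudo.points.ravel()
            w = spec.weights if spec.weights is not None else np.ones_like(s1)
            rho = weighted_l2_distance(s1, s2, w)
        if spec.clip is not None:
            rho = clip_distance(rho, spec.clip)
        return rho
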