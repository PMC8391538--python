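"""Self-contained generative models used to exercise the private sampler.

Two benchmark simulators ship:

* a 5-component mixture of unit-width uniforms on [0, 5) with a symmetric
  Dirichlet(1) prior over the mixing proportions — the classic summary-free
  ABC toy problem where ground truth is known;
* a cubic outbreak-curve model y(t) = a3 + a2 t + a1 t^2 + a0 t^3 with
  independent N(0, 1) priors on the coefficients, emulating short daily
  case-count series (default 18 days) such as the early phase of an
  epidemic.  The observed counts are synthetic: a noisy, rounded,
  nonnegative cubic trend generated in-package so every experiment runs
  offline.
"""

from __future__ import annotations

from typing import Callable, Iterator

import numpy as np

from .distances import DataSet
from .engine import SimPair

__all__ = [
    "THETA_STAR",
    "sample_simplex_prior",
    "sample_mixture_data",
    "sample_polynomial_prior",
    "polynomial_curve",
    "synthetic_outbreak_counts",
    "generate_pair_stream",
    "mixture_stream",
    "polynomial_stream",
]

# ground-truth mixing proportions of the benchmark mixture experiment
THETA_STAR = np.array([0.25, 0.04, 0.33, 0.04, 0.34])


def sample_simplex_prior(rng: np.random.Generator) -> np.ndarray:
    """One draw from Dirichlet(1, ..., 1): uniform on the 5-simplex."""
    return rng.dirichlet(np.ones(5))


def sample_mixture_data(theta, n: int, rng: np.random.Generator) -> DataSet:
    """n draws from sum_i theta_i * Uniform([i-1, i)).

    Sampled in two exact stages: a multinomial pick of the component, then a
    uniform draw inside its unit bin.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (5,) or np.any(theta < 0) or abs(theta.sum() - 1.0) > 1e-8:
        raise ValueError("theta must be a 5-vector on the probability simplex")
    if n < 1:
        raise ValueError("n must be >= 1")
    comp = rng.choice(5, size=n, p=theta / theta.sum())
    y = comp + rng.uniform(0.0, 1.0, size=n)
    return DataSet(y)


def sample_polynomial_prior(rng: np.random.Generator) -> np.ndarray:
    """Coefficients (a0, a1, a2, a3), each independently N(0, 1)."""
    return rng.standard_normal(4)


def polynomial_curve(a, t_grid) -> np.ndarray:
    """y(t) = a3 + a2 t + a1 t^2 + a0 t^3 (a0 is the cubic term)."""
    a = np.asarray(a, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    return a[3] + a[2] * t + a[1] * t**2 + a[0] * t**3


def synthetic_outbreak_counts(
    a_true,
    n_days: int = 18,
    noise_sd: float = 5.0,
    rng: np.random.Generator | None = None,
) -> DataSet:
    """Synthetic daily case counts on days t = 1..n_days.

    Counts are the cubic trend plus Gaussian noise, rounded and floored at
    zero — a stand-in with the shape of a short outbreak series (18 points
    by default).
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(0) if rng is None else rng
    t = np.arange(1, n_days + 1, dtype=float)
    y = polynomial_curve(a_true, t)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_days)
    counts = np.maximum(0.0, np.round(y))
    return DataSet(counts)


def generate_pair_stream(
    prior_sampler: Callable[[np.random.Generator], np.ndarray],
    data_sampler: Callable[[np.ndarray, np.random.Generator], DataSet],
    T: int,
    rng: np.random.Generator,
) -> Iterator[SimPair]:
    """Lazy stream of T i.i.d. (theta_t, Y_t) pairs, indices 1..T.

    Laziness matters: the private sampler breaks after c acceptances, and an
    unconsumed tail of the stream is never simulated.
    """
    if T < 1:
        raise ValueError("stream length T must be >= 1")
    for t in range(1, T + 1):
        theta = prior_sampler(rng)
        yield SimPair(theta=theta, pseudo_data=data_sampler(theta, rng), index=t)


def mixture_stream(
    T: int, n_per_dataset: int, rng: np.random.Generator
) -> Iterator[SimPair]:
    """Prior + simulator stream for the uniform-mixture benchmark."""
    return generate_pair_stream(
        sample_simplex_prior,
        lambda th, r: sample_mixture_data(th, n_per_dataset, r),
        T,
        rng,
    )


def polynomial_stream(
    T: int, rng: np.random.Generator, n_days: int = 18
) -> Iterator[SimPair]:
    """Prior + simulator stream for the outbreak-curve benchmark.

    Pseudo-data are the noise-free rounded curves; only the observed series
    carries observation noise.
    """
    t_grid = np.arange(1, n_days + 1, dtype=float)

    def simulate(a, r):
        return DataSet(np.maximum(0.0, np.round(polynomial_curve(a, t_grid))))

    return generate_pair_stream(sample_polynomial_prior, simulate, T, rng)
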