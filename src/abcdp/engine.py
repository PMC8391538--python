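"""The c-sample private accept/reject loop and the non-private baseline.

``run_abcdp`` consumes a stream of (theta_t, Y_t) pairs.  The threshold is
noised once up front with Lap(b) (and re-noised after every acceptance when
RESAMPLE is on); each distance is noised with Lap(2b); a pair is accepted when
the noisy distance falls at or below the noisy threshold; the loop breaks as
soon as c acceptances have been released.  The non-private baseline
``run_rejection_abc`` applies the exact rule rho_t <= eps_abc over the full
stream with no early stop, so the two can be compared at the same T.

Noise-draw order is fixed for reproducibility: one threshold draw before the
loop, then one distance draw per step, then (RESAMPLE only) one threshold
draw immediately after each acceptance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .distances import DataSet, DistanceSpec, as_dataset
from .privacy import PrivacyBudget, draw_laplace

__all__ = [
    "SimPair",
    "IndicatorTrace",
    "run_abcdp",
    "run_abcdp_from_distances",
    "run_rejection_abc",
    "posterior_mean",
    "stream_distances",
]


@dataclass(frozen=True)
class SimPair:
    """One item of the public stream: a prior draw and its pseudo-dataset."""

    theta: np.ndarray
    pseudo_data: DataSet
    index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", np.atleast_1d(np.asarray(self.theta, dtype=float)))
        object.__setattr__(self, "pseudo_data", as_dataset(self.pseudo_data))


@dataclass
class IndicatorTrace:
    """Record of one accept/reject run.

    ``indicators`` is the released binary stream; ``raw_distances`` (and, for
    private runs, ``noisy_distances``) are diagnostics computed on the
    private data — they are retained for theory checks and must never leave
    the data owner's side.
    """

    indicators: np.ndarray
    raw_distances: np.ndarray
    noisy_distances: np.ndarray | None
    thetas: np.ndarray
    private: bool
    termination_step: int

    @property
    def count(self) -> int:
        return int(self.indicators.sum())

    @property
    def accepted_indices(self) -> np.ndarray:
        """0-based positions of accepted pairs within the consumed stream."""
        return np.flatnonzero(self.indicators)

    @property
    def accepted_thetas(self) -> np.ndarray:
        return self.thetas[self.accepted_indices]


def _as_pair_iter(pairs: Iterable) -> Iterator[SimPair]:
    it = iter(pairs)
    first = next(it, None)
    if first is None:
        raise ValueError("empty simulation stream")

    def chain():
        yield first
        yield from it

    return chain()


def run_abcdp(
    observed,
    pairs: Iterable[SimPair],
    epsilon_abc: float,
    budget: PrivacyBudget,
    distance: DistanceSpec,
    rng: np.random.Generator,
) -> IndicatorTrace:
    """Private c-sample run over a (possibly lazy) stream of pairs.

    Stops as soon as ``budget.c`` acceptances are out; a stream exhausted
    with fewer acceptances is a valid run (the claimed budget remains an
    upper bound on the loss) — the shortfall is visible in the trace.
    """
    observed = as_dataset(observed)
    dist = distance.bind(observed)
    b = budget.noise_scale_b

    eps_hat = epsilon_abc + draw_laplace(b, rng)
    indicators, raw, noisy, thetas = [], [], [], []
    count = 0
    step = 0
    for pair in _as_pair_iter(pairs):
        step += 1
        rho = dist(pair.pseudo_data)
        rho_hat = rho + draw_laplace(2.0 * b, rng)
        tau = 1 if rho_hat <= eps_hat else 0
        indicators.append(tau)
        raw.append(rho)
        noisy.append(rho_hat)
        thetas.append(pair.theta)
        if tau:
            count += 1
            if budget.resample:
                eps_hat = epsilon_abc + draw_laplace(b, rng)
        if count >= budget.c:
            break
    return IndicatorTrace(
        indicators=np.array(indicators, dtype=int),
        raw_distances=np.array(raw, dtype=float),
        noisy_distances=np.array(noisy, dtype=float),
        thetas=np.vstack(thetas),
        private=True,
        termination_step=step,
    )


def run_abcdp_from_distances(
    raw_distances: Sequence[float],
    thetas: np.ndarray,
    epsilon_abc: float,
    budget: PrivacyBudget,
    rng: np.random.Generator,
) -> IndicatorTrace:
    """Private run on precomputed distances (for noise replicates / sweeps).

    Identical decision path and noise order as :func:`run_abcdp`; useful when
    many privacy settings are replayed against one simulated stream.
    """
    rho = np.asarray(raw_distances, dtype=float).ravel()
    if rho.size == 0:
        raise ValueError("empty distance stream")
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    b = budget.noise_scale_b

    eps_hat = epsilon_abc + draw_laplace(b, rng)
    indicators = np.zeros(rho.size, dtype=int)
    noisy = np.empty(rho.size)
    count = 0
    step = 0
    for t in range(rho.size):
        step = t + 1
        noisy[t] = rho[t] + draw_laplace(2.0 * b, rng)
        if noisy[t] <= eps_hat:
            indicators[t] = 1
            count += 1
            if budget.resample:
                eps_hat = epsilon_abc + draw_laplace(b, rng)
        if count >= budget.c:
            break
    return IndicatorTrace(
        indicators=indicators[:step],
        raw_distances=rho[:step],
        noisy_distances=noisy[:step],
        thetas=thetas[:step],
        private=True,
        termination_step=step,
    )


def run_rejection_abc(
    observed,
    pairs: Iterable[SimPair],
    epsilon_abc: float,
    distance: DistanceSpec,
) -> IndicatorTrace:
    """Non-private rejection rule tau_t = 1[rho_t <= eps_abc] over the full
    stream; deterministic given its inputs."""
    observed = as_dataset(observed)
    dist = distance.bind(observed)
    raw, thetas = [], []
    for pair in _as_pair_iter(pairs):
        raw.append(dist(pair.pseudo_data))
        thetas.append(pair.theta)
    rho = np.array(raw, dtype=float)
    return IndicatorTrace(
        indicators=(rho <= epsilon_abc).astype(int),
        raw_distances=rho,
        noisy_distances=None,
        thetas=np.vstack(thetas),
        private=False,
        termination_step=rho.size,
    )


def stream_distances(
    observed, pairs: Iterable[SimPair], distance: DistanceSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Materialize a stream into (thetas, raw distances) for reuse across
    privacy settings."""
    dist = distance.bind(as_dataset(observed))
    raw, thetas = [], []
    for pair in _as_pair_iter(pairs):
        raw.append(dist(pair.pseudo_data))
        thetas.append(pair.theta)
    return np.vstack(thetas), np.array(raw, dtype=float)


def posterior_mean(
    trace: IndicatorTrace,
    thetas: np.ndarray | None = None,
    f: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """(1/count) * sum_t f(theta_t) * indicator_t — the ABC estimate of
    E[f(theta) | Y*] (f defaults to the identity)."""
    if trace.count == 0:
        raise ValueError("no accepted samples: posterior mean undefined")
    thetas = trace.thetas if thetas is None else np.atleast_2d(np.asarray(thetas, dtype=float))
    acc = thetas[np.flatnonzero(trace.indicators)]
    if f is not None:
        acc = np.vstack([np.atleast_1d(f(th)) for th in acc])
    return acc.mean(axis=0)
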