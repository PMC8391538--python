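"""Privacy accounting: sensitivity, budget <-> Laplace-scale calibration, noise.

The accept/reject stream is released under pure epsilon-DP by perturbing both
the ABC threshold (Laplace scale b) and each distance (Laplace scale 2b), in
the style of the sparse vector technique: only above-threshold answers (the
at most c acceptances) carry privacy cost.  Linear composition gives

    epsilon_total = (c + 1) * delta_rho / b    (threshold noised once)
    epsilon_total = 2 c * delta_rho / b        (threshold re-noised per accept)

and the calibration below solves these for b.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PrivacyBudget",
    "mmd_sensitivity",
    "noise_scale",
    "budget_of_noise_scale",
    "draw_laplace",
]


def mmd_sensitivity(N: int, B_k: float = 1.0) -> float:
    """Global sensitivity of root-MMD: replacing one of N private records
    moves the distance by at most 2*sqrt(B_k)/N."""
    if not (isinstance(N, (int, np.integer)) and N >= 1):
        raise ValueError("private dataset size N must be a positive integer")
    if not B_k > 0:
        raise ValueError("kernel bound B_k must be positive")
    return 2.0 * math.sqrt(B_k) / N


def noise_scale(
    epsilon_total: float, c: int, delta_rho: float, resample: bool
) -> float:
    """Laplace scale b achieving a total budget epsilon_total for c releases.

    Returns 0 for epsilon_total = inf (the non-private limit).
    """
    if not c >= 1:
        raise ValueError("target acceptance count c must be >= 1")
    if not delta_rho > 0:
        raise ValueError("sensitivity delta_rho must be positive")
    if not epsilon_total > 0:
        raise ValueError("epsilon_total must be positive")
    if math.isinf(epsilon_total):
        return 0.0
    if resample:
        return 2.0 * c * delta_rho / epsilon_total
    return (c + 1) * delta_rho / epsilon_total


def budget_of_noise_scale(b: float, c: int, delta_rho: float, resample: bool) -> float:
    """Total privacy loss of a run with Laplace scale b (inverse of
    :func:`noise_scale`); b = 0 maps back to an infinite budget."""
    if b == 0:
        return math.inf
    if not b > 0:
        raise ValueError("noise scale b must be positive")
    if not c >= 1:
        raise ValueError("target acceptance count c must be >= 1")
    if resample:
        return 2.0 * c * delta_rho / b
    return (c + 1) * delta_rho / b


def draw_laplace(scale: float, rng: np.random.Generator) -> float:
    """One zero-mean Laplace draw; exactly 0.0 when scale == 0 so that an
    infinite budget reduces bit-for-bit to the non-private algorithm."""
    if scale < 0:
        raise ValueError("Laplace scale must be nonnegative")
    if scale == 0:
        return 0.0
    return float(rng.laplace(0.0, scale))


@dataclass(frozen=True)
class PrivacyBudget:
    """Total budget epsilon_total, target release count c, RESAMPLE mode and
    the sensitivity delta_rho; the Laplace scale b is derived, never stored
    inconsistently."""

    epsilon_total: float
    c: int
    delta_rho: float
    resample: bool = False

    def __post_init__(self) -> None:
        if not self.epsilon_total > 0:
            raise ValueError("epsilon_total must be positive (or math.inf)")
        if not self.c >= 1:
            raise ValueError("c must be a positive integer")
        if not (self.delta_rho > 0 and np.isfinite(self.delta_rho)):
            raise ValueError("delta_rho must be positive and finite")

    @property
    def noise_scale_b(self) -> float:
        return noise_scale(self.epsilon_total, self.c, self.delta_rho, self.resample)

    def accounting(self) -> dict:
        """Privacy accounting summary for result bundles."""
        b = self.noise_scale_b
        return {
            "epsilon_total": self.epsilon_total,
            "noise_scale_b": b,
            "c_target": self.c,
            "resample": self.resample,
            "delta_rho": self.delta_rho,
        }
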