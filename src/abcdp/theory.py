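"""Closed-form theory for the noise-perturbed accept/reject indicators.

Let m ~ Lap(b) be the threshold noise and v ~ Lap(2b) the distance noise.
Their difference Z = m - v has density

    f_Z(z) = (1/(6b)) * [2 exp(-|z|/(2b)) - exp(-|z|/b)],

tail G_b(a) = P[Z >= a] = (1/6) [4 exp(-a/(2b)) - exp(-a/b)] for a >= 0, and
CDF F_Z(a) = H[a] + (1 - 2 H[a]) G_b(|a|) with Heaviside convention H[0] = 1.

A private step flips the non-private indicator with probability
G_b(|rho_t - eps_abc|): the further a distance sits from the threshold, the
less likely the Laplace noise is to change the decision.  Summed flip
probabilities bound the expected L2 gap between the private and non-private
posterior expectations of any function f with finite K_T = max_t ||f(theta_t)||.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FlipModel",
    "BoundInputs",
    "noise_diff_pdf",
    "noise_diff_cdf",
    "flip_tail_G",
    "flip_probability",
    "expected_error_bound",
    "error_tail_bound",
]


def _check_b(b: float) -> None:
    if not b > 0:
        raise ValueError("Laplace scale b must be positive")


def noise_diff_pdf(z, b: float):
    """Density of Z = Lap(b) - Lap(2b); even, positive, integrates to 1."""
    _check_b(b)
    az = np.abs(np.asarray(z, dtype=float))
    out = (2.0 * np.exp(-az / (2.0 * b)) - np.exp(-az / b)) / (6.0 * b)
    return out if out.ndim else float(out)


def flip_tail_G(a, b: float):
    """Upper tail G_b(a) = P[Z >= a] for a >= 0; G_b(0) = 1/2, decreasing."""
    _check_b(b)
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("tail argument a must be nonnegative")
    out = (4.0 * np.exp(-a / (2.0 * b)) - np.exp(-a / b)) / 6.0
    return out if out.ndim else float(out)


def noise_diff_cdf(a, b: float):
    """CDF of Z; symmetric about 0 (F_Z(-a) = 1 - F_Z(a)), F_Z(0) = 1/2."""
    _check_b(b)
    a = np.asarray(a, dtype=float)
    H = (a >= 0).astype(float)  # Heaviside, H[0] = 1
    out = H + (1.0 - 2.0 * H) * (4.0 * np.exp(-np.abs(a) / (2.0 * b)) - np.exp(-np.abs(a) / b)) / 6.0
    return out if out.ndim else float(out)


def flip_probability(rho_t, epsilon_abc: float, b: float):
    """P[private indicator != non-private indicator] at one step.

    Equals G_b(|rho_t - eps_abc|); at b = 0 the private run is exactly the
    non-private one, so the flip probability is 0 by convention.
    """
    gap = np.abs(np.asarray(rho_t, dtype=float) - epsilon_abc)
    if b == 0:
        out = np.zeros_like(gap)
        return out if out.ndim else float(out)
    return flip_tail_G(gap, b)


@dataclass(frozen=True)
class FlipModel:
    """Convenience wrapper fixing the threshold-noise scale b (> 0)."""

    b: float

    def __post_init__(self) -> None:
        _check_b(self.b)

    def pdf(self, z):
        return noise_diff_pdf(z, self.b)

    def cdf(self, a):
        return noise_diff_cdf(a, self.b)

    def tail(self, a):
        return flip_tail_G(a, self.b)

    def flip_probability(self, rho_t, epsilon_abc: float):
        return flip_probability(rho_t, epsilon_abc, self.b)


@dataclass(frozen=True)
class BoundInputs:
    """Inputs of the posterior-expectation error bounds.

    raw_distances: the non-private distances rho_1..T;
    epsilon_abc: the ABC threshold;
    K_T: max_t ||f(theta_t)||_2 of the integrand f (must be finite);
    c_prime: the non-private acceptance count (>= 1 by assumption).
    """

    raw_distances: np.ndarray
    epsilon_abc: float
    K_T: float
    c_prime: int

    def __post_init__(self) -> None:
        rho = np.asarray(self.raw_distances, dtype=float).ravel()
        if np.any(rho < 0) or not np.all(np.isfinite(rho)):
            raise ValueError("raw distances must be finite and nonnegative")
        object.__setattr__(self, "raw_distances", rho)
        if not (self.K_T >= 0 and np.isfinite(self.K_T)):
            raise ValueError("K_T must be finite and nonnegative")
        if not self.c_prime >= 1:
            raise ValueError("c_prime must be >= 1")


def expected_error_bound(inputs: BoundInputs, b: float) -> float:
    """Bound on E || private posterior mean of f - non-private one ||_2:

        (2 K_T / c') * sum_t G_b(|rho_t - eps_abc|).

    Tends to 0 as b -> 0 whenever every rho_t differs from eps_abc.
    """
    gaps = np.abs(inputs.raw_distances - inputs.epsilon_abc)
    if b == 0:
        return 0.0
    return float(2.0 * inputs.K_T / inputs.c_prime * np.sum(flip_tail_G(gaps, b)))


def error_tail_bound(a: float, inputs: BoundInputs, b: float) -> float:
    """Lower bound on P[|| gap ||_2 <= a]:

        1 - (4 K_T / (3 a c')) * sum_t exp(-|rho_t - eps_abc| / (2b)).

    May be negative (vacuous); returned as-is so callers can flag it.
    """
    if not a > 0:
        raise ValueError("tail level a must be positive")
    if b == 0:
        return 1.0
    gaps = np.abs(inputs.raw_distances - inputs.epsilon_abc)
    s = float(np.sum(np.exp(-gaps / (2.0 * b))))
    return 1.0 - 4.0 * inputs.K_T / (3.0 * a * inputs.c_prime) * s
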