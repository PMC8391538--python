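"""Model/Results interface over the accept/reject engine.

Usage mirrors the fit-centric style of statistical modelling packages::

    model = ABCDP(observed, prior_sampler, data_sampler,
                  distance=spec, epsilon_abc=0.05,
                  epsilon_total=1.0, c=10, resample=False)
    res = model.fit(T=2000, seed=7)
    res.params            # private ABC posterior-mean estimate of theta
    res.summary()         # text table with privacy accounting

``RejectionABC`` is the non-private baseline with the same constructor minus
the privacy arguments; it scans the full stream (no early stop).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .distances import DataSet, DistanceSpec, as_dataset
from .engine import (
    IndicatorTrace,
    posterior_mean,
    run_abcdp,
    run_rejection_abc,
)
from .privacy import PrivacyBudget
from .simulators import generate_pair_stream


class ABCResults:
    """Posterior samples and diagnostics from one accept/reject run."""

    def __init__(self, model, trace: IndicatorTrace, seed: int | None):
        self.model = model
        self.trace = trace
        self.seed = seed

    @property
    def n_accepted(self) -> int:
        return self.trace.count

    @property
    def accepted_params(self) -> np.ndarray:
        return self.trace.accepted_thetas

    @property
    def params(self) -> np.ndarray:
        """ABC posterior-mean estimate of the simulator parameters."""
        return posterior_mean(self.trace)

    def posterior_mean(self, f: Callable | None = None) -> np.ndarray:
        return posterior_mean(self.trace, f=f)

    def mse(self, theta_true) -> float:
        """Mean squared error of ``params`` against a known ground truth."""
        diff = self.params - np.asarray(theta_true, dtype=float)
        return float(np.mean(diff**2))

    def accounting(self) -> dict:
        if getattr(self.model, "budget", None) is None:
            return {"epsilon_total": math.inf, "noise_scale_b": 0.0, "private": False}
        acc = self.model.budget.accounting()
        acc["c_achieved"] = self.n_accepted
        acc["private"] = True
        return acc

    def summary(self) -> str:
        lines = [
            "Approximate Bayesian computation results",
            "=" * 46,
            f"{'steps consumed':<24}{self.trace.termination_step}",
            f"{'accepted samples':<24}{self.n_accepted}",
        ]
        acc = self.accounting()
        if acc.get("private"):
            lines += [
                f"{'epsilon_total':<24}{acc['epsilon_total']}",
                f"{'Laplace scale b':<24}{acc['noise_scale_b']:.6g}",
                f"{'resample threshold':<24}{acc['resample']}",
                f"{'sensitivity delta_rho':<24}{acc['delta_rho']:.6g}",
            ]
        else:
            lines.append(f"{'privacy':<24}non-private baseline")
        if self.n_accepted > 0:
            est = ", ".join(f"{v:.4f}" for v in self.params)
            lines.append(f"{'posterior mean':<24}[{est}]")
        lines.append("=" * 46)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<ABCResults: {self.n_accepted} accepted / {self.trace.termination_step} steps>"


class RejectionABC:
    """Non-private rejection sampler: accept theta_t iff rho_t <= eps_abc."""

    def __init__(
        self,
        observed,
        prior_sampler: Callable,
        data_sampler: Callable,
        distance: DistanceSpec,
        epsilon_abc: float,
    ):
        self.observed: DataSet = as_dataset(observed)
        self.prior_sampler = prior_sampler
        self.data_sampler = data_sampler
        self.distance = distance
        self.epsilon_abc = float(epsilon_abc)

    def _stream(self, T: int, rng: np.random.Generator):
        return generate_pair_stream(self.prior_sampler, self.data_sampler, T, rng)

    def fit(self, T: int, seed: int | None = None, rng: np.random.Generator | None = None) -> ABCResults:
        rng = np.random.default_rng(seed) if rng is None else rng
        trace = run_rejection_abc(
            self.observed, self._stream(T, rng), self.epsilon_abc, self.distance
        )
        return ABCResults(self, trace, seed)


class ABCDP(RejectionABC):
    """Differentially private c-sample rejection sampler.

    Adds Laplace noise to the threshold and to every distance, releasing at
    most ``c`` acceptances under a total pure-DP budget ``epsilon_total``
    (``math.inf`` runs the exact non-private decision path).  ``delta_rho``
    defaults to "auto": derived from the distance spec and the observed
    dataset size (possible for MMD only).
    """

    def __init__(
        self,
        observed,
        prior_sampler: Callable,
        data_sampler: Callable,
        distance: DistanceSpec,
        epsilon_abc: float,
        epsilon_total: float = math.inf,
        c: int = 10,
        resample: bool = False,
        delta_rho: float | str = "auto",
    ):
        super().__init__(observed, prior_sampler, data_sampler, distance, epsilon_abc)
        if delta_rho == "auto":
            delta_rho = distance.delta_rho(self.observed.n_points)
        self.budget = PrivacyBudget(
            epsilon_total=float(epsilon_total),
            c=int(c),
            delta_rho=float(delta_rho),
            resample=bool(resample),
        )

    def fit(self, T: int, seed: int | None = None, rng: np.random.Generator | None = None) -> ABCResults:
        rng = np.random.default_rng(seed) if rng is None else rng
        # independent sub-streams: simulation noise vs privacy noise, so the
        # same stream can be replayed under a different privacy setting
        sim_rng, noise_rng = rng.spawn(2)
        trace = run_abcdp(
            self.observed,
            self._stream(T, sim_rng),
            self.epsilon_abc,
            self.budget,
            self.distance,
            noise_rng,
        )
        return ABCResults(self, trace, seed)
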