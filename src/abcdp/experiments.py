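"""Experiment runners: single runs, privacy sweeps, flip-probability tables.

`run_experiment` wires a full pipeline per the run configuration: simulate
(or load) the observed data, build the public parameter/pseudo-data stream,
score the non-private rejection baseline and the private sampler on the same
stream, and report posterior summaries, privacy accounting and the
closed-form error bounds.  All randomness derives from the configured seed,
so replaying a results bundle's embedded config reproduces its indicators
bit for bit.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, dump_json
from .distances import DataSet, DistanceSpec, KernelSpec, median_heuristic_bandwidth
from .engine import IndicatorTrace, posterior_mean, run_abcdp_from_distances, stream_distances
from .privacy import PrivacyBudget
from .simulators import (
    THETA_STAR,
    generate_pair_stream,
    polynomial_curve,
    sample_mixture_data,
    sample_polynomial_prior,
    sample_simplex_prior,
    synthetic_outbreak_counts,
)
from .theory import BoundInputs, expected_error_bound, flip_probability

log = logging.getLogger("abcdp")

# default ground truth of the synthetic outbreak-curve experiment
A_TRUE = np.array([0.01, -0.1, 2.0, 1.0])

__all__ = ["run_experiment", "sweep", "flip_prob_table", "A_TRUE"]


def _prepare_problem(cfg: RunConfig, rng: np.random.Generator):
    """Observed data, ground truth (or None), prior and simulator callables."""
    if cfg.model == "mixture":
        observed = sample_mixture_data(THETA_STAR, cfg.n_observed, rng)
        return observed, THETA_STAR, sample_simplex_prior, (
            lambda th, r: sample_mixture_data(th, cfg.n_per_dataset, r)
        )
    # polynomial / external-csv: short daily count series + cubic simulator;
    # n_observed is the number of days (use 18 for the reference setting)
    if cfg.model == "external-csv":
        observed = DataSet.from_csv(cfg.observed_csv)
        truth = None
        n_days = observed.n_points
    else:
        n_days = cfg.n_observed
        observed = synthetic_outbreak_counts(A_TRUE, n_days=n_days, rng=rng)
        truth = A_TRUE
    t_grid = np.arange(1, n_days + 1, dtype=float)

    def simulate(a, r):
        return DataSet(np.maximum(0.0, np.round(polynomial_curve(a, t_grid))))

    return observed, truth, sample_polynomial_prior, simulate


def _distance_spec(cfg: RunConfig, prior_sampler, data_sampler, rng) -> DistanceSpec:
    sens = None if cfg.delta_rho == "auto" else float(cfg.delta_rho)
    if cfg.kind == "mmd":
        bw = cfg.bandwidth
        if bw == "median":
            # pilot pseudo-datasets only; the private data never enter
            n_pilot = max(2, math.ceil(1000 / max(cfg.n_per_dataset, 1)))
            pilots = [data_sampler(prior_sampler(rng), rng) for _ in range(n_pilot)]
            bw = median_heuristic_bandwidth(pilots, rng=rng)
            log.info("median-heuristic bandwidth: %.4g", bw)
        return DistanceSpec(
            kind="mmd", kernel=KernelSpec(bandwidth=float(bw)), clip=cfg.clip, sensitivity=sens
        )
    weights = None if cfg.weights is None else np.asarray(cfg.weights, dtype=float)
    return DistanceSpec(kind="weighted_l2", weights=weights, clip=cfg.clip, sensitivity=sens)


def _baseline_trace(rho: np.ndarray, thetas: np.ndarray, epsilon_abc: float) -> IndicatorTrace:
    return IndicatorTrace(
        indicators=(rho <= epsilon_abc).astype(int),
        raw_distances=rho,
        noisy_distances=None,
        thetas=thetas,
        private=False,
        termination_step=rho.size,
    )


def run_experiment(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Simulate -> baseline rejection ABC -> private run -> summaries.

    Returns (and optionally writes) a self-describing results bundle.  The
    privacy-safe artifacts are the indicators and accepted parameters; raw
    distances stay in memory and are logged only at DEBUG level.
    """
    cfg.validate()
    master = np.random.default_rng(cfg.seed)
    obs_rng, bw_rng, stream_rng, noise_rng = master.spawn(4)

    observed, truth, prior_sampler, data_sampler = _prepare_problem(cfg, obs_rng)
    spec = _distance_spec(cfg, prior_sampler, data_sampler, bw_rng)

    stream = generate_pair_stream(prior_sampler, data_sampler, cfg.T, stream_rng)
    thetas, rho = stream_distances(observed, stream, spec)
    log.debug("raw distances (do not release): %s", rho)

    baseline = _baseline_trace(rho, thetas, cfg.epsilon_abc)

    if cfg.kind == "weighted_l2" and cfg.delta_rho == "auto":
        # validate() only allows this when epsilon_total is inf; b = 0 either way
        delta_rho = 1.0
    else:
        delta_rho = spec.delta_rho(observed.n_points)
    budget = PrivacyBudget(
        epsilon_total=cfg.epsilon_total, c=cfg.c, delta_rho=delta_rho, resample=cfg.resample
    )
    private = run_abcdp_from_distances(rho, thetas, cfg.epsilon_abc, budget, noise_rng)

    results: dict = {
        "config": cfg.to_dict(),
        "accounting": {**budget.accounting(), "c_achieved": private.count},
        "baseline": {"n_accepted": baseline.count},
        "private": {
            "indicators": private.indicators.tolist(),
            "n_accepted": private.count,
            "termination_step": private.termination_step,
        },
    }
    log.info(
        "accounting: epsilon_total=%s b=%.4g accepted %d/%d (baseline %d)",
        cfg.epsilon_total, budget.noise_scale_b, private.count, cfg.c, baseline.count,
    )

    for name, trace in (("baseline", baseline), ("private", private)):
        if trace.count > 0:
            pm = posterior_mean(trace)
            results[name]["posterior_mean"] = pm.tolist()
            if truth is not None:
                results[name]["mse"] = float(np.mean((pm - truth) ** 2))
        else:
            results[name]["status"] = "no-accepted-samples"

    if baseline.count >= 1 and budget.noise_scale_b > 0:
        K_T = float(np.max(np.linalg.norm(thetas, axis=1)))
        bi = BoundInputs(rho, cfg.epsilon_abc, K_T, baseline.count)
        results["theory"] = {
            "expected_error_bound": expected_error_bound(bi, budget.noise_scale_b),
            "mean_flip_probability": float(
                np.mean(flip_probability(rho, cfg.epsilon_abc, budget.noise_scale_b))
            ),
        }
    if truth is not None:
        results["theta_true"] = np.asarray(truth).tolist()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dump_json(results, out / "results.json")
        pd.DataFrame(private.accepted_thetas).to_csv(
            out / "accepted_theta.csv", index=False, header=False
        )
    return results


def sweep(
    cfg: RunConfig,
    c_grid=(10, 100, 1000),
    eps_abc_grid=(0.05, 0.1, 0.2, 0.5),
    eps_total_grid=(0.5, 1.0, 10.0, math.inf),
    resample_modes=(False, True),
    n_seeds: int = 1,
) -> pd.DataFrame:
    """Grid of private-run MSEs over (c, eps_abc, eps_total, resample).

    Distances are simulated once per seed and replayed across the whole
    privacy grid (the stream is public, so this is sound and exact).
    Replicate seeds derive from ``cfg.seed`` by a counter scheme.
    """
    cfg.validate()
    rows = []
    for rep in range(n_seeds):
        sub = RunConfig(**{**cfg.to_dict(), "epsilon_total": math.inf, "seed": cfg.seed + rep})
        master = np.random.default_rng(sub.seed)
        obs_rng, bw_rng, stream_rng, noise_rng = master.spawn(4)
        observed, truth, prior_sampler, data_sampler = _prepare_problem(sub, obs_rng)
        spec = _distance_spec(sub, prior_sampler, data_sampler, bw_rng)
        stream = generate_pair_stream(prior_sampler, data_sampler, sub.T, stream_rng)
        thetas, rho = stream_distances(observed, stream, spec)
        delta_rho = spec.delta_rho(observed.n_points)
        for c in c_grid:
            for eps_abc in eps_abc_grid:
                for eps_total in eps_total_grid:
                    for resample in resample_modes:
                        budget = PrivacyBudget(eps_total, int(c), delta_rho, resample)
                        trace = run_abcdp_from_distances(
                            rho, thetas, eps_abc, budget, noise_rng.spawn(1)[0]
                        )
                        row = {
                            "seed": sub.seed, "c": c, "epsilon_abc": eps_abc,
                            "epsilon_total": eps_total, "resample": resample,
                            "n_accepted": trace.count,
                        }
                        if trace.count > 0 and truth is not None:
                            pm = posterior_mean(trace)
                            row["mse"] = float(np.mean((pm - truth) ** 2))
                        else:
                            row["mse"] = math.nan
                        rows.append(row)
    return pd.DataFrame(rows)


def flip_prob_table(
    N_grid,
    c_grid,
    eps_total_grid,
    eps_abc: float = 0.2,
    rho_samples=None,
    resample: bool = False,
    B_k: float = 1.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Flip probability per (N, c, eps_total, rho) — the guideline surface
    for choosing c given the dataset size and privacy level.

    ``rho_samples`` defaults to 100 Uniform[0, 1] draws.  An infinite budget
    gives flip probability 0 exactly.
    """
    from .privacy import mmd_sensitivity, noise_scale

    if rho_samples is None:
        rng = np.random.default_rng(0) if rng is None else rng
        rho_samples = rng.uniform(0.0, 1.0, size=100)
    rho_samples = np.asarray(rho_samples, dtype=float)
    rows = []
    for N in N_grid:
        delta = mmd_sensitivity(int(N), B_k)
        for c in c_grid:
            for eps_total in eps_total_grid:
                b = noise_scale(float(eps_total), int(c), delta, resample)
                fp = flip_probability(rho_samples, eps_abc, b)
                for r, p in zip(rho_samples, np.atleast_1d(fp)):
                    rows.append(
                        {"N": int(N), "c": int(c), "epsilon_total": float(eps_total),
                         "rho": float(r), "flip_probability": float(p)}
                    )
    return pd.DataFrame(rows)
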