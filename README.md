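# abcdp — differentially private rejection ABC

Likelihood-free (simulation-based) Bayesian inference with a formal privacy
guarantee for the observed data. The package is aimed at settings common in
biostatistics and epidemiological modelling — outbreak case counts,
genotype-derived transmission data — where the *simulator* and its prior are
public but the *observations* are sensitive, and the accept/reject decisions
of approximate Bayesian computation (ABC) would otherwise leak information
about individual records.

## The method

Rejection ABC draws parameters from the prior, simulates a pseudo-dataset
for each draw, and accepts θ_t whenever a distance falls under a threshold:

    τ_t = 1[ ρ(Y*, Y_t) ≤ ε_abc ],   t = 1, …, T.

The observed data Y\* enter only through the distance ρ. This package
privatizes exactly that step, in the style of the sparse vector technique:
the threshold is perturbed once with Laplace(b) noise (optionally redrawn
after every acceptance, the RESAMPLE option) and each distance with
Laplace(2b) noise; the run stops after `c` acceptances. The whole indicator
stream — and, by post-processing invariance, the accepted posterior
samples — is then ε_total-differentially private with

    ε_total = (c + 1) Δρ / b      (RESAMPLE off)
    ε_total = 2 c Δρ / b          (RESAMPLE on)

where Δρ is the global sensitivity of the distance. The default distance is
the (biased, V-statistic) kernel maximum mean discrepancy with a Gaussian
kernel, for which Δρ = 2√B_k / N = 2/N with N the number of private records,
so the noise needed for a fixed budget shrinks as the dataset grows. Only
*accepted* samples cost budget: an arbitrarily long stream of rejections is
free.

The closed-form noise theory ships alongside the sampler: the density and
CDF of the noise difference Lap(b) − Lap(2b), the per-step **flip
probability** G_b(|ρ_t − ε_abc|) that a private indicator disagrees with the
non-private one, and the bounds on the L2 gap between private and
non-private posterior expectations (in expectation and in probability).
Every formula is cross-validated in the test suite against quadrature,
Monte-Carlo sampling and the engine itself.

Two self-contained benchmark simulators are included: a 5-component mixture
of unit uniforms with a Dirichlet(1) prior (known ground truth
θ\* = [0.25, 0.04, 0.33, 0.04, 0.34]), and a cubic outbreak-curve model
y(t) = a₃ + a₂t + a₁t² + a₀t³ with N(0,1) priors over the coefficients,
paired with a synthetic 18-day case-count generator.

## Worked example

```python
import numpy as np
from abcdp import ABCDP, DistanceSpec, KernelSpec
from abcdp.simulators import THETA_STAR, sample_mixture_data, sample_simplex_prior

rng = np.random.default_rng(0)
observed = sample_mixture_data(THETA_STAR, 1000, rng)   # the private data

model = ABCDP(
    observed,
    sample_simplex_prior,                                # public prior
    lambda theta, r: sample_mixture_data(theta, 1000, r),# public simulator
    distance=DistanceSpec(kind="mmd", kernel=KernelSpec(bandwidth=1.26)),
    epsilon_abc=0.05,      # ABC similarity threshold (on root-MMD)
    epsilon_total=10.0,    # total privacy budget
    c=10,                  # at most 10 released posterior samples
)
res = model.fit(T=2000, seed=42)
print(res.summary())
```

prints

```
Approximate Bayesian computation results
==============================================
steps consumed          2000
accepted samples        6
epsilon_total           10.0
Laplace scale b         0.0022
resample threshold      False
sensitivity delta_rho   0.002
posterior mean          [0.2275, 0.0782, 0.2690, 0.0796, 0.3456]
==============================================
```

Six of the 2000 prior draws were (noisily) accepted; the private
posterior-mean estimate of the mixing proportions sits within ~0.06 of the
ground truth in every coordinate, and releasing it consumed at most
ε_total = 10 — here the Laplace scale b = (c+1)Δρ/ε_total = 0.0022 is small
against the threshold 0.05, so the decisions almost never flip
(G_b(gap) ≈ 0 for typical distance gaps). Tightening the budget to
ε_total ≤ 1 visibly inflates the estimation error; `abcdp sweep` maps that
trade-off.

A command-line layer wraps the same pipeline:

```bash
abcdp simulate --model mixture --seed 1 --n 1000 --out obs.csv
abcdp run --config cfg.yaml --seed 7 --out results/
abcdp sweep --config cfg.yaml --seeds 5 --out sweep.csv
abcdp theory flip-prob --n-grid 10,100,1000 --out flip.csv
```

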