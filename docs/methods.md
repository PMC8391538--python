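# Methods

## Model and guarantee

The package implements rejection ABC whose accept/reject indicators are
released under pure ε-differential privacy. The privacy unit is one row of
the observed dataset Y\* (neighbouring datasets differ in a single record).
The mechanism perturbs the two quantities the decision depends on:

* threshold: ε̂_abc = ε_abc + m, m ~ Lap(b), drawn once before the loop and,
  when `resample=True`, redrawn immediately after each acceptance;
* distance: ρ̂_t = ρ(Y\*, Y_t) + ν_t, ν_t ~ Lap(2b), drawn once per step.

A step is accepted when ρ̂_t ≤ ε̂_abc (non-strict; ties are measure-zero
under the noise) and the loop breaks after `c` acceptances. Under linear
composition the run is ε_total-DP with ε_total = (c+1)Δρ/b without
resampling and 2cΔρ/b with it; `abcdp.privacy.noise_scale` inverts these to
calibrate b, and `budget_of_noise_scale` is the exact algebraic inverse.
Only above-threshold (accept) answers consume budget, which is what makes
the approach economical when acceptances are sparse (c ≪ T).

Accepted parameters and indicators are safe to release by post-processing
invariance. Raw and noisy distances are *diagnostics*: the trace retains
them for the theory cross-checks, the CLI logs them only at DEBUG with a
warning, and they must never leave the data owner's side.

## Distance and sensitivity

The default ρ is the square root of the biased (V-statistic) empirical
MMD² — diagonal terms included — under a Gaussian kernel
k(x,y) = exp(−‖x−y‖²/2l²), bounded by B_k = 1 for every bandwidth. The
V-statistic is the squared norm of the difference of empirical mean
embeddings, hence nonnegative, so the root is well defined; tiny negative
values from floating cancellation (> −1e−12) are truncated to zero. For
this ρ the global sensitivity is Δρ = 2√B_k/N and the distance itself never
exceeds 2√B_k; both facts are verified by randomized search in the tests.
The threshold ε_abc applies to the *root* MMD: the bounds above hold on
that scale, and the non-private reduction keeps a single consistent scale
throughout. Unequal dataset sizes are accepted by the estimator, but the
sensitivity that calibrates the noise always uses the private dataset's N.

The kernel bandwidth defaults to the median heuristic — the median pairwise
Euclidean distance over pooled *pseudo-data* points, so it costs no privacy
budget. Pools larger than 1000 points are subsampled with a seeded
generator to bound the quadratic pair enumeration; a zero median (possible
with heavily duplicated points) falls back to the smallest nonzero
distance, and fully degenerate input is an error.

A weighted L2 distance on summary vectors is provided for simulators with
unbounded raw distances, together with distance clipping min(ρ, C). After
clipping, no sensitivity is derivable from first principles, so the package
requires an explicit `delta_rho` there and refuses to guess.

## Noise theory

With Z = m − ν ~ Lap(b) − Lap(2b), independent,

* f_Z(z) = (1/6b)[2e^{−|z|/2b} − e^{−|z|/b}] (derived via characteristic
  functions; verified by quadrature and 10⁶-sample Monte Carlo),
* G_b(a) = P[Z ≥ a] = (1/6)[4e^{−a/2b} − e^{−a/b}], with G_b(0) = 1/2,
* F_Z(a) = H[a] + (1 − 2H[a])G_b(|a|), Heaviside convention H[0] = 1
  (observationally irrelevant at a = 0 since F_Z(0) = 1/2 either way).

The per-step flip probability is P[τ̃_t ≠ τ_t] = G_b(|ρ_t − ε_abc|). At
b = 0 the mechanism is exactly the non-private rule, so the flip
probability is defined as 0 by convention and G/F are never evaluated
there. For an integrand f with K_T = max_t ‖f(θ_t)‖₂ finite (required as a
precondition) and a non-private acceptance count c′ ≥ 1, the expected L2
gap between private and non-private posterior means is bounded by
(2K_T/c′)·Σ_t G_b(|ρ_t − ε_abc|), and P[gap ≤ a] ≥
1 − (4K_T/3ac′)·Σ_t e^{−|ρ_t−ε_abc|/2b}. The tail bound can be negative
(vacuous); it is returned as-is so callers can flag it. Closed forms are
the production path; adaptive quadrature (absolute tolerance 1e−10 in the
oracle tests) is used only for validation.

## Engine conventions

* Noise order is fixed and documented (threshold draw, then one distance
  draw per step, then a threshold redraw after each acceptance if
  resampling), so seeded runs are bit-reproducible; `run_abcdp` on a lazy
  stream and `run_abcdp_from_distances` on precomputed distances follow the
  identical decision path.
* If the stream is exhausted before `c` acceptances the run is valid: the
  claimed ε_total remains an upper bound on the actual loss, and the
  accounting reports the claimed (not recomputed) budget with the achieved
  count alongside.
* The non-private baseline never stops early; the private run does. The two
  are therefore compared at the same T with possibly different acceptance
  counts, which is also the setting of the posterior-error bounds.
* ε_total = ∞ is an explicit sentinel mapping to b = 0, with Laplace draws
  returning exactly 0.0 — the non-private reduction is testable bit for
  bit.

## Synthetic data

The mixture benchmark (Dirichlet(1) prior over 5 mixing proportions,
observations from Σ_i θ_i·Uniform[i−1, i), ground truth
θ\* = [0.25, 0.04, 0.33, 0.04, 0.34]) is sampled in two exact stages —
multinomial component, then uniform within the bin — so occupancy tests
have an exact multinomial reference. The reference configuration uses
N = 5000 observed points and n = 5000 per pseudo-dataset.

The outbreak benchmark generates daily case counts from a cubic trend
y(t) = a₃ + a₂t + a₁t² + a₀t³ on t = 1..18 (18 points, the size typical of
an early outbreak window) with additive Gaussian noise (default sd 5),
rounded and floored at zero; coefficients default to
a = (0.01, −0.1, 2.0, 1.0), all within ~2 prior standard deviations of the
N(0,1) prior. The distance for this model is (clipped) L2 on the count
vector — a deliberate interpretation, since short count series admit no
natural kernel embedding at n = 18. These generators emulate the *shape* of
real surveillance data, not its epidemiology: counts are independent around
a smooth trend, with no day-of-week effects, reporting delays or
overdispersion, so passing tests demonstrate correctness of the mechanism
and calibration, not fitness of the cubic model for real outbreaks.

Stochastic birth–death simulators for endemic-disease transmission are out
of scope; the weighted-L2 + clipping distance with user-supplied
sensitivity is the supported integration point for external simulators of
that kind.

## Test problem sizes

The benchmark rerun in the test suite uses N = n = 1000, T = 2000,
ε_abc = 0.05 and 20 seeds — a scale at which ground-truth recovery by
non-private ABC (mean absolute error < 0.1) and the monotone improvement
of private MSE across ε_total ∈ {0.5, 1, 10, ∞} are both stable. The
release cap is c = 10, the value appropriate to a 2000-step stream with an
sub-1% acceptance rate (larger caps would mostly bind on flipped, i.e.
uninformative, acceptances at tight budgets). Monotonicity is asserted on
seed-averaged MSEs within two standard errors of the paired differences;
strict improvement is required between the tightest and the infinite
budget.

## Known limitations

* Pure ε-DP with linear composition only: no (ε, δ) relaxations, strong /
  Rényi composition, or Gaussian mechanism. For very small N the budget
  grows quickly in c.
* Only the Gaussian kernel ships (the kernel interface admits extension);
  the MMD estimator is the biased V-statistic, not the unbiased
  U-statistic, by design.
* No sequential Monte Carlo ABC: the privacy analysis covers threshold
  indicators, not importance weights.
* No automatic summary-statistic learning; summaries for the weighted-L2
  path are the user's responsibility, as is their sensitivity.
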