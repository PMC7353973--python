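# Methods

## Model and assumptions

The package implements a deterministic, mean-field consumer–resource
model on two equally sized patches. Resources grow logistically and do
not move; consumers have a Type I (linear, non-saturating) functional
response, no interference competition, and are well mixed within each
patch. Consumer movement between patches is fitness-directed: the
per-capita rate from patch j into patch i is Q_ij = β exp(λ(w_i − w_j)),
with fitness w_i = cαR_i − μ the local per-capita growth rate. The
demography switch p ∈ {0, 1} removes or includes consumer birth–death
terms; with p = 0 total consumer density is a conserved quantity of the
flow (the two migration terms are exact negations, so conservation holds
to machine precision in the implemented right-hand side, not merely to
integrator tolerance).

Scope is deliberately limited to two patches, sedentary resources,
Type I consumption and non-oscillatory parameter regimes; saturating
functional responses, travel costs, movement delays and N > 2 patches
are out of scope.

## Parameters

| symbol | meaning | units | default (study core) |
|---|---|---|---|
| r_H, r_L | resource intrinsic growth rates | 1/time | 2, 1 |
| K_H, K_L | resource carrying capacities | density | 100, 50 |
| α | attack rate | 1/(consumer·time) | 0.05 |
| c | conversion efficiency | – | 0.05 |
| μ | consumer mortality | 1/time | 0.1 |
| β | mobility (baseline movement rate) | 1/time | swept |
| λ | fitness sensitivity | time | swept |
| γ | coupling λ = γβ | time² | {0.1, 1, 10} |
| C_T | mean consumer density per patch (p = 0) | density | 15 |

The "high/low" patch labels are fields, never indices; constructing
parameters with the low patch richer than the high one warns (the
equations stay valid, but every downstream column name would silently
mean the opposite patch).

## Numerical choices

* **Integration.** Trajectories use `scipy.integrate.solve_ivp` with the
  stiffness-switching LSODA method at rtol 1e-10 / atol 1e-12 over a
  default horizon of 5000 time units, which is ample for every studied
  parameterization to settle. The derivative field is never clipped;
  instead the solution is monitored and any component below −1e-6
  aborts, separating genuine misuse from floating jitter around zero.
* **Movement-kernel overflow.** The exponent λ(w_i − w_j) is clamped to
  ±700 before exponentiation. At λ = 1000 a transient O(0.1) fitness gap
  would otherwise overflow; the clamp preserves sign and monotonicity,
  and at equilibrium the exponent is always small because fitness gaps
  vanish.
* **Demography-free equilibria.** The flux-balance condition is solved
  in log-ratio form, g(C_H) = ln((2C_T − C_H)/C_H) + 2λcα(R_H − R_L),
  which is strictly decreasing in C_H, by Brent's method on
  (ε, 2C_T − ε), ε = 1e-12·C_T, at xtol 1e-15. A bracketed scalar solve
  on a monotone function is unconditionally convergent, unlike 4-D
  Newton from a poor seed. Solutions with a non-positive resource
  density are rejected (outside the positive-density regime the model
  restricts itself to).
* **General equilibria.** `scipy.optimize.root` (hybr) on the derivative
  field; for p = 0 the solve runs on the reduced 3-D system with
  C_L = 2C_T − C_H eliminated, because the conservation law makes the
  full 4-D field singular at its fixed points. The default seed for
  p = 1 is the no-movement closed form: its fitness gap is exactly zero,
  so the movement exponential starts at 1 for any λ — a seed with
  resources at K/2 puts the λ = 1000 exponent near 60 and the iteration
  diverges. Sweeps seed each grid point with the previous point's
  solution (continuation); on non-convergence the point falls back to a
  horizon-5000 integration whose endpoint is then polished by the root
  solver. Accepted roots must have residual < 1e-10 and no negative
  component.
* **Stability.** Jacobians are central finite differences of the
  implemented right-hand side (step 1e-6·max(1, |x_j|)), validated in
  the tests against the analytic logistic-block entries at the
  extinction and resource-only states. This keeps the classification
  honest against the code actually integrated rather than a separately
  derived matrix. For p = 0 the conserved total contributes a neutral
  direction, so stability is classified on the reduced 3-D system; the
  reported eigenvalue list then has three entries, four otherwise.
* **Cross-checks.** Every sweep re-derives a seeded random ~10% of its
  rows by an independent route — numeric root for analytically computed
  rows, long integration from a perturbed state for numeric rows — and
  requires componentwise agreement within 1e-6. The default seed
  (20200247) makes logs reproducible.
* **Turning points.** The covarying scenario's disparity minimum is
  located by a grid scan and, when interior, refined with SciPy's
  bounded scalar minimizer (golden-section with parabolic steps, xatol
  1e-5) on the continuous equilibrium map. When the discrete argmin
  falls on the first grid point, the bracket is extended toward β = 0
  whenever the zero-movement closed form shows a larger disparity, since
  the true dip can sit below the coarse grid's first point (it does for
  γ = 10).

## Sweep grids

Figure-style sweeps default to: λ on 50 log-spaced points over
[0.01, 20] plus λ = 0 (demography-free and fixed-mobility scenarios);
β on 50 linear points over [0, 10] (fixed-sensitivity scenario) or
(0, 10] (covarying scenario, whose β = 0 endpoint is the closed form).
These ranges are wide enough to show the plateaus and the covarying
reversal; they are configurable per run. Fixed levels follow the
presets: λ ∈ {0.1, 10, 1000}, β ∈ {0.01, 0.1, 1}, γ ∈ {0.1, 1, 10}.
Convergence-time runs start from resources at K/2 and a strongly
unequal 90/10 consumer split, a nondegenerate start chosen so the
timing is not dominated by an accidental near-equilibrium initial
condition.

## What the presets do and do not emulate

The shipped presets are the study parameterizations of an asymmetric
two-patch landscape: a deterministic ODE skeleton with no environmental
stochasticity, no temporal forcing, no individual variation and no
measurement noise. Tests passing on these presets demonstrate the
internal consistency of the solvers and the qualitative movement–
demography interaction (equal split under random movement, IFD limits,
the regional-density trichotomy, the covarying reversal); they say
nothing about parameter ranges that produce oscillations (excluded from
scope) or about how real census data would constrain the parameters.

## Known limitations

* At extreme fitness sensitivity (λ = 1000) the equilibrium with any
  β > 0 carries a small finite-λ offset from the immobile closed form —
  about 3% in the smallest component C_L* for the study parameters,
  nearly independent of β. The λ → ∞ limit does recover the closed form
  exactly; "mobility has little effect at large λ" is therefore true of
  variation *across* β but the curves sit a few percent off the β = 0
  intercept.
* The implicit p = 0 solver requires β > 0: without movement the
  demography-free model has a continuum of fixed points (any split is
  stationary), so "the" equilibrium is undefined there.
* Stability classification is local (eigenvalues at the fixed point);
  basins of attraction are probed only indirectly through the
  integration cross-checks.
* Finite-difference Jacobians carry O(h²) truncation error; eigenvalues
  are accurate to roughly 1e-9 on O(1) entries, far below the margins by
  which the studied equilibria are stable.
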