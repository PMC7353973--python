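# twopatch

Simulation and equilibrium analysis of a two-patch consumer–resource
system in which consumers move between patches at a rate that depends on
both their baseline mobility and their sensitivity to fitness
differences.

## The problem

How animals distribute themselves over a heterogeneous landscape depends
on two distinct movement traits: *mobility* — how often an individual
moves at all — and *fitness sensitivity* — how strongly its movement is
biased toward the patch currently offering higher fitness. Classic
habitat-selection theory treats these as independent and predicts that
they pull in opposite directions: sensitivity drives the system toward
an ideal free distribution (IFD, equal fitness in all occupied patches),
while mobility acts as random mixing that pulls it away. In real animals
the two traits are often positively correlated (more mobile animals
sample their environment more and perceive quality gradients better),
and this package exists to quantify what that correlation does to
consumer and resource distributions, both with and without consumer
birth–death dynamics.

## The model

Two equally sized patches, a high-quality one (H) and a low-quality one
(L). Resources R_i grow logistically and are immobile; consumers C_i
feed with a Type I (linear) functional response and migrate:

    dR_H/dt = r_H R_H (1 − R_H/K_H) − α R_H C_H
    dR_L/dt = r_L R_L (1 − R_L/K_L) − α R_L C_L
    dC_H/dt = p (cα R_H − μ) C_H + C_L Q_HL − C_H Q_LH
    dC_L/dt = p (cα R_L − μ) C_L + C_H Q_LH − C_L Q_HL

with consumer fitness w_i = cα R_i − μ (the local per-capita growth
rate) and the movement kernel

    Q_ij = β exp(λ (w_i − w_j)),

where β is mobility, λ is fitness sensitivity, and p ∈ {0, 1} switches
consumer demography off or on. Correlated movement traits are modelled
by slaving λ = γβ with γ > 0.

Key analytical structure the package implements:

* **p = 1, β = 0** (demography, no movement): patches decouple;
  R* = μ/(cα) in both patches and C_i* = (r_i/α)(1 − μ/(cα K_i))
  — fitness is zero everywhere, an IFD produced by demography alone.
* **p = 0** (movement, no demography): total consumers 2 C_T are
  conserved and the unique stable equilibrium satisfies the migration
  flux balance C_L* Q_HL = C_H* Q_LH, i.e.
  C_L*/C_H* = exp(−2λcα (R_H* − R_L*)) with each resource on its
  nullcline R_i* = K_i (1 − α C_i*/r_i). The fixed point depends on λ
  but not on β; β only sets the convergence speed.
* **p = 1, β > 0**: no closed form; equilibria come from numerical
  root-finding cross-validated against long integration, with stability
  classified from the Jacobian eigenvalues.

## Worked example

Equilibrium of the demography-free system (preset `fig1`: r_H=2, r_L=1,
K_H=100, K_L=50, c=α=0.05, μ=0.1, C_T=15) at fitness sensitivity λ=4:

```
$ twopatch equilibrium --preset fig1 --lam 4
{
  "R_H": 51.9526434662539,
  "R_L": 23.047356533746104,
  "C_H": 19.21894261349844,
  "C_L": 10.781057386501558,
  "w_H": 0.029881608665634773,
  "w_L": -0.042381608665634736,
  "residual": 7.105427357601002e-15,
  "stable": true,
  "method": "implicit_no_demography",
  ...
}
```

Consumers over-match the high-quality patch (19.2 vs 10.8 per patch,
against an equal 15/15 split at λ=0) but the fitness gap has not yet
closed (w_H > 0 > w_L): λ=4 sits part-way between random mixing and the
IFD limit. The residual confirms a fixed point of the full dynamics.

With demography on and movement traits covarying (λ = γβ), the
between-patch consumer disparity C_H* − C_L* starts at 20 (the immobile
demographic equilibrium: 24 vs 4), initially shrinks as movement mixes
consumers, then recovers once fitness-directed movement dominates:

```python
from twopatch import covary_disparity_minimum, figure_presets
params = figure_presets()["fig5"].params
for gamma in (0.1, 1.0, 10.0):
    beta, d = covary_disparity_minimum(params, gamma)
    print(f"gamma={gamma:>4}: minimum disparity {d:.3f} consumers/patch "
          f"at beta = {beta:.3f}")
```

prints

```
gamma= 0.1: minimum disparity 1.073 consumers/patch at beta = 1.580
gamma= 1.0: minimum disparity 3.120 consumers/patch at beta = 0.498
gamma=10.0: minimum disparity 7.433 consumers/patch at beta = 0.155
```

— the stronger the coupling γ, the earlier (and shallower) the turn back
toward fitness-directed behaviour.

The `twopatch sweep --preset fig3` (and `fig1`, `fig2_*`, `fig4`,
`fig5`) commands write the full tidy equilibrium tables behind these
summaries as CSV.

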