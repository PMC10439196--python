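# stochprey

Numerical simulator for a **stochastic ratio-dependent predator–prey
reaction–diffusion system** in one space dimension, aimed at ecological
modellers who need population-density solutions that stay nonnegative.

The model couples prey density P(x, t) and predator density Q(x, t):

```
∂P/∂t = σ₁ ∂²P/∂x² + P(a − bP) − cPQ/(mQ + P) + η₁ P Ḃ₁(t)
∂Q/∂t = σ₂ ∂²Q/∂x² − dQ + fPQ/(mQ + P) + η₂ Q Ḃ₂(t)
```

with homogeneous Neumann boundaries.  Here a is the prey growth rate, a/b the
carrying capacity, c the capturing rate, m the half-saturation constant, f the
conversion rate, d the predator death rate, σᵢ diffusion coefficients and ηᵢ
the strengths of multiplicative time noise driven by Wiener processes B₁, B₂.
The functional response cPQ/(mQ+P) is *ratio-dependent*: predation saturates
in the prey-to-predator ratio rather than in prey density alone.

The package provides:

* **Two explicit schemes** — a stochastic forward Euler scheme (`sfe`,
  conditionally stable, can produce negative or divergent densities) and a
  Mickens-type stochastic non-standard finite difference scheme (`nsfd`),
  whose loss terms sit in the update's denominator so nonnegative data stay
  nonnegative for *any* step sizes.
* **Equilibrium and bifurcation analysis** — the predator-free state
  (a/b, 0), the coexistence point
  P\* = ((am−c)f + cd)/(bmf), Q\* = (f−d)(amf−cf+cd)/(bdm²f),
  the stability criterion Λ = (c−mf)d² − (c−ma−md)f² (stable for Λ > 0), and
  the closed-form threshold f\* where Λ changes sign.
* **Von Neumann stability analysis** — per-frequency amplification factors
  and the smallest constant χ with E|g|² ≤ 1 + χΔτ.
* **Diagnostics** — steady-state distance, positivity/divergence reports,
  oscillation metrics, strong self-convergence under coupled Brownian-path
  refinement, and an empirical mean-square consistency check against
  manufactured profiles.

## Worked example

```python
from stochprey import equilibria, get_preset, run_preset
import numpy as np

preset = get_preset("fig1_coexistence")        # f=0.79, stable coexistence
print(equilibria(preset.params).coexistence_point)
# (0.4701627486437614, 0.2726943942133816)

finals = []
for seed in range(10):
    res = run_preset("fig1_coexistence", "nsfd", seed)
    finals.append((res.mean_P[-500:].mean(), res.mean_Q[-500:].mean()))
print(np.mean(finals, axis=0))
# [0.47773228 0.27279564]
```

The ensemble mean of the space-averaged densities over the final 10% of a
5000-step NSFD run, (0.478, 0.273), sits on the closed-form coexistence point
(0.470, 0.273) up to the O(Δτ, η) bias of the scheme — the population settles
at stable coexistence.  Lowering the conversion rate below the death rate
(f = 0.4 < d = 0.5) starves the predator out; raising it to f = 0.84 pushes
the system past the stability threshold f\* ≈ 0.80475 and on to joint
extinction.  The `examples/` scripts walk through each capability:
equilibria/regimes, the coexistence run, the forward-Euler/NSFD dichotomy at
a large diffusion number, the convergence study, and the consistency check.

A thin CLI mirrors the library:

```sh
stochprey simulate --preset fig9_stiff_diffusion --scheme nsfd --seed 1 --out runs/fig9
stochprey equilibria --config run.yaml
stochprey stability --config run.yaml --scheme sfe
```

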