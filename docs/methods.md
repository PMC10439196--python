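# Methods

## Model

The simulator integrates a ratio-dependent predator–prey system on an
interval [0, L] with no-flux (homogeneous Neumann) boundaries:

    ∂P/∂t = σ₁ P_xx + P(a − bP) − c PQ/(mQ + P) + η₁ P Ḃ₁(t)
    ∂Q/∂t = σ₂ Q_xx − d Q + f PQ/(mQ + P) + η₂ Q Ḃ₂(t)

The noise is **multiplicative in the state and scalar in space**: B₁ and B₂
are functions of time only, so one Gaussian increment per species per step is
applied identically at every node.  This models environment-wide fluctuation
(weather, resource pulses) rather than local demographic noise; it is *not* a
space–time white-noise field, and spatial roughening driven by noise is
outside the model class.  By default the two species are driven by
independent Wiener processes; a `shared` mode drives both with a single
process.

The functional response PQ/(mQ+P) is extended by the exact branch
PQ/(mQ+P) := 0 at mQ+P = 0 (no epsilon smoothing), which makes the
extinction state (0, 0) a bit-exact fixed point of the drift and of both
discrete schemes.

### Equilibria and regimes

The predator-free equilibrium is (a/b, 0) — the root of the prey drift.
Parts of the literature label this state "(1, 0)"; the report carries that
label but all quantitative checks use a/b.  The coexistence point

    P* = ((am − c)f + cd)/(bmf),   Q* = (f − d)(amf − cf + cd)/(bdm²f)

exists iff f > d and (am − c)f + cd > 0, and is classified by the sign of

    Λ = (c − mf)d² − (c − ma − md)f²

(stable for Λ > 0, unstable for Λ < 0; "neutral" is declared only at exact
zero — callers choose their own tolerances).  Λ is quadratic in the
conversion rate f, so the loss-of-stability threshold f* is found in closed
form; for the bundled coefficient set (a=1.1, b=0.7, c=2.1, m=1, d=0.5) it is
f* ≈ 0.80475.  Near-threshold behaviour under noise and diffusion is
ambiguous and the package makes no claim that the criterion predicts the
oscillation onset exactly at f*.

## Discretization

Uniform grid with n intervals (n+1 nodes, x_m = mh, h = L/n), time levels
t_k = kΔτ, diffusion numbers D_i = Δτσ_i/h².  Neumann boundaries use
second-order ghost reflection (node −1 ↦ node 1, node n+1 ↦ node n−1).

**Stochastic forward Euler (SFE)** — forward-time centred-space with an
Euler–Maruyama noise term; the step-k increment multiplies the step-k state:

    P^{k+1} = D₁(P_{m+1}+P_{m−1}) + (1−2D₁)P + ΔτP(a−bP) − cΔτ·r + η₁P·ΔB₁
    Q^{k+1} = D₂(Q_{m+1}+Q_{m−1}) + (1−2D₂−dΔτ)Q + fΔτ·r + η₂Q·ΔB₂

with r = PQ/(mQ+P).  Outputs are deliberately **not** clipped or projected to
nonnegative values: reproducing the scheme's failure modes (negative
densities, blow-up at large D) is part of this package's purpose.

**Non-standard finite difference (NSFD)** — Mickens construction: every loss
term (self-limitation, predation, death, the implicit part of the stencil)
moves to the denominator:

    P^{k+1} = [D₁(P_{m+1}+P_{m−1}) + (1+aΔτ)P + η₁P·ΔB₁]
              / [1 + 2D₁ + bΔτP + cΔτ·Q/(mQ+P)]
    Q^{k+1} = [D₂(Q_{m+1}+Q_{m−1}) + Q + fΔτ·r + η₂Q·ΔB₂]
              / [1 + 2D₂ + dΔτ]

With ΔB = 0 both updates are ratios of nonnegative quantities, so positivity
holds unconditionally in (Δτ, h).  The predator numerator carries the current
value Q_m^k; this term is required for consistency (without it a constant
field would collapse by a factor ≈ 1/(1+2D₂+dΔτ) per step) and matches the
scheme's own linearized form used in the stability analysis.  With noise the
numerator can turn negative only in the measure-zero-practical event
|η·ΔB| > 1 + aΔτ (prey) or a comparably large draw (predator); at the
bundled η = 0.01, Δτ = 0.1 this is a >300σ event, so positivity holds for all
practical paths.

### Spatial homogeneity and the divergence demonstration

Exactly constant profiles form an invariant manifold of both schemes under
time-only noise: the stencil sees identical neighbours at every node
(including the boundaries, via ghost reflection), so every node performs the
same arithmetic and remains identical — in floating point as well as exactly.
A diffusion-driven instability is invisible on that manifold.  The
`fig9_stiff_diffusion` preset (D = 3.6) therefore seeds the highest-frequency
Neumann-compatible grid mode, amp·cos(nπx/L) with amp = 10⁻⁶, on top of the
constant initial data; this is the package's chosen stand-in for the
inhomogeneity any practical computation carries, and it leaves the initial
profiles at 0.6/0.4 to six decimals.  All other presets use exactly constant
initial data.

## Noise generation

A single integer master seed yields fixed per-species substreams
(`SeedSequence` spawn keys), so one number reproduces a run.
`refine_increments` draws conditionally correct finer increments given a
coarse path (Brownian-bridge conditional law) and enforces exact block sums,
which couples step-halved runs to the same Brownian path for strong
self-convergence studies.

## Stability analysis

Linearizing each equation (growth aP for prey, decay −dQ for the predator,
coupling dropped) and inserting a Fourier mode gives per-frequency
deterministic amplification factors

    SFE:   g_P = 1 + aΔτ − 4D₁ sin²(θ/2),      g_Q = 1 − dΔτ − 4D₂ sin²(θ/2)
    NSFD:  g_P = (1 + 2D₁ + aΔτ − 4D₁ sin²(θ/2))/(1 + 2D₁)
           g_Q = (1 + 2D₂ − 4D₂ sin²(θ/2))/(1 + 2D₂ + dΔτ)

The mean-square criterion used for verdicts is the relaxed bound
E|g|² ≤ 1 + χΔτ.  The report computes the worst |g_det|² over a uniform
θ-grid on [0, π] (1025 points by default; g is affine in sin²(θ/2), so the
extrema sit at the endpoints and the grid is generous), converts it to the
smallest admissible χ, and adds the noise contribution — |η|² for SFE and
|η/denominator|² for NSFD, as the factors above imply.  The verdict compares
this minimal χ against a tolerance, default

    χ_tol = η₁² + η₂² + 2·max(a, d) + 1,

which admits the O(Δτ) reaction-driven growth any explicit scheme exhibits
(χ ≈ 2a at θ=0) while rejecting diffusion-driven blow-up (χ ~ (4D−2)²/Δτ).
The literal hard bound |g_det|² ≤ 1 is reported separately as informational:
it cannot hold at θ = 0 for a growing species, and the NSFD prey factor
exceeds 1 at θ = 0 by exactly aΔτ/(1+2D₁) — bounded growth, not instability.
The NSFD predator factor satisfies |g| < 1 for all θ and all admissible
parameters.

## Diagnostics

* **Steady-state distance** — nodewise time averages over the final window
  (default 10% of steps, taken over the stored snapshots), sup over nodes,
  max over species, against a reference point.
* **Oscillation metrics** — after discarding the first 20% of a probe series
  as transient (the model prescribes no burn-in; 20% is a fixed choice),
  counts strict sign changes about a reference level and averages the peak
  excursion between consecutive crossings.
* **Strong self-convergence** — RMS terminal gap between runs at Δτ and Δτ/2
  driven by the same Brownian path (coupled via `refine_increments`),
  averaged over paths; the noise-free limit shows the expected first-order
  halving.
* **Empirical mean-square consistency** — one-step residual between the
  continuous operator applied to a smooth manufactured profile (time
  integrals by composite trapezoid quadrature at 64 panels per step — far
  below the residual being measured — and the stochastic integral by a
  left-point Itô sum on fine increments whose sum is exactly the step draw)
  and the discrete scheme operator on the same samples, averaged over
  interior nodes and noise draws.  On a refinement sequence with Δτ ∝ h² the
  residual decreases for both schemes; for profiles constant in space and
  time the two operators coincide and the residual vanishes identically.
  This is an empirical counterpart to the schemes' mean-square consistency,
  not an order-of-convergence claim.

## Default problem sizes

The bundled presets use the full experiment grids (L=30, n=100, Δτ=0.1,
N=5000, initial P≡0.6, Q≡0.4; the predator-free preset uses Δτ=0.01, and the
divergence demo L=10, n=60).  The convergence and consistency studies in the
tests and examples use shorter horizons (T=5, 40 intervals, 8 paths; one-step
residuals at n=20..80): these quantities stabilize at small problem sizes,
and the package treats them as its standard study sizes.

## Known limitations

* Noise scalar in space only; no Q-Wiener/cylindrical space–time noise.
* Scalar (per-species) Von Neumann analysis; the coupled system's matrix
  analysis and any rigorous nonlinear stability statement are out of scope.
* Explicit schemes only; no implicit, splitting, or adaptive stepping; 1-D
  geometry with Neumann boundaries only.
* The synthetic experiments start from spatially constant data, so passing
  tests say nothing about pattern formation from structured initial data.
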