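"""Spatial grid, the two time-stepping schemes, and the simulation loop.

Two explicit schemes advance the stochastic reaction-diffusion system on a
uniform 1-D grid with homogeneous Neumann boundaries (ghost reflection):

* ``sfe_step`` — stochastic forward Euler: forward-time centred-space stencil
  plus an Euler-Maruyama multiplicative-noise increment.  Conditionally
  stable; deliberately NOT clipped to nonnegative values, so its failure
  modes (negative densities, blow-up at large diffusion numbers) are
  observable.
* ``nsfd_step`` — stochastic non-standard finite difference (Mickens
  construction): every loss term is moved into the update's denominator, so
  nonnegative input gives nonnegative output for ANY step sizes.

The noise is scalar in space: one increment per species per step multiplies
the current state value at every node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .model import ModelParameters
from .noise import NoiseIncrements

__all__ = [
    "Discretization",
    "FieldState",
    "SimulationResult",
    "make_initial_state",
    "sfe_step",
    "nsfd_step",
    "simulate",
]

DEFAULT_DIVERGENCE_CAP = 1.0e6


@dataclass(frozen=True)
class Discretization:
    """Uniform space-time grid: n intervals (n+1 nodes) on [0, L], N steps.

    The diffusion numbers D_i = delta_tau * sigma_i / h^2 are derived
    properties, never stored, so they cannot drift out of sync with the grid.
    """

    domain_length: float
    n_intervals: int
    delta_tau: float
    n_steps: int

    def __post_init__(self) -> None:
        if self.domain_length <= 0:
            raise ValueError("domain_length must be positive")
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")
        if self.delta_tau <= 0:
            raise ValueError("delta_tau must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def h(self) -> float:
        return self.domain_length / self.n_intervals

    @property
    def final_time(self) -> float:
        return self.n_steps * self.delta_tau

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(0.0, self.domain_length, self.n_intervals + 1)

    def diffusion_numbers(self, p: ModelParameters) -> Tuple[float, float]:
        h2 = self.h * self.h
        return self.delta_tau * p.sigma1 / h2, self.delta_tau * p.sigma2 / h2


@dataclass
class FieldState:
    """Prey/predator density profiles at one time level."""

    step: int
    P: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        if self.P.shape != self.Q.shape or self.P.ndim != 1:
            raise ValueError("P and Q must be 1-D arrays of equal length")


@dataclass
class SimulationResult:
    """Trajectory summary plus provenance and positivity/divergence diagnostics.

    ``probe_P``/``probe_Q`` hold the full time series at one node;
    ``mean_P``/``mean_Q`` the space-averaged series (both length
    completed_steps+1 including the initial level).  ``snapshots`` stacks the
    full profiles at ``snapshot_steps`` with axes (time, node, species).
    """

    scheme: str
    params: ModelParameters
    disc: Discretization
    seed: Optional[int]
    probe_node: int
    times: np.ndarray
    probe_P: np.ndarray
    probe_Q: np.ndarray
    mean_P: np.ndarray
    mean_Q: np.ndarray
    snapshot_steps: np.ndarray
    snapshots: np.ndarray
    final_state: FieldState
    min_value: float
    negative_count: int
    diverged: bool
    divergence_step: Optional[int]
    completed_steps: int
    divergence_cap: float = DEFAULT_DIVERGENCE_CAP
    preset: Optional[str] = field(default=None)


def make_initial_state(
    disc: Discretization, P0: float, Q0: float, perturbation: float = 0.0
) -> FieldState:
    """Constant initial profiles P=P0, Q=Q0 at every node.

    ``perturbation`` optionally adds amp*cos(n*pi*x/L) — the highest-frequency
    Neumann-compatible grid mode, i.e. an alternating +/-amp pattern — to both
    profiles.  Exactly constant data is an invariant manifold of both schemes
    under time-only noise, so demonstrating a spatial instability requires a
    nonzero spatial seed; the default is the unperturbed constant state.
    """
    if P0 < 0 or Q0 < 0:
        raise ValueError("initial densities must be nonnegative")
    n_nodes = disc.n_intervals + 1
    P = np.full(n_nodes, float(P0))
    Q = np.full(n_nodes, float(Q0))
    if perturbation != 0.0:
        mode = perturbation * np.cos(np.arange(n_nodes) * np.pi)  # (-1)^m pattern
        P = P + mode
        Q = Q + mode
        if P.min() < 0 or Q.min() < 0:
            raise ValueError("perturbation drives an initial density negative")
    return FieldState(step=0, P=P, Q=Q)


def _neighbor_sum(u: np.ndarray) -> np.ndarray:
    """u_{m+1} + u_{m-1} with Neumann ghost reflection (-1 -> 1, n+1 -> n-1)."""
    s = np.empty_like(u)
    s[1:-1] = u[2:] + u[:-2]
    s[0] = 2.0 * u[1]
    s[-1] = 2.0 * u[-2]
    return s


def _ratio(P: np.ndarray, Q: np.ndarray, m: float) -> np.ndarray:
    """Elementwise P*Q/(m*Q+P) with the exact guard := 0 where m*Q+P == 0."""
    denom = m * Q + P
    out = np.zeros_like(denom)
    np.divide(P * Q, denom, out=out, where=denom != 0.0)
    return out


def sfe_step(
    state: FieldState,
    p: ModelParameters,
    disc: Discretization,
    dB1: float,
    dB2: float,
) -> FieldState:
    """One stochastic forward Euler step.

    P' = D1 (P_{m+1}+P_{m-1}) + (1-2D1) P + dt*P(a-bP) - c*dt*PQ/(mQ+P) + eta1*P*dB1
    Q' = D2 (Q_{m+1}+Q_{m-1}) + (1-2D2-d*dt) Q + f*dt*PQ/(mQ+P) + eta2*Q*dB2

    No positivity projection is applied: negative or unbounded outputs are a
    documented property of this scheme outside its stability region.
    """
    D1, D2 = disc.diffusion_numbers(p)
    dt = disc.delta_tau
    P, Q = state.P, state.Q
    r = _ratio(P, Q, p.m)
    P_new = (
        D1 * _neighbor_sum(P)
        + (1.0 - 2.0 * D1) * P
        + dt * P * (p.a - p.b * P)
        - p.c * dt * r
        + p.eta1 * P * dB1
    )
    Q_new = (
        D2 * _neighbor_sum(Q)
        + (1.0 - 2.0 * D2 - p.d * dt) * Q
        + p.f * dt * r
        + p.eta2 * Q * dB2
    )
    return FieldState(step=state.step + 1, P=P_new, Q=Q_new)


def nsfd_step(
    state: FieldState,
    p: ModelParameters,
    disc: Discretization,
    dB1: float,
    dB2: float,
) -> FieldState:
    """One stochastic non-standard finite difference step.

    P' = [D1 (P_{m+1}+P_{m-1}) + (1+a*dt) P + eta1*P*dB1]
         / [1 + 2D1 + b*dt*P + c*dt*Q/(mQ+P)]
    Q' = [D2 (Q_{m+1}+Q_{m-1}) + Q + f*dt*PQ/(mQ+P) + eta2*Q*dB2]
         / [1 + 2D2 + d*dt]

    Loss terms sit in the denominators, so with dB=0 the update maps
    nonnegative states to nonnegative states for any (dt, h).  The predator
    numerator carries the current value Q_m^k (consistent with the scheme's
    linearized form); without it a constant field would collapse in one step.
    """
    D1, D2 = disc.diffusion_numbers(p)
    dt = disc.delta_tau
    P, Q = state.P, state.Q
    r = _ratio(P, Q, p.m)
    # Q/(mQ+P) guard mirrors the ratio guard (0 at the origin)
    denom_pq = p.m * Q + P
    q_over = np.zeros_like(denom_pq)
    np.divide(Q, denom_pq, out=q_over, where=denom_pq != 0.0)
    P_new = (D1 * _neighbor_sum(P) + (1.0 + p.a * dt) * P + p.eta1 * P * dB1) / (
        1.0 + 2.0 * D1 + p.b * dt * P + p.c * dt * q_over
    )
    Q_new = (D2 * _neighbor_sum(Q) + Q + p.f * dt * r + p.eta2 * Q * dB2) / (
        1.0 + 2.0 * D2 + p.d * dt
    )
    return FieldState(step=state.step + 1, P=P_new, Q=Q_new)


_STEPPERS = {"sfe": sfe_step, "nsfd": nsfd_step}


def simulate(
    scheme: str,
    p: ModelParameters,
    disc: Discretization,
    init: FieldState,
    noise: NoiseIncrements,
    probe_node: Optional[int] = None,
    snapshot_stride: Optional[int] = None,
    divergence_cap: float = DEFAULT_DIVERGENCE_CAP,
    seed: Optional[int] = None,
) -> SimulationResult:
    """Advance ``init`` N steps (or until divergence) and collect diagnostics.

    Divergence means a non-finite value or a magnitude above
    ``divergence_cap``; the loop halts there and records the offending step.
    The probe series is recorded every step, full-profile snapshots every
    ``snapshot_stride`` steps (default ~N/50), and the space-averaged series
    every step.
    """
    if scheme not in _STEPPERS:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {sorted(_STEPPERS)}")
    n_nodes = disc.n_intervals + 1
    if len(init.P) != n_nodes:
        raise ValueError("initial state does not match the discretization")
    if noise.n_steps < disc.n_steps:
        raise ValueError("noise path shorter than the number of steps")
    if abs(noise.delta_tau - disc.delta_tau) > 1e-12 * disc.delta_tau:
        raise ValueError("noise delta_tau does not match the discretization")
    if probe_node is None:
        probe_node = disc.n_intervals // 2
    if not 0 <= probe_node < n_nodes:
        raise ValueError("probe node outside the grid")
    if snapshot_stride is None:
        snapshot_stride = max(1, disc.n_steps // 50)

    step_fn = _STEPPERS[scheme]
    N = disc.n_steps
    probe_P = np.empty(N + 1)
    probe_Q = np.empty(N + 1)
    mean_P = np.empty(N + 1)
    mean_Q = np.empty(N + 1)
    snap_steps = [0]
    snaps = [np.stack([init.P, init.Q], axis=-1)]

    state = FieldState(step=init.step, P=init.P.copy(), Q=init.Q.copy())
    probe_P[0], probe_Q[0] = state.P[probe_node], state.Q[probe_node]
    mean_P[0], mean_Q[0] = state.P.mean(), state.Q.mean()
    min_value = float(min(state.P.min(), state.Q.min()))
    negative_count = int((state.P < 0).sum() + (state.Q < 0).sum())
    diverged = False
    divergence_step: Optional[int] = None
    completed = 0

    for k in range(N):
        state = step_fn(state, p, disc, noise.dB1[k], noise.dB2[k])
        completed = k + 1
        probe_P[completed], probe_Q[completed] = state.P[probe_node], state.Q[probe_node]
        with np.errstate(invalid="ignore"):
            mean_P[completed], mean_Q[completed] = state.P.mean(), state.Q.mean()
        finite = np.isfinite(state.P).all() and np.isfinite(state.Q).all()
        if finite:
            lo = float(min(state.P.min(), state.Q.min()))
            hi = float(max(np.abs(state.P).max(), np.abs(state.Q).max()))
            min_value = min(min_value, lo)
            negative_count += int((state.P < 0).sum() + (state.Q < 0).sum())
        if (completed % snapshot_stride == 0) or completed == N:
            snap_steps.append(completed)
            snaps.append(np.stack([state.P, state.Q], axis=-1))
        if not finite or hi > divergence_cap:
            diverged = True
            divergence_step = completed
            if snap_steps[-1] != completed:
                snap_steps.append(completed)
                snaps.append(np.stack([state.P, state.Q], axis=-1))
            break

    n_rec = completed + 1
    return SimulationResult(
        scheme=scheme,
        params=p,
        disc=disc,
        seed=seed if seed is not None else noise.seed,
        probe_node=probe_node,
        times=np.arange(n_rec) * disc.delta_tau,
        probe_P=probe_P[:n_rec],
        probe_Q=probe_Q[:n_rec],
        mean_P=mean_P[:n_rec],
        mean_Q=mean_Q[:n_rec],
        snapshot_steps=np.array(snap_steps),
        snapshots=np.stack(snaps),
        final_state=state,
        min_value=min_value,
        negative_count=negative_count,
        diverged=diverged,
        divergence_step=divergence_step,
        completed_steps=completed,
        divergence_cap=divergence_cap,
    )
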