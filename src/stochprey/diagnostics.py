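"""Convergence, positivity, oscillation, and mean-square consistency diagnostics.

These operations quantify the qualitative claims made about the two schemes:
approach to a steady state, positivity preservation (or its failure),
oscillatory regimes, strong self-convergence under coupled Brownian-path
refinement, and an empirical mean-square consistency check against a smooth
manufactured solution profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

from .model import ModelParameters, reaction_terms
from .noise import NoiseIncrements, refine_increments, wiener_increments
from .schemes import Discretization, FieldState, SimulationResult, simulate

__all__ = [
    "ConvergenceTable",
    "PositivityReport",
    "ManufacturedProfile",
    "steady_state_distance",
    "positivity_divergence_report",
    "oscillation_metrics",
    "strong_self_convergence",
    "empirical_consistency",
    "default_manufactured_profiles",
    "reference_reaction_trajectory",
]


@dataclass(frozen=True)
class ConvergenceTable:
    """Terminal discrepancies between consecutive step-size refinement levels."""

    delta_taus: np.ndarray        # n_levels values, halving
    discrepancies: np.ndarray     # n_levels - 1 RMS terminal gaps
    log2_ratios: np.ndarray       # n_levels - 2 observed orders


@dataclass(frozen=True)
class PositivityReport:
    min_value: float
    negative_count: int
    diverged: bool
    divergence_step: Optional[int]


def steady_state_distance(
    result: SimulationResult,
    point: Tuple[float, float],
    window_fraction: float = 0.1,
) -> float:
    """Sup-over-nodes distance of windowed time averages from a target point.

    Each node's densities are averaged over the snapshots falling in the final
    ``window_fraction`` of completed steps; the distance is the worse, over
    the two species, of the largest nodewise deviation from ``point``.
    """
    if not 0.0 < window_fraction <= 1.0:
        raise ValueError("window_fraction must lie in (0, 1]")
    if result.diverged:
        raise ValueError(
            "result is divergent; use positivity_divergence_report instead"
        )
    cutoff = (1.0 - window_fraction) * result.completed_steps
    mask = result.snapshot_steps >= cutoff
    if not mask.any():
        mask[-1] = True
    window = result.snapshots[mask]          # (n_snap, node, species)
    avg = window.mean(axis=0)
    dP = float(np.abs(avg[:, 0] - point[0]).max())
    dQ = float(np.abs(avg[:, 1] - point[1]).max())
    return max(dP, dQ)


def positivity_divergence_report(result: SimulationResult) -> PositivityReport:
    """Positivity and divergence summary accumulated over every iterate."""
    return PositivityReport(
        min_value=result.min_value,
        negative_count=result.negative_count,
        diverged=result.diverged,
        divergence_step=result.divergence_step,
    )


def oscillation_metrics(
    series: np.ndarray, reference: float, transient_fraction: float = 0.2
) -> Tuple[int, float]:
    """(crossing count, mean amplitude) of a probe series about a reference level.

    The first ``transient_fraction`` of the series is discarded as burn-in.
    Crossings are strict sign changes of series - reference; the amplitude is
    the mean, over the segments between consecutive crossings, of the largest
    absolute excursion within the segment.  A constant series gives (0, 0).
    """
    series = np.asarray(series, dtype=float)
    if series.size < 10:
        raise ValueError("series too short (need >= 10 points)")
    start = int(np.floor(transient_fraction * series.size))
    dev = series[start:] - reference
    sign = np.sign(dev)
    # carry the previous sign across exact zeros so touching the reference
    # does not double-count
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    change = np.nonzero(sign[1:] * sign[:-1] < 0)[0] + 1
    n_crossings = int(change.size)
    if n_crossings < 2:
        return n_crossings, 0.0
    seg_peaks = [
        np.abs(dev[change[i]:change[i + 1]]).max() for i in range(n_crossings - 1)
    ]
    return n_crossings, float(np.mean(seg_peaks))


def strong_self_convergence(
    scheme: str,
    p: ModelParameters,
    disc: Discretization,
    init: FieldState,
    n_levels: int = 3,
    n_paths: int = 8,
    seed: int = 0,
    noise_mode: str = "independent",
) -> ConvergenceTable:
    """Terminal RMS gaps between step-halved runs driven by the SAME Brownian path.

    Level l uses delta_tau/2^l and 2^l * N steps on the identical spatial
    grid; the fine increments are conditional refinements of the coarse ones,
    so consecutive levels see the same underlying noise and their terminal
    difference measures pure time-discretization error.
    """
    if n_levels < 2:
        raise ValueError("need at least two refinement levels")
    if n_paths < 1:
        raise ValueError("need at least one path")
    ss = np.random.SeedSequence(seed)
    path_seeds = [int(s) for s in ss.generate_state(2 * n_paths)[:n_paths] % (2**31)]

    delta_taus = disc.delta_tau / 2.0 ** np.arange(n_levels)
    sq_gaps = np.zeros(n_levels - 1)
    for ps in path_seeds:
        noise = wiener_increments(disc.n_steps, disc.delta_tau, ps, noise_mode)
        terminals = []
        for level in range(n_levels):
            d_l = Discretization(
                disc.domain_length,
                disc.n_intervals,
                disc.delta_tau / 2**level,
                disc.n_steps * 2**level,
            )
            res = simulate(scheme, p, d_l, init, noise, seed=ps)
            terminals.append(np.stack([res.final_state.P, res.final_state.Q]))
            if level < n_levels - 1:
                noise = refine_increments(noise, 2, ps + level + 1)
        for level in range(n_levels - 1):
            sq_gaps[level] += np.mean((terminals[level] - terminals[level + 1]) ** 2)
    disc_rms = np.sqrt(sq_gaps / n_paths)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.log2(disc_rms[:-1] / disc_rms[1:])
    return ConvergenceTable(
        delta_taus=delta_taus, discrepancies=disc_rms, log2_ratios=ratios
    )


# ---------------------------------------------------------------------------
# empirical mean-square consistency
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ManufacturedProfile:
    """Smooth space-time profile with an analytic second space derivative."""

    value: Callable[[np.ndarray, float], np.ndarray]
    dxx: Callable[[np.ndarray, float], np.ndarray]


def default_manufactured_profiles(L: float) -> Tuple[ManufacturedProfile, ManufacturedProfile]:
    """Standard strictly-positive Neumann-compatible test profiles on [0, L]."""
    w = np.pi / L

    def p_val(x, t):
        return 2.0 + np.cos(w * x) * np.exp(-t)

    def p_dxx(x, t):
        return -(w**2) * np.cos(w * x) * np.exp(-t)

    def q_val(x, t):
        return 1.0 + 0.5 * np.cos(w * x) * np.exp(-t)

    def q_dxx(x, t):
        return -0.5 * (w**2) * np.cos(w * x) * np.exp(-t)

    return ManufacturedProfile(p_val, p_dxx), ManufacturedProfile(q_val, q_dxx)


def _ratio_arr(P: np.ndarray, Q: np.ndarray, m: float) -> np.ndarray:
    denom = m * Q + P
    out = np.zeros_like(denom)
    np.divide(P * Q, denom, out=out, where=denom != 0.0)
    return out


def empirical_consistency(
    scheme: str,
    psi_p: ManufacturedProfile,
    psi_q: ManufacturedProfile,
    p: ModelParameters,
    disc_sequence: Sequence[Discretization],
    n_noise_samples: int = 16,
    seed: int = 0,
    quad_subdivisions: int = 64,
) -> np.ndarray:
    """Mean-square one-step residual of the scheme against the continuous operator.

    For each discretization the continuous one-step operator is evaluated on
    the manufactured profiles by composite trapezoid quadrature of the time
    integrals (``quad_subdivisions`` panels per step) and a left-point Ito sum
    for the stochastic integral, using fine Wiener increments whose sum is
    exactly the step increment the discrete scheme consumes.  The residual is
    the mean square, over interior nodes and noise samples, of the difference
    between the two operators (both species summed).  Returns one residual
    per level; along a refinement sequence with delta_tau proportional to h^2
    the residuals must decrease.
    """
    if scheme not in ("sfe", "nsfd"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if n_noise_samples < 1:
        raise ValueError("need at least one noise sample")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(33,)))
    J = quad_subdivisions
    residuals = []
    for disc in disc_sequence:
        dt, h = disc.delta_tau, disc.h
        x = disc.nodes[1:-1]  # interior nodes; boundaries use ghost values
        u = np.linspace(0.0, dt, J + 1)
        Pu = np.stack([psi_p.value(x, t) for t in u])   # (J+1, nodes)
        Qu = np.stack([psi_q.value(x, t) for t in u])
        if Pu.min() <= 0 or Qu.min() <= 0:
            raise ValueError("manufactured profiles must be strictly positive")
        Pxx = np.stack([psi_p.dxx(x, t) for t in u])
        Qxx = np.stack([psi_q.dxx(x, t) for t in u])
        P0, Q0 = Pu[0], Qu[0]
        P1, Q1 = Pu[-1], Qu[-1]
        P0l, P0r = psi_p.value(x - h, 0.0), psi_p.value(x + h, 0.0)
        Q0l, Q0r = psi_q.value(x - h, 0.0), psi_q.value(x + h, 0.0)
        r_u = _ratio_arr(Pu, Qu, p.m)

        # deterministic parts of the continuous operator (time integrals)
        cont_P_det = (
            p.sigma1 * np.trapezoid(Pxx, u, axis=0)
            + np.trapezoid(Pu * (p.a - p.b * Pu), u, axis=0)
            - p.c * np.trapezoid(r_u, u, axis=0)
        )
        cont_Q_det = (
            p.sigma2 * np.trapezoid(Qxx, u, axis=0)
            - p.d * np.trapezoid(Qu, u, axis=0)
            + p.f * np.trapezoid(r_u, u, axis=0)
        )

        r0 = _ratio_arr(P0, Q0, p.m)
        if scheme == "sfe":
            disc_P_det = (
                p.sigma1 * dt * (P0r - 2.0 * P0 + P0l) / h**2
                + dt * P0 * (p.a - p.b * P0)
                - p.c * dt * r0
            )
            disc_Q_det = (
                p.sigma2 * dt * (Q0r - 2.0 * Q0 + Q0l) / h**2
                - p.d * dt * Q0
                + p.f * dt * r0
            )
        else:
            # the NSFD one-step operator evaluates the stencil centre, the
            # self-limitation factor, and the loss terms at the new level
            disc_P_det = (
                p.sigma1 * dt * (P0r - 2.0 * P1 + P0l) / h**2
                + dt * P0 * (p.a - p.b * P1)
                - p.c * dt * Q0 * P1 / (p.m * Q0 + P0)
            )
            disc_Q_det = (
                p.sigma2 * dt * (Q0r - 2.0 * Q1 + Q0l) / h**2
                - p.d * dt * Q1
                + p.f * dt * r0
            )

        # stochastic part: fine increments summing exactly to the step draw
        sq = 0.0
        for _ in range(n_noise_samples):
            fine1 = rng.normal(0.0, np.sqrt(dt / J), size=J)
            fine2 = rng.normal(0.0, np.sqrt(dt / J), size=J)
            dB1, dB2 = fine1.sum(), fine2.sum()
            cont_P = cont_P_det + p.eta1 * (Pu[:-1] * fine1[:, None]).sum(axis=0)
            cont_Q = cont_Q_det + p.eta2 * (Qu[:-1] * fine2[:, None]).sum(axis=0)
            d_P = disc_P_det + p.eta1 * P0 * dB1
            d_Q = disc_Q_det + p.eta2 * Q0 * dB2
            sq += np.mean((d_P - cont_P) ** 2) + np.mean((d_Q - cont_Q) ** 2)
        residuals.append(sq / n_noise_samples)
    return np.asarray(residuals)


def reference_reaction_trajectory(
    p: ModelParameters, P0: float, Q0: float, T: float, n_steps: int = 20000
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """High-accuracy RK4 integration of the reaction ODE pair.

    Independent cross-check for the schemes in the diffusion-free,
    noise-free limit.  Returns (t, P, Q) arrays of length n_steps + 1.
    """
    dt = T / n_steps
    t = np.linspace(0.0, T, n_steps + 1)
    P = np.empty(n_steps + 1)
    Q = np.empty(n_steps + 1)
    P[0], Q[0] = P0, Q0

    def rhs(y):
        return np.array(reaction_terms(max(y[0], 0.0), max(y[1], 0.0), p))

    y = np.array([P0, Q0], dtype=float)
    for k in range(n_steps):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * dt * k1)
        k3 = rhs(y + 0.5 * dt * k2)
        k4 = rhs(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        P[k + 1], Q[k + 1] = y
    return t, P, Q
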