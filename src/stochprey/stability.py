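"""Von Neumann amplification factors and mean-square stability verdicts.

Each scheme, linearized about small densities (prey growth a, predator decay
d, ratio terms dropped), has a per-frequency amplification factor
g(theta) = g_det(theta) + (noise term).  Mean-square stability in the relaxed
sense requires

    E|g|^2 <= 1 + chi * delta_tau        for some constant chi,

which tolerates the O(delta_tau) reaction-driven growth every explicit scheme
has, while still rejecting diffusion-driven blow-up (whose chi scales like
1/delta_tau).  The report therefore carries ``minimal_chi`` — the smallest
chi that makes the inequality hold over the frequency grid, plus the additive
noise contribution — along with the truth value of the literal hard bound
|g_det|^2 <= 1 (informational: it cannot hold at theta=0 for a growing
species).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .model import ModelParameters
from .schemes import Discretization

__all__ = ["AmplificationReport", "amplification_factor", "stability_report", "default_chi_tol"]

_SCHEMES = ("sfe", "nsfd")
_SPECIES = ("prey", "predator")


@dataclass(frozen=True)
class AmplificationReport:
    scheme: str
    species: str
    grid_size: int
    max_g_squared: float
    worst_theta: float
    minimal_chi: float
    chi_tol: float
    verdict: bool
    literal_theorem_condition: bool


def _g_det(scheme: str, species: str, s: np.ndarray, p: ModelParameters, disc: Discretization):
    """Deterministic amplification factor as a function of s = sin^2(theta/2)."""
    D1, D2 = disc.diffusion_numbers(p)
    dt = disc.delta_tau
    if scheme == "sfe":
        if species == "prey":
            return 1.0 + p.a * dt - 4.0 * D1 * s
        return 1.0 - p.d * dt - 4.0 * D2 * s
    if species == "prey":
        return (1.0 + 2.0 * D1 + p.a * dt - 4.0 * D1 * s) / (1.0 + 2.0 * D1)
    return (1.0 + 2.0 * D2 - 4.0 * D2 * s) / (1.0 + 2.0 * D2 + p.d * dt)


def _noise_chi(scheme: str, species: str, p: ModelParameters, disc: Discretization) -> float:
    """Additive noise contribution to chi: |eta/denominator|^2 per scheme."""
    D1, D2 = disc.diffusion_numbers(p)
    dt = disc.delta_tau
    if scheme == "sfe":
        return p.eta1**2 if species == "prey" else p.eta2**2
    if species == "prey":
        return (p.eta1 / (1.0 + 2.0 * D1)) ** 2
    return (p.eta2 / (1.0 + 2.0 * D2 + p.d * dt)) ** 2


def amplification_factor(
    scheme: str,
    species: str,
    theta: float,
    p: ModelParameters,
    disc: Discretization,
) -> float:
    """Deterministic part of g at frequency angle theta in [0, pi]."""
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if species not in _SPECIES:
        raise ValueError(f"unknown species {species!r}")
    if not 0.0 <= theta <= np.pi:
        raise ValueError("theta must lie in [0, pi]")
    s = np.sin(theta / 2.0) ** 2
    return float(_g_det(scheme, species, np.asarray(s), p, disc))


def default_chi_tol(p: ModelParameters) -> float:
    """Tolerance admitting reaction-rate growth but not diffusion blow-up."""
    return p.eta1**2 + p.eta2**2 + 2.0 * max(p.a, p.d) + 1.0


def stability_report(
    scheme: str,
    p: ModelParameters,
    disc: Discretization,
    chi_tol: float | None = None,
    grid_size: int = 1025,
) -> Dict[str, AmplificationReport]:
    """Scan theta over [0, pi] and render a per-species stability verdict."""
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if grid_size < 64:
        raise ValueError("grid_size must be >= 64")
    if chi_tol is None:
        chi_tol = default_chi_tol(p)
    if chi_tol < 0:
        raise ValueError("chi_tol must be nonnegative")
    theta = np.linspace(0.0, np.pi, grid_size)
    s = np.sin(theta / 2.0) ** 2
    out: Dict[str, AmplificationReport] = {}
    for species in _SPECIES:
        g = _g_det(scheme, species, s, p, disc)
        g2 = g * g
        i_worst = int(np.argmax(g2))
        max_g2 = float(g2[i_worst])
        chi = max(0.0, (max_g2 - 1.0) / disc.delta_tau) + _noise_chi(scheme, species, p, disc)
        out[species] = AmplificationReport(
            scheme=scheme,
            species=species,
            grid_size=grid_size,
            max_g_squared=max_g2,
            worst_theta=float(theta[i_worst]),
            minimal_chi=chi,
            chi_tol=float(chi_tol),
            verdict=chi <= chi_tol,
            literal_theorem_condition=bool(np.all(g2 <= 1.0)),
        )
    return out
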