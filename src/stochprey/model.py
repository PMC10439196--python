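"""Continuous ratio-dependent predator-prey model: coefficients, drifts, equilibria.

The reaction part of the system is

    dP/dt = P(a - bP) - c P Q / (m Q + P)
    dQ/dt = -d Q + f P Q / (m Q + P)

with a ratio-dependent functional response: the per-capita predation rate
depends on the prey-to-predator ratio P/Q rather than on P alone.  The full
model adds Fickian diffusion (sigma1, sigma2) and multiplicative time noise
(eta1, eta2) on each species; those coefficients live here so one parameter
object describes the whole stochastic PDE system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Mapping, Optional, Tuple

__all__ = [
    "ModelParameters",
    "EquilibriumReport",
    "validate_parameters",
    "reaction_terms",
    "equilibria",
    "hopf_threshold_f",
]

#: fields that must be strictly positive
_POSITIVE = ("a", "b", "c", "m", "f", "d", "sigma1", "sigma2")
#: fields that must be nonnegative
_NONNEGATIVE = ("eta1", "eta2")


@dataclass(frozen=True)
class ModelParameters:
    """Coefficients of the stochastic reaction-diffusion system.

    Attributes
    ----------
    a : prey intrinsic growth rate (1/time).
    b : prey self-limitation coefficient (1/(density*time)); a/b is the
        prey carrying capacity.
    c : capturing rate (1/time).
    m : half capturing saturation constant (dimensionless).
    f : conversion rate (1/time) — fraction of consumed prey converted into
        predator growth; the control parameter for regime transitions.
    d : predator death rate (1/time).
    sigma1, sigma2 : diffusion coefficients (length^2/time).
    eta1, eta2 : noise strengths (1/sqrt(time)); zero switches the noise off.
    """

    a: float
    b: float
    c: float
    m: float
    f: float
    d: float
    sigma1: float
    sigma2: float
    eta1: float = 0.0
    eta2: float = 0.0

    def __post_init__(self) -> None:
        for name in _POSITIVE + _NONNEGATIVE:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or not math.isfinite(value):
                raise ValueError(f"parameter {name!r} must be a finite number, got {value!r}")
        for name in _POSITIVE:
            if getattr(self, name) <= 0:
                raise ValueError(
                    f"parameter {name!r} must be strictly positive, got {getattr(self, name)}"
                )
        for name in _NONNEGATIVE:
            if getattr(self, name) < 0:
                raise ValueError(
                    f"parameter {name!r} must be nonnegative, got {getattr(self, name)}"
                )

    def replace(self, **changes) -> "ModelParameters":
        kwargs = {f.name: getattr(self, f.name) for f in fields(self)}
        kwargs.update(changes)
        return ModelParameters(**kwargs)


@dataclass(frozen=True)
class EquilibriumReport:
    """Equilibria of the reaction system and the coexistence stability verdict.

    ``criterion_value`` is the signed quantity

        Lambda = (c - m f) d^2 - (c - m a - m d) f^2

    whose sign classifies the coexistence point: positive -> stable,
    negative -> unstable, exactly zero -> neutral.  It is reported raw so
    callers decide their own tolerances.  ``prey_only_label`` records the
    conventional "(1, 0)" name for the predator-free state used in parts of
    the literature; the actual drift root is (a/b, 0) and that is what
    ``prey_only_point`` holds.
    """

    prey_only_point: Tuple[float, float]
    coexistence_feasible: bool
    coexistence_point: Optional[Tuple[float, float]] = None
    criterion_value: Optional[float] = None
    classification: str = "infeasible"
    prey_only_label: str = "(1, 0)"


def validate_parameters(raw: Mapping[str, float]) -> ModelParameters:
    """Build a validated :class:`ModelParameters` from a flat name->number mapping.

    Unknown keys raise, as do missing ones, so config typos fail loudly.
    """
    known = {f.name for f in fields(ModelParameters)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
    missing = {n for n in known if n not in raw and n not in ("eta1", "eta2")}
    if missing:
        raise ValueError(f"missing parameter(s): {sorted(missing)}")
    return ModelParameters(**{k: float(v) for k, v in raw.items()})


def _ratio(P: float, Q: float, m: float) -> float:
    """P*Q/(m*Q + P) with the exact guard ratio := 0 at m*Q + P == 0.

    The guard makes the origin an exact fixed point of the drift (extinction
    state preserved bit-exactly); no epsilon smoothing.
    """
    denom = m * Q + P
    if denom == 0.0:
        return 0.0
    return P * Q / denom


def reaction_terms(P: float, Q: float, p: ModelParameters) -> Tuple[float, float]:
    """Deterministic drift pair (dP/dt, dQ/dt) of the reaction system.

    Raises for negative or non-finite densities: the functional response is
    only meaningful on the nonnegative quadrant.
    """
    if not (math.isfinite(P) and math.isfinite(Q)):
        raise ValueError("densities must be finite")
    if P < 0 or Q < 0:
        raise ValueError("densities must be nonnegative")
    r = _ratio(P, Q, p.m)
    dP = P * (p.a - p.b * P) - p.c * r
    dQ = -p.d * Q + p.f * r
    return dP, dQ


def equilibria(p: ModelParameters) -> EquilibriumReport:
    """Equilibria of the reaction system and the coexistence classification.

    The predator-free state is (a/b, 0).  The coexistence point

        P* = ((a m - c) f + c d) / (b m f)
        Q* = (f - d)(a m f - c f + c d) / (b d m^2 f)

    exists (both components positive) iff f > d and (a m - c) f + c d > 0.
    """
    prey_only = (p.a / p.b, 0.0)
    shared = (p.a * p.m - p.c) * p.f + p.c * p.d  # common numerator factor
    feasible = (p.f > p.d) and (shared > 0)
    if not feasible:
        return EquilibriumReport(prey_only_point=prey_only, coexistence_feasible=False)
    P_star = shared / (p.b * p.m * p.f)
    Q_star = (p.f - p.d) * shared / (p.b * p.d * p.m**2 * p.f)
    crit = (p.c - p.m * p.f) * p.d**2 - (p.c - p.m * p.a - p.m * p.d) * p.f**2
    if crit > 0:
        cls = "stable"
    elif crit < 0:
        cls = "unstable"
    else:
        cls = "neutral"
    return EquilibriumReport(
        prey_only_point=prey_only,
        coexistence_feasible=True,
        coexistence_point=(P_star, Q_star),
        criterion_value=crit,
        classification=cls,
    )


def hopf_threshold_f(
    p: ModelParameters, f_interval: Tuple[float, float]
) -> Optional[float]:
    """Conversion rate f at which the coexistence criterion changes sign.

    Lambda(f) = c d^2 - m d^2 f - (c - m a - m d) f^2 is quadratic in f; the
    root is found in closed form and returned only if it lies inside
    ``f_interval`` (which must sit inside (d, inf) for the coexistence point
    to be meaningful).  Returns ``None`` when no admissible root lies in the
    interval.
    """
    lo, hi = f_interval
    if lo >= hi:
        raise ValueError("empty search interval")
    if lo < p.d:
        raise ValueError("interval must lie inside (d, inf)")
    q2 = -(p.c - p.m * p.a - p.m * p.d)
    q1 = -p.m * p.d**2
    q0 = p.c * p.d**2
    roots = []
    if q2 == 0.0:
        if q1 != 0.0:
            roots = [-q0 / q1]
    else:
        disc = q1 * q1 - 4.0 * q2 * q0
        if disc >= 0:
            sq = math.sqrt(disc)
            # numerically stable quadratic formula
            qq = -0.5 * (q1 + math.copysign(sq, q1))
            roots = [qq / q2]
            if qq != 0.0:
                roots.append(q0 / qq)
    inside = sorted(r for r in roots if lo < r < hi)
    return inside[0] if inside else None
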