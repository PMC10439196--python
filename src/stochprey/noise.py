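"""Seeded Wiener increments driving the two species, scalar in space.

The noise in this model depends on time only: at each time step one Gaussian
increment per species is drawn and applied identically at every spatial node.
A single integer master seed yields deterministic per-species substreams, and
`refine_increments` builds conditionally-correct finer increments whose block
sums reproduce a coarse path exactly — the coupling needed for strong
self-convergence studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseIncrements", "wiener_increments", "refine_increments"]

# fixed spawn keys for the per-species substreams
_PREY_STREAM = 101
_PREDATOR_STREAM = 202


@dataclass(frozen=True)
class NoiseIncrements:
    """Per-step Wiener increments dB ~ N(0, delta_tau) for both species."""

    n_steps: int
    delta_tau: float
    dB1: np.ndarray
    dB2: np.ndarray
    mode: str  # "independent" or "shared"
    seed: int

    def __post_init__(self) -> None:
        if len(self.dB1) != self.n_steps or len(self.dB2) != self.n_steps:
            raise ValueError("increment arrays must have length n_steps")


def wiener_increments(
    n_steps: int, delta_tau: float, seed: int, mode: str = "independent"
) -> NoiseIncrements:
    """Draw the two driving increment sequences.

    mode="independent" uses two deterministic substreams of ``seed``;
    mode="shared" makes dB1 and dB2 the identical sequence (a single driving
    Wiener process for both species).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if delta_tau <= 0:
        raise ValueError("delta_tau must be positive")
    if mode not in ("independent", "shared"):
        raise ValueError(f"unknown noise mode {mode!r}")
    sd = float(np.sqrt(delta_tau))
    rng1 = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_PREY_STREAM,)))
    dB1 = rng1.normal(0.0, sd, size=n_steps)
    if mode == "shared":
        dB2 = dB1.copy()
    else:
        rng2 = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(_PREDATOR_STREAM,))
        )
        dB2 = rng2.normal(0.0, sd, size=n_steps)
    return NoiseIncrements(n_steps, float(delta_tau), dB1, dB2, mode, int(seed))


def _refine_one(coarse: np.ndarray, factor: int, dt_fine: float, rng) -> np.ndarray:
    """Conditional-Gaussian refinement of one increment sequence.

    Draw iid fine increments, then shift each block so its sum equals the
    coarse increment; this is exactly the Brownian-bridge conditional law,
    and the block-sum constraint holds to machine precision by construction.
    """
    n = len(coarse)
    fine = rng.normal(0.0, np.sqrt(dt_fine), size=(n, factor))
    correction = (coarse - fine.sum(axis=1)) / factor
    fine += correction[:, None]
    # enforce exact block sums against rounding: absorb the residual in the
    # last entry of each block
    fine[:, -1] += coarse - fine.sum(axis=1)
    return fine.reshape(-1)


def refine_increments(coarse: NoiseIncrements, factor: int, seed: int) -> NoiseIncrements:
    """Increments on step delta_tau/factor coupled to ``coarse``.

    Each consecutive block of ``factor`` fine increments sums exactly to the
    corresponding coarse increment, so a fine-step simulation follows the same
    Brownian path as the coarse one.
    """
    if factor < 2:
        raise ValueError("refinement factor must be >= 2")
    dt_fine = coarse.delta_tau / factor
    rng1 = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_PREY_STREAM, 7)))
    dB1 = _refine_one(coarse.dB1, factor, dt_fine, rng1)
    if coarse.mode == "shared":
        dB2 = dB1.copy()
    else:
        rng2 = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(_PREDATOR_STREAM, 7))
        )
        dB2 = _refine_one(coarse.dB2, factor, dt_fine, rng2)
    return NoiseIncrements(
        coarse.n_steps * factor, dt_fine, dB1, dB2, coarse.mode, int(seed)
    )
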