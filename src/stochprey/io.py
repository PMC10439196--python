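"""Config files, persisted run outputs, and run manifests.

Configs are flat YAML mappings (model coefficients plus grid/run keys).  A
persisted run consists of: a probe time series as CSV with header ``t,P,Q``
(6 significant digits), the snapshot stack as a compressed NumPy archive with
axes (time, node, species) at full double precision, and a JSON metadata
record carrying everything needed to re-create the run exactly — parameters,
grid, scheme, seed, noise mode, package version, and a config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import yaml

from . import __version__
from .model import ModelParameters, validate_parameters
from .noise import wiener_increments
from .schemes import (
    DEFAULT_DIVERGENCE_CAP,
    Discretization,
    SimulationResult,
    make_initial_state,
    simulate,
)

__all__ = [
    "load_config",
    "split_config",
    "config_hash",
    "write_run",
    "rerun_from_metadata",
]

_MODEL_KEYS = ("a", "b", "c", "m", "f", "d", "sigma1", "sigma2", "eta1", "eta2")


def load_config(path: str | Path) -> Dict[str, float]:
    """Read a flat key->number YAML config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key: value mapping")
    return raw


def split_config(raw: Dict) -> Tuple[ModelParameters, Discretization, Dict]:
    """Split a flat config into model parameters, grid, and remaining run keys.

    Grid keys: L, n, delta_tau, N.  Everything else (scheme, seed, P0, Q0,
    noise_mode, probe_node, snapshot_stride, divergence_cap, ...) is returned
    in the run-options mapping.
    """
    params = validate_parameters({k: raw[k] for k in _MODEL_KEYS if k in raw})
    for key in ("L", "n", "delta_tau", "N"):
        if key not in raw:
            raise ValueError(f"config missing grid key {key!r}")
    disc = Discretization(
        float(raw["L"]), int(raw["n"]), float(raw["delta_tau"]), int(raw["N"])
    )
    run = {k: v for k, v in raw.items() if k not in _MODEL_KEYS + ("L", "n", "delta_tau", "N")}
    return params, disc, run


def config_hash(record: Dict) -> str:
    """SHA-256 of the canonical JSON form of a config record."""
    blob = json.dumps(record, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()


def _metadata(result: SimulationResult, noise_mode: str) -> Dict:
    record = {
        "scheme": result.scheme,
        "seed": result.seed,
        "noise_mode": noise_mode,
        "preset": result.preset,
        "params": dataclasses.asdict(result.params),
        "disc": dataclasses.asdict(result.disc),
        "probe_node": result.probe_node,
        "snapshot_stride": int(result.snapshot_steps[1])
        if len(result.snapshot_steps) > 1
        else 1,
        "divergence_cap": result.divergence_cap,
        "P0": float(result.snapshots[0, 0, 0]),
        "Q0": float(result.snapshots[0, 0, 1]),
        "initial_profile": {
            "P": result.snapshots[0, :, 0].tolist(),
            "Q": result.snapshots[0, :, 1].tolist(),
        },
        "diverged": result.diverged,
        "divergence_step": result.divergence_step,
        "completed_steps": result.completed_steps,
        "version": __version__,
    }
    record["config_hash"] = config_hash(
        {k: record[k] for k in ("scheme", "seed", "noise_mode", "params", "disc")}
    )
    return record


def write_run(result: SimulationResult, out_dir: str | Path, noise_mode: str = "independent") -> Path:
    """Persist probe CSV, snapshot archive, and the metadata/manifest record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "probe.csv", "w") as fh:
        fh.write("t,P,Q\n")
        for t, pv, qv in zip(result.times, result.probe_P, result.probe_Q):
            fh.write(f"{t:.6g},{pv:.6g},{qv:.6g}\n")
    np.savez_compressed(
        out / "snapshots.npz",
        snapshots=result.snapshots,
        snapshot_steps=result.snapshot_steps,
        mean_P=result.mean_P,
        mean_Q=result.mean_Q,
    )
    meta = _metadata(result, noise_mode)
    with open(out / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out


def rerun_from_metadata(metadata_path: str | Path) -> SimulationResult:
    """Re-create a persisted run exactly from its metadata record alone."""
    with open(metadata_path) as fh:
        meta = json.load(fh)
    params = ModelParameters(**meta["params"])
    disc = Discretization(**meta["disc"])
    init = make_initial_state(disc, 0.0, 0.0)
    init.P = np.asarray(meta["initial_profile"]["P"], dtype=float)
    init.Q = np.asarray(meta["initial_profile"]["Q"], dtype=float)
    noise = wiener_increments(
        disc.n_steps, disc.delta_tau, meta["seed"], meta["noise_mode"]
    )
    result = simulate(
        meta["scheme"],
        params,
        disc,
        init,
        noise,
        probe_node=meta["probe_node"],
        snapshot_stride=meta.get("snapshot_stride"),
        divergence_cap=meta.get("divergence_cap", DEFAULT_DIVERGENCE_CAP),
        seed=meta["seed"],
    )
    result.preset = meta.get("preset")
    return result
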