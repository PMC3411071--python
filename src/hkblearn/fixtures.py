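"""Canonical synthetic fixture bundle for both learner profiles.

Emits, per profile (bistable / multistable): a short noisy trajectory, a
scanning-probe result over the 13 standard required phases, a bifurcation
diagram over lambda in [0, 5], and its event list.  Stochastic outputs are
deterministic under the seed; the deterministic outputs (fixed points,
diagrams) do not depend on it at all.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .fixed_points import sweep_bifurcation
from .model import get_schedule
from .protocol import ScanningProbe, run_scanning
from .simulate import SimulationConfig, integrate

__all__ = ["generate_fixtures"]

PROFILES = ("bistable", "multistable")


def generate_fixtures(
    seed: int,
    out_dir,
    trajectory_duration: float = 10.0,
    lambda_step: float = 0.25,
) -> dict:
    """Write the fixture bundle under ``out_dir``; returns a manifest dict
    mapping relative file names to SHA-256 checksums."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}

    for k, profile in enumerate(PROFILES):
        schedule = get_schedule(profile)
        params = schedule(0.0)
        cfg = SimulationConfig(seed=seed + 10_000 * k)

        traj = integrate(params, replace(cfg, duration=trajectory_duration, phi0_deg=60.0))
        stride = max(1, len(traj.times) // 1000)
        traj_df = pd.DataFrame(
            {"time": traj.times[::stride], "phi_deg": traj.phases_deg[::stride]}
        )
        _write_csv(traj_df, out / f"{profile}_trajectory.csv", manifest)

        scan = run_scanning(params, ScanningProbe(), cfg)
        _write_csv(scan.to_frame(), out / f"{profile}_scan.csv", manifest)

        lam_grid = np.arange(0.0, 5.0 + 1e-9, lambda_step)
        diagram = sweep_bifurcation(profile, lam_grid)
        _write_csv(diagram.to_frame(), out / f"{profile}_bifurcation.csv", manifest)
        events_path = out / f"{profile}_events.json"
        events_path.write_text(json.dumps(diagram.events_records(), indent=2) + "\n")
        manifest[events_path.name] = _sha256(events_path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _write_csv(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest[path.name] = _sha256(path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
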