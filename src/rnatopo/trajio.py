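"""Trajectory and result serialization.

The native trajectory container is written as a documented ``.npz``
columnar table (binary) with an equivalent plain-text TSV alternative;
run metadata (config, seed, exchange statistics) goes to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .sampler import TrajectoryEnsemble


def save_trajectory(traj: TrajectoryEnsemble, prefix: str | Path) -> list[Path]:
    """Write ``<prefix>.npz`` (+ ``<prefix>.meta.json``); returns paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    arrays = {
        "frame_replica": traj.frame_replica,
        "exchange_attempts": traj.exchange_attempts,
        "exchange_accepts": traj.exchange_accepts,
    }
    if traj.frames is not None:
        arrays["frames"] = traj.frames
    for name, arr in traj.observables.items():
        arrays[f"obs__{name}"] = arr
    npz = prefix.with_suffix(".npz")
    np.savez_compressed(npz, **arrays)
    meta = {
        "config": _jsonable(traj.config),
        "n_frames": traj.n_frames,
        "equilibration": traj.equilibration,
        "temperature": traj.temperature,
        "frame_stride": traj.frame_stride,
        "seed": traj.seed,
        "exchange_rates": [None if np.isnan(x) else float(x)
                           for x in traj.exchange_rates],
        "observables": list(traj.observables),
    }
    meta_path = prefix.with_suffix(".meta.json")
    meta_path.write_text(json.dumps(meta, indent=1))
    return [npz, meta_path]


def load_trajectory(prefix: str | Path) -> TrajectoryEnsemble:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".meta.json").read_text())
    data = np.load(prefix.with_suffix(".npz"))
    obs = {k[len("obs__"):]: data[k] for k in data.files if k.startswith("obs__")}
    return TrajectoryEnsemble(
        config=meta["config"], n_frames=meta["n_frames"],
        equilibration=meta["equilibration"], observables=obs,
        frames=data["frames"] if "frames" in data.files else None,
        frame_stride=meta["frame_stride"],
        frame_replica=data["frame_replica"],
        temperature=meta["temperature"],
        exchange_attempts=data["exchange_attempts"],
        exchange_accepts=data["exchange_accepts"],
        seed=meta["seed"],
    )


def trajectory_to_tsv(traj: TrajectoryEnsemble) -> str:
    """Plain-text serialization: frame, bead, x, y, z (stored frames)."""
    if traj.frames is None:
        raise ValueError("run did not store coordinate frames")
    lines = ["frame\tbead\tx\ty\tz"]
    for f, coords in enumerate(traj.frames):
        for b, (x, y, z) in enumerate(coords):
            lines.append(f"{f}\t{b}\t{x:.3f}\t{y:.3f}\t{z:.3f}")
    return "\n".join(lines) + "\n"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
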