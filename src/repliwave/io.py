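"""Serialisation: lattice snapshots, time-series tables, run manifests and
snapshot rendering.

Snapshots are compressed numpy array containers with a JSON header carrying
the format version, clock, window origin and the PCG32 generator state, so a
resumed run replays bit-for-bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import LatticeState
from .dynamics import Trajectory

SNAPSHOT_MAGIC = "repliwave-snapshot"
SNAPSHOT_VERSION = 1


class SnapshotError(ValueError):
    """A snapshot file is corrupt or has an incompatible version."""


def save_snapshot(state: LatticeState, path: str | Path) -> None:
    """Lossless dump of grid, traits, bonds, ages, clock and RNG state."""
    header = {
        "magic": SNAPSHOT_MAGIC,
        "version": SNAPSHOT_VERSION,
        "sweeps": state.sweeps,
        "dt": state.dt,
        "offset_x": state.offset_x,
        "periodic_x": bool(state.periodic_x),
        "rng": [int(state.rng[0]), int(state.rng[1])],
    }
    np.savez_compressed(
        path,
        kind=state.kind, trait=state.trait, bond=state.bond,
        role=state.role, age=state.age,
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
    )


def load_snapshot(path: str | Path) -> LatticeState:
    """Restore a snapshot; errors explicitly on corruption or a version
    mismatch rather than coercing silently."""
    try:
        with np.load(path) as data:
            header = json.loads(bytes(data["header"]).decode())
            arrays = {k: data[k] for k in ("kind", "trait", "bond", "role", "age")}
    except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
        raise SnapshotError(f"cannot read snapshot {path}: {exc}") from exc
    if header.get("magic") != SNAPSHOT_MAGIC:
        raise SnapshotError(f"{path} is not a lattice snapshot")
    if header.get("version") != SNAPSHOT_VERSION:
        raise SnapshotError(
            f"snapshot version {header.get('version')} is not supported "
            f"(expected {SNAPSHOT_VERSION})")
    return LatticeState(
        kind=arrays["kind"], trait=arrays["trait"], bond=arrays["bond"],
        role=arrays["role"], age=arrays["age"], dt=float(header["dt"]),
        rng=np.array(header["rng"], dtype=np.uint64),
        sweeps=int(header["sweeps"]), offset_x=int(header["offset_x"]),
        periodic_x=bool(header["periodic_x"]),
    )


def write_timeseries(trajectory: Trajectory, path: str | Path) -> None:
    """One TSV row per sample; times are in AUT.  The column set is fixed —
    parasite extinction leaves empty beta fields, it never drops columns."""
    if len(trajectory) == 0:
        raise ValueError("cannot write an empty trajectory")
    frame = trajectory.to_frame()
    with open(path, "w") as fh:
        fh.write("# t is in AUT; rates in AUT^-1; counts are per sample window\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="")


def read_timeseries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


@dataclass
class RunManifest:
    """Everything needed to regenerate a run's outputs: the resolved config,
    the seed, code version, wall time and the output file index."""

    config: dict
    seed: int
    code_version: str
    started: float = field(default_factory=time.time)
    finished: float | None = None
    outputs: list[str] = field(default_factory=list)
    status: str = "completed"

    def write(self, path: str | Path) -> None:
        base = Path(path).parent
        for out in self.outputs:
            if not (base / out).exists():
                raise FileNotFoundError(f"manifest lists missing output {out}")
        with open(path, "w") as fh:
            json.dump({
                "config": self.config,
                "seed": self.seed,
                "code_version": self.code_version,
                "started": self.started,
                "finished": self.finished,
                "outputs": self.outputs,
                "status": self.status,
            }, fh, indent=2)


# Rendering convention: empty black, replicators blue (complexed: lighter),
# parasites red (complexed: orange).
_COLORS = {
    "empty": (0.0, 0.0, 0.0),
    "replicator": (0.25, 0.45, 0.95),
    "replicator_complex": (0.55, 0.8, 1.0),
    "parasite": (0.85, 0.15, 0.15),
    "parasite_complex": (1.0, 0.6, 0.2),
}


def render_snapshot(state: LatticeState, path: str | Path) -> None:
    """Render a snapshot to PNG (replicators/parasites/empty in distinct
    colours, complex members marked by a lighter shade)."""
    import matplotlib
    matplotlib.use("Agg")
    from matplotlib.image import imsave

    img = np.zeros(state.kind.shape + (3,), dtype=float)
    bound = state.bond >= 0
    for mask, color in (
        ((state.kind == 1) & ~bound, _COLORS["replicator"]),
        ((state.kind == 1) & bound, _COLORS["replicator_complex"]),
        ((state.kind == 2) & ~bound, _COLORS["parasite"]),
        ((state.kind == 2) & bound, _COLORS["parasite_complex"]),
    ):
        img[mask] = color
    imsave(path, img)
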