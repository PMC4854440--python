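"""Serialization: extended-XYZ trajectories, topology sidecars,
checkpoints, run configs and tabular reports.

Trajectories are plain-text extended XYZ (bead label + full-precision
coordinates, optional velocities) with the box in the ``Lattice`` field;
a YAML sidecar stores the molecule templates and counts needed to
reconstruct the bonded topology.  Checkpoints are versioned ``.npz``
containers carrying everything needed for an exact restart.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .state import SystemState
from .topology import MoleculeTemplate, Topology, assemble
from .trajectory import Frame, Trajectory

CHECKPOINT_FORMAT = "dpdmem-checkpoint-1"


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def write_frames(path, traj: Trajectory, with_velocities: bool = False) -> None:
    """Write a trajectory as extended-XYZ text (lossless %.17g floats)."""
    labels = traj.topology.bead_labels()
    with open(path, "w") as fh:
        for fr in traj:
            vel = fr.velocities if with_velocities else None
            props = "species:S:1:pos:R:3" + (":vel:R:3" if vel is not None else "")
            lat = (f"{fr.box[0]:.17g} 0 0 0 {fr.box[1]:.17g} 0 0 0 "
                   f"{fr.box[2]:.17g}")
            fh.write(f"{len(fr.positions)}\n")
            fh.write(f'Lattice="{lat}" Properties={props} Time={fr.time:.17g}\n')
            for i, (lb, p) in enumerate(zip(labels, fr.positions)):
                line = f"{lb} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}"
                if vel is not None:
                    v = vel[i]
                    line += f" {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}"
                fh.write(line + "\n")


def read_frames(path, topology: Topology) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_frames`."""
    traj = Trajectory(topology)
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header:
                break
            try:
                n = int(header.strip())
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: expected atom count") from exc
            comment = fh.readline()
            lineno += 1
            box, time = _parse_comment(comment, path, lineno)
            has_vel = ":vel:R:3" in comment
            pos = np.empty((n, 3))
            vel = np.empty((n, 3)) if has_vel else None
            for i in range(n):
                parts = fh.readline().split()
                lineno += 1
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: malformed atom line")
                pos[i] = [float(x) for x in parts[1:4]]
                if has_vel:
                    vel[i] = [float(x) for x in parts[4:7]]
            traj.frames.append(Frame(positions=pos, box=box, time=time,
                                     velocities=vel))
    return traj


def _parse_comment(comment: str, path, lineno: int):
    box = None
    time = 0.0
    for token in _split_keyvals(comment):
        key, _, val = token.partition("=")
        if key == "Lattice":
            vals = [float(x) for x in val.strip('"').split()]
            box = np.array([vals[0], vals[4], vals[8]])
        elif key == "Time":
            time = float(val)
    if box is None:
        raise ValueError(f"{path}:{lineno}: missing Lattice entry")
    return box, time


def _split_keyvals(line: str) -> list[str]:
    out, cur, inq = [], [], False
    for ch in line.strip():
        if ch == '"':
            inq = not inq
            cur.append(ch)
        elif ch == " " and not inq:
            if cur:
                out.append("".join(cur))
                cur = []
        else:
            cur.append(ch)
    if cur:
        out.append("".join(cur))
    return out


# ---------------------------------------------------------------------------
# topology sidecar
# ---------------------------------------------------------------------------

def write_topology(path, topology: Topology) -> None:
    doc = {
        "type_labels": list(topology.type_labels),
        "molecules": [
            {"name": tmpl.name, "count": count, "template": tmpl.to_dict()}
            for tmpl, count in topology.molecules
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_topology(path) -> Topology:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    mols = [
        (MoleculeTemplate.from_dict(m["name"], m["template"]), int(m["count"]))
        for m in doc["molecules"]
    ]
    return assemble(mols, tuple(doc["type_labels"]))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, state: SystemState) -> None:
    """Versioned binary checkpoint for an exact restart."""
    doc = {
        "type_labels": list(state.topology.type_labels),
        "molecules": [
            {"name": t.name, "count": c, "template": t.to_dict()}
            for t, c in state.topology.molecules
        ],
    }
    np.savez(
        path,
        format=CHECKPOINT_FORMAT,
        positions=state.positions,
        velocities=state.velocities,
        box=state.box,
        time=state.time,
        step=state.step,
        topology_yaml=yaml.safe_dump(doc, sort_keys=False),
    )


def load_checkpoint(path) -> SystemState:
    with np.load(path, allow_pickle=False) as data:
        fmt = str(data["format"])
        if fmt != CHECKPOINT_FORMAT:
            raise ValueError(f"unsupported checkpoint format {fmt!r}")
        doc = yaml.safe_load(str(data["topology_yaml"]))
        mols = [
            (MoleculeTemplate.from_dict(m["name"], m["template"]), int(m["count"]))
            for m in doc["molecules"]
        ]
        topo = assemble(mols, tuple(doc["type_labels"]))
        return SystemState(
            positions=data["positions"],
            velocities=data["velocities"],
            topology=topo,
            box=data["box"],
            time=float(data["time"]),
            step=int(data["step"]),
        )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable description of one simulation run.

    A run is reproducible from ``(config, seed)`` alone: the recipe names
    a builder and its arguments, and all integrator/ensemble parameters
    are explicit.
    """

    recipe: dict = field(default_factory=dict)
    forcefield: dict | None = None       # override table; None = packaged
    ensemble: str = "NVT"                # NVT | NPT_normal_zero_tension
    dt: float = 0.02
    n_steps: int = 0
    P_target: float = 89.0
    lambda_vv: float = 0.5
    piston: dict = field(default_factory=dict)
    traj_stride: int = 0                 # 0 = no trajectory output
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "recipe": self.recipe,
            "forcefield": self.forcefield,
            "ensemble": self.ensemble,
            "dt": self.dt,
            "n_steps": self.n_steps,
            "P_target": self.P_target,
            "lambda_vv": self.lambda_vv,
            "piston": self.piston,
            "traj_stride": self.traj_stride,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class Report:
    """One observable with reduced- and physical-unit values."""

    name: str
    value: float
    uncertainty: float
    unit_reduced: str
    value_physical: float | None = None
    unit_physical: str | None = None
    provenance: str = ""


def write_report(path, reports: list[Report]) -> None:
    df = pd.DataFrame([r.__dict__ for r in reports])
    df.to_csv(path, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
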