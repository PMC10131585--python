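"""In-memory trajectories and plain-text frame I/O (multi-model PDB, XYZ)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from cycbind.structure import ParamStructure


@dataclass
class Trajectory:
    """Ordered coordinate frames congruent with a topology.

    ``frame_interval`` is in ns per frame; the screening default of 0.2 ns
    matches a 200 ps trajectory output stride.
    """

    frames: List[np.ndarray] = field(default_factory=list)
    frame_interval: float = 0.2

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        if self.frames:
            shape = self.frames[0].shape
            for i, f in enumerate(self.frames):
                if f.shape != shape:
                    raise ValueError(f"frame {i} has shape {f.shape}, expected {shape}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        return len(self.frames) * self.frame_interval

    def check_congruent(self, topology: ParamStructure) -> None:
        for i, f in enumerate(self.frames):
            if f.shape != (topology.n_atoms, 3):
                raise ValueError(
                    f"frame {i} has {f.shape[0]} atoms; topology has {topology.n_atoms}"
                )


def write_xyz(trajectory: Trajectory, names: Sequence[str], path) -> None:
    lines = []
    for f in trajectory.frames:
        lines.append(str(len(names)))
        lines.append(f"frame_interval_ns={trajectory.frame_interval}")
        for nm, (x, y, z) in zip(names, f):
            lines.append(f"{nm} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path, frame_interval: float = 0.2) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1]
        if "frame_interval_ns=" in comment:
            frame_interval = float(comment.split("frame_interval_ns=")[1].split()[0])
        coords = []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append(np.asarray(coords))
        i += 2 + n
    return Trajectory(frames=frames, frame_interval=frame_interval)


def write_multimodel_pdb(trajectory: Trajectory, topology: ParamStructure, path) -> None:
    trajectory.check_congruent(topology)
    stack = struc.AtomArrayStack(len(trajectory), topology.n_atoms)
    arr = topology.to_atom_array()
    for cat in arr.get_annotation_categories():
        stack.set_annotation(cat, arr.get_annotation(cat))
    stack.coord = np.asarray(trajectory.frames, dtype=np.float32)
    f = pdbio.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def read_multimodel_pdb(path, frame_interval: float = 0.2) -> Trajectory:
    f = pdbio.PDBFile.read(str(path))
    stack = f.get_structure()
    frames = [np.asarray(stack.coord[i], dtype=float) for i in range(stack.stack_depth())]
    return Trajectory(frames=frames, frame_interval=frame_interval)
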