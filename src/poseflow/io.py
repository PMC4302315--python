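"""File I/O: multi-model PDB (via biotite), XYZ frame blocks, ensembles.

Coordinates are Å everywhere.  PDB files round-trip to the format's printed
precision (1e-3 Å); XYZ files are written with 6 decimals.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .topology import Topology
from .trajectory import Trajectory, TrajectoryEnsemble

__all__ = [
    "read_ensemble",
    "read_frames",
    "write_frames",
    "read_xyz",
    "write_xyz",
    "read_pdb",
    "write_pdb",
]


def _element_of(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


# ----------------------------------------------------------------------
# XYZ: repeated blocks of "n_atoms \n comment \n n_atoms coordinate lines"
# ----------------------------------------------------------------------

def write_xyz(path: str | Path, coords: np.ndarray, names: Sequence[str], comment: str = "") -> None:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_atoms = coords.shape[1]
    if len(names) != n_atoms:
        raise ValueError(f"{len(names)} names for {n_atoms} atoms")
    lines: list[str] = []
    for k, frame in enumerate(coords):
        lines.append(str(n_atoms))
        lines.append(comment or f"frame {k}")
        for name, (x, y, z) in zip(names, frame):
            lines.append(f"{name} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read all frames of an XYZ file; returns (coords (m,n,3), atom names)."""
    raw = [ln for ln in Path(path).read_text().splitlines()]
    frames: list[np.ndarray] = []
    names: list[str] = []
    i = 0
    while i < len(raw):
        if not raw[i].strip():
            i += 1
            continue
        try:
            n = int(raw[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path}: frame {len(frames)}: expected atom count line, got {raw[i]!r}") from exc
        block = raw[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: frame {len(frames)}: truncated (expected {n} atom lines)")
        coords = np.empty((n, 3))
        frame_names: list[str] = []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: frame {len(frames)}: malformed atom line {ln!r}")
            frame_names.append(parts[0])
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        if not names:
            names = frame_names
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: empty XYZ file")
    return np.stack(frames), names


# ----------------------------------------------------------------------
# multi-model PDB via biotite
# ----------------------------------------------------------------------

def _scan_pdb_model_counts(path: str | Path) -> list[int]:
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model_kw = False
    for ln in Path(path).read_text().splitlines():
        rec = ln[:6].strip()
        if rec == "MODEL":
            saw_model_kw = True
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current += 1
    if not saw_model_kw:
        counts = [current] if current else []
    elif in_model and current:
        counts.append(current)
    return counts


def write_pdb(path: str | Path, coords: np.ndarray, names: Sequence[str], roles: Sequence[str] | None = None) -> None:
    """Write one or more frames as a multi-model PDB.

    ``roles`` (optional, per atom, "protein"/"ligand") controls residue
    naming and hetero flags so viewers distinguish the ligand.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    m, n, _ = coords.shape
    if len(names) != n:
        raise ValueError(f"{len(names)} names for {n} atoms")
    if roles is None:
        roles = ["ligand"] * n
    stack = struc.AtomArrayStack(m, n)
    stack.coord = coords.astype(np.float32)
    stack.chain_id = np.array(["A" if r == "protein" else "L" for r in roles])
    stack.res_id = np.array([1 if r == "protein" else 2 for r in roles])
    stack.res_name = np.array(["PRO" if r == "protein" else "LIG" for r in roles])
    stack.atom_name = np.array([str(nm)[:4] for nm in names])
    stack.element = np.array([_element_of(nm) for nm in names])
    stack.hetero = np.array([r != "protein" for r in roles])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_pdb(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a (multi-model) PDB; returns (coords (m,n,3), atom names)."""
    pdb = PDBFile.read(str(path))
    coords = pdb.get_coord(model=None)
    if coords.ndim == 2:
        coords = coords[None]
    arr = pdb.get_structure(model=1)
    return np.asarray(coords, dtype=float), list(arr.atom_name)


# ----------------------------------------------------------------------
# ensemble-level reading
# ----------------------------------------------------------------------

def read_frames(path: str | Path, topology: Topology) -> np.ndarray:
    """Read one trajectory file (PDB or XYZ by extension), validating the
    per-frame atom count against the topology."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        raw = [ln for ln in path.read_text().splitlines()]
        # validate block headers frame by frame so errors cite the frame
        i, frame_no = 0, 0
        while i < len(raw):
            if not raw[i].strip():
                i += 1
                continue
            n = int(raw[i].strip())
            if n != topology.n_atoms:
                raise ValueError(
                    f"{path}: frame {frame_no} has {n} atoms, topology has {topology.n_atoms}"
                )
            i += 2 + n
            frame_no += 1
        coords, _ = read_xyz(path)
    elif suffix == ".pdb":
        counts = _scan_pdb_model_counts(path)
        if not counts:
            raise ValueError(f"{path}: empty PDB file (no ATOM records)")
        for frame_no, c in enumerate(counts):
            if c != topology.n_atoms:
                raise ValueError(
                    f"{path}: frame {frame_no} has {c} atoms, topology has {topology.n_atoms}"
                )
        coords, _ = read_pdb(path)
    else:
        raise ValueError(f"{path}: unsupported trajectory format {suffix!r} (use .pdb or .xyz)")
    if coords.shape[0] == 0:
        raise ValueError(f"{path}: empty trajectory file")
    return coords


def write_frames(path: str | Path, coords: np.ndarray, topology: Topology) -> None:
    names = topology.atom_names()
    roles = [a.role for a in topology.atoms]
    if Path(path).suffix.lower() == ".xyz":
        write_xyz(path, coords, names)
    else:
        write_pdb(path, coords, names, roles)


def read_ensemble(
    paths: Sequence[str | Path],
    topology: Topology | str | Path,
    frame_spacing_ns: float,
) -> TrajectoryEnsemble:
    """Build a :class:`TrajectoryEnsemble` from one file per trajectory."""
    if not isinstance(topology, Topology):
        topology = Topology.from_file(topology)
    trajectories = []
    for p in paths:
        coords = read_frames(p, topology)
        trajectories.append(Trajectory(coords, frame_spacing_ns, traj_id=str(p)))
    return TrajectoryEnsemble(topology, trajectories)
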