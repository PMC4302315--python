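"""Trajectory containers: frames of protein+ligand coordinates in Å."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .topology import Topology

__all__ = ["Trajectory", "TrajectoryEnsemble", "LigandPose", "FrameId"]

#: (trajectory index, frame index) pair identifying one frame of an ensemble.
FrameId = tuple[int, int]


@dataclass
class Trajectory:
    """One contiguous simulation run: ``coords`` has shape (n_frames, n_atoms, 3) Å."""

    coords: np.ndarray
    frame_spacing_ns: float
    traj_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] == 0:
            raise ValueError("trajectory must contain at least one frame")
        if not (self.frame_spacing_ns > 0):
            raise ValueError("frame spacing must be strictly positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


class TrajectoryEnsemble:
    """Independent trajectories sharing one :class:`Topology`.

    The ensemble is the raw input of the protocol: many parallel binding
    simulations whose frames are later pooled for clustering and transition
    counting (transitions are never counted across trajectory boundaries).
    """

    def __init__(self, topology: Topology, trajectories: Sequence[Trajectory]):
        self.topology = topology
        self.trajectories = list(trajectories)
        if not self.trajectories:
            raise ValueError("ensemble must contain at least one trajectory")
        for t in self.trajectories:
            if t.coords.shape[1] != topology.n_atoms:
                raise ValueError(
                    f"trajectory {t.traj_id!r}: {t.coords.shape[1]} atoms per frame, "
                    f"topology has {topology.n_atoms}"
                )

    @property
    def n_trajectories(self) -> int:
        return len(self.trajectories)

    @property
    def n_frames_total(self) -> int:
        return sum(t.n_frames for t in self.trajectories)

    @property
    def aggregate_time_ns(self) -> float:
        return sum(t.n_frames * t.frame_spacing_ns for t in self.trajectories)

    @property
    def frame_spacing_ns(self) -> float:
        spacings = {t.frame_spacing_ns for t in self.trajectories}
        if len(spacings) != 1:
            raise ValueError("trajectories have heterogeneous frame spacings")
        return spacings.pop()

    def get_frame(self, frame_id: FrameId) -> np.ndarray:
        ti, fi = frame_id
        return self.trajectories[ti].coords[fi]

    def iter_frame_ids(self, stride: int = 1) -> Iterator[FrameId]:
        for ti, t in enumerate(self.trajectories):
            for fi in range(0, t.n_frames, stride):
                yield (ti, fi)

    def prefix(self, max_aggregate_time_ns: float) -> "TrajectoryEnsemble":
        """Sub-ensemble holding exactly the first ``max_aggregate_time_ns`` of
        aggregate data, taking trajectories (and leading parts of the last
        included trajectory) in order."""
        budget = max_aggregate_time_ns
        out: list[Trajectory] = []
        for t in self.trajectories:
            if budget <= 0:
                break
            n_keep = min(t.n_frames, int(round(budget / t.frame_spacing_ns)))
            if n_keep >= 1:
                out.append(Trajectory(t.coords[:n_keep], t.frame_spacing_ns, t.traj_id))
            budget -= n_keep * t.frame_spacing_ns
        if not out:
            raise ValueError("prefix time shorter than a single frame")
        return TrajectoryEnsemble(self.topology, out)


@dataclass
class LigandPose:
    """Ligand heavy-atom coordinates (Å) in the protein-aligned frame."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("pose coords must have shape (n_heavy, 3)")

    def validate(self, topology: Topology) -> None:
        if self.coords.shape[0] != topology.n_ligand_heavy:
            raise ValueError(
                f"pose has {self.coords.shape[0]} atoms, topology expects "
                f"{topology.n_ligand_heavy} ligand heavy atoms"
            )
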