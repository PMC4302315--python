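"""Structural state definition by clustering of protein-aligned ligand poses.

k-centers (farthest-point) clustering guarantees every strided frame lies
within a radius ``cutoff`` of some cluster center; a hybrid k-medoids pass
then refines the centers by stochastic medoid-swap proposals with greedy
acceptance, which can only lower the within-cluster distance objective.
All distances are the exact pairwise protein-aligned ligand RMSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry
from .topology import Topology
from .trajectory import FrameId, TrajectoryEnsemble

__all__ = ["Assignments", "ClusterModel", "kcenters", "kmedoids_refine", "assign"]


@dataclass
class Assignments:
    """Cluster labels for a (possibly strided) sweep over an ensemble."""

    frame_ids: list[FrameId]
    labels: np.ndarray
    stride: int
    spacing_ns: float  # effective time between consecutive labelled frames

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.frame_ids) != len(self.labels):
            raise ValueError("frame_ids and labels length mismatch")

    def dtrajs(self) -> list[np.ndarray]:
        """Per-trajectory label sequences in frame order (for transition counting)."""
        order: dict[int, list[tuple[int, int]]] = {}
        for (ti, fi), lab in zip(self.frame_ids, self.labels):
            order.setdefault(ti, []).append((fi, lab))
        out = []
        for ti in sorted(order):
            seq = sorted(order[ti])
            out.append(np.array([lab for _, lab in seq], dtype=int))
        return out

    def frames_of_state(self, state: int) -> list[FrameId]:
        return [fid for fid, lab in zip(self.frame_ids, self.labels) if lab == state]

    def counts_per_state(self, n_states: int) -> np.ndarray:
        return np.bincount(self.labels, minlength=n_states)

    def to_csv(self, path: str | Path) -> None:
        lines = ["trajectory,frame,cluster"]
        for (ti, fi), lab in zip(self.frame_ids, self.labels):
            lines.append(f"{ti},{fi},{lab}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path, stride: int, spacing_ns: float) -> "Assignments":
        frame_ids: list[FrameId] = []
        labels: list[int] = []
        for line in Path(path).read_text().splitlines()[1:]:
            if not line.strip():
                continue
            ti, fi, lab = line.split(",")
            frame_ids.append((int(ti), int(fi)))
            labels.append(int(lab))
        return cls(frame_ids, np.array(labels), stride, spacing_ns)


@dataclass
class ClusterModel:
    """Cluster centers (medoids) plus the strided assignments that built them."""

    topology: Topology
    center_frame_ids: list[FrameId]
    center_coords: np.ndarray  # (K, n_atoms, 3)
    cutoff: float
    stride: int
    assignments: Assignments

    @property
    def n_clusters(self) -> int:
        return len(self.center_frame_ids)

    def validate(self, stack: np.ndarray | None = None) -> None:
        labels = self.assignments.labels
        if labels.min() < 0 or labels.max() >= self.n_clusters:
            raise AssertionError("labels out of range")
        if len(np.unique(labels)) != self.n_clusters:
            raise AssertionError("some cluster has no members")

    def representative_pose(self, state: int, reference_frame: np.ndarray) -> np.ndarray:
        """Ligand heavy-atom coordinates of a center, in the protein frame of
        ``reference_frame``."""
        aligned = geometry.superpose_frame(self.center_coords[state], reference_frame, self.topology)
        return aligned[self.topology.ligand_heavy_indices]


def _frame_stack(ensemble: TrajectoryEnsemble, frame_ids: list[FrameId]) -> np.ndarray:
    return np.stack([ensemble.get_frame(fid) for fid in frame_ids])


def _distances_to_centers(
    stack: np.ndarray, center_coords: np.ndarray, topology: Topology
) -> np.ndarray:
    """(n_frames, n_centers) matrix of exact ligand_rmsd(frame, center)."""
    out = np.empty((stack.shape[0], center_coords.shape[0]))
    for k in range(center_coords.shape[0]):
        out[:, k] = geometry.ligand_rmsd_to_reference(stack, center_coords[k], topology)
    return out


def kcenters(
    ensemble: TrajectoryEnsemble,
    cutoff: float = 3.0,
    stride: int = 100,
    seed_frame: FrameId = (0, 0),
) -> ClusterModel:
    """Farthest-point clustering until every strided frame is within
    ``cutoff`` Å (ligand RMSD) of its nearest center.

    Deterministic: the next center is always the frame farthest from the
    existing centers, starting from ``seed_frame``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    top = ensemble.topology
    frame_ids = list(ensemble.iter_frame_ids(stride))
    if not frame_ids:
        raise ValueError("empty ensemble")
    stack = _frame_stack(ensemble, frame_ids)
    try:
        seed_pos = frame_ids.index(tuple(seed_frame))
    except ValueError as exc:
        raise ValueError(f"seed frame {seed_frame} not among strided frames") from exc

    centers = [seed_pos]
    dist = geometry.ligand_rmsd_to_reference(stack, stack[seed_pos], top)
    labels = np.zeros(len(frame_ids), dtype=int)
    while dist.max() > cutoff and len(centers) < len(frame_ids):
        new_pos = int(np.argmax(dist))
        d_new = geometry.ligand_rmsd_to_reference(stack, stack[new_pos], top)
        take = d_new < dist  # strict: ties stay with the lower (earlier) center
        labels[take] = len(centers)
        dist = np.where(take, d_new, dist)
        centers.append(new_pos)

    spacing = ensemble.frame_spacing_ns * stride
    assignments = Assignments(frame_ids, labels, stride, spacing)
    model = ClusterModel(
        topology=top,
        center_frame_ids=[frame_ids[p] for p in centers],
        center_coords=stack[centers].copy(),
        cutoff=cutoff,
        stride=stride,
        assignments=assignments,
    )
    return model


def kmedoids_refine(
    model: ClusterModel,
    ensemble: TrajectoryEnsemble,
    n_iter: int = 5,
    rng_seed: int = 0,
) -> ClusterModel:
    """Hybrid k-medoids refinement.

    Each pass proposes, per cluster, one random member as the new medoid and
    accepts iff the within-cluster sum of distances to the medoid does not
    increase; frames are then reassigned to their nearest medoids.  The
    total within-cluster distance is non-increasing across passes.  Clusters
    emptied by reassignment (possible when two medoids coincide) are dropped
    and labels re-densified.
    """
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    if n_iter == 0:
        return model
    top = ensemble.topology
    frame_ids = model.assignments.frame_ids
    stack = _frame_stack(ensemble, frame_ids)
    labels = model.assignments.labels.copy()
    center_pos = np.array([frame_ids.index(fid) for fid in model.center_frame_ids])
    rng = np.random.default_rng(rng_seed)

    for _ in range(n_iter):
        for k in range(len(center_pos)):
            members = np.flatnonzero(labels == k)
            if members.size == 0:
                continue
            cand = int(rng.choice(members))
            if cand == center_pos[k]:
                continue
            d_cur = geometry.ligand_rmsd_to_reference(stack[members], stack[center_pos[k]], top)
            d_cand = geometry.ligand_rmsd_to_reference(stack[members], stack[cand], top)
            if d_cand.sum() <= d_cur.sum():
                center_pos[k] = cand
        dmat = _distances_to_centers(stack, stack[center_pos], top)
        labels = np.argmin(dmat, axis=1)
        # drop empty clusters, keep labels dense
        occupied = np.unique(labels)
        if occupied.size < len(center_pos):
            remap = -np.ones(len(center_pos), dtype=int)
            remap[occupied] = np.arange(occupied.size)
            labels = remap[labels]
            center_pos = center_pos[occupied]

    spacing = ensemble.frame_spacing_ns * model.stride
    assignments = Assignments(frame_ids, labels, model.stride, spacing)
    return ClusterModel(
        topology=top,
        center_frame_ids=[frame_ids[p] for p in center_pos],
        center_coords=stack[center_pos].copy(),
        cutoff=model.cutoff,
        stride=model.stride,
        assignments=assignments,
    )


def kmedoids_objective(model: ClusterModel, ensemble: TrajectoryEnsemble) -> float:
    """Total within-cluster sum of member-to-medoid distances (Å)."""
    stack = _frame_stack(ensemble, model.assignments.frame_ids)
    total = 0.0
    for k in range(model.n_clusters):
        members = np.flatnonzero(model.assignments.labels == k)
        d = geometry.ligand_rmsd_to_reference(stack[members], model.center_coords[k], ensemble.topology)
        total += float(d.sum())
    return total


def assign(
    ensemble: TrajectoryEnsemble,
    model: ClusterModel,
    stride: int = 1,
    chunk: int = 4096,
) -> Assignments:
    """Map every ``stride``-th frame to its nearest center by ligand RMSD.

    Ties (within exact float equality) go to the lowest cluster index.
    """
    if ensemble.topology.n_atoms != model.center_coords.shape[1]:
        raise ValueError("topology mismatch between ensemble and cluster model")
    if ensemble.topology != model.topology:
        raise ValueError("topology mismatch between ensemble and cluster model")
    frame_ids = list(ensemble.iter_frame_ids(stride))
    labels = np.empty(len(frame_ids), dtype=int)
    for lo in range(0, len(frame_ids), chunk):
        ids = frame_ids[lo : lo + chunk]
        stack = _frame_stack(ensemble, ids)
        dmat = _distances_to_centers(stack, model.center_coords, ensemble.topology)
        labels[lo : lo + len(ids)] = np.argmin(dmat, axis=1)
    spacing = ensemble.frame_spacing_ns * stride
    return Assignments(frame_ids, labels, stride, spacing)
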