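"""Adaptive-sampling workflow: convergence monitoring, seed selection, and
initial-ensemble pose seeding.

The protocol loop is: simulate → cluster → MSM → rank; monitor the RMSD of
the top-populated state's pose to a reference at fixed aggregate-time
checkpoints (rolling mean/std over 2 points); if not converged, seed new
simulations from the current MSM states and repeat.  This module never
launches simulations — it emits restart structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cluster import Assignments
from .msm import TransitionModel
from .pipeline import run_pose_pipeline
from .topology import Topology
from .trajectory import FrameId, LigandPose, TrajectoryEnsemble

__all__ = [
    "ConvergenceSeries",
    "SeedSet",
    "convergence_series",
    "select_seeds",
    "grid_pose_seeding",
]


@dataclass
class ConvergenceSeries:
    """Top-state pose RMSD to the reference across aggregate-time checkpoints."""

    times_us: np.ndarray
    rmsd_A: np.ndarray
    interval_us: float
    skipped: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times_us = np.asarray(self.times_us, dtype=float)
        self.rmsd_A = np.asarray(self.rmsd_A, dtype=float)
        if np.any(np.diff(self.times_us) <= 0):
            raise ValueError("checkpoint times must be strictly increasing")

    @property
    def rolling_mean(self) -> np.ndarray:
        """Mean over a 2-point window; undefined (NaN) at the first point."""
        out = np.full_like(self.rmsd_A, np.nan)
        if len(self.rmsd_A) >= 2:
            out[1:] = 0.5 * (self.rmsd_A[1:] + self.rmsd_A[:-1])
        return out

    @property
    def rolling_std(self) -> np.ndarray:
        out = np.full_like(self.rmsd_A, np.nan)
        if len(self.rmsd_A) >= 2:
            pairs = np.stack([self.rmsd_A[1:], self.rmsd_A[:-1]])
            out[1:] = pairs.std(axis=0)
        return out

    def is_converged(self, tolerance_A: float = 0.5) -> bool:
        """Converged when the last two checkpoints differ by < tolerance."""
        if len(self.rmsd_A) < 2:
            return False
        return bool(abs(self.rmsd_A[-1] - self.rmsd_A[-2]) < tolerance_A)

    def to_csv(self, path: str | Path) -> None:
        lines = ["aggregate_time_us,rmsd_A,rolling_mean,rolling_std"]
        rm, rs = self.rolling_mean, self.rolling_std
        for i in range(len(self.times_us)):
            m = "" if np.isnan(rm[i]) else format(rm[i], ".8g")
            s = "" if np.isnan(rs[i]) else format(rs[i], ".8g")
            lines.append(f"{self.times_us[i]:.8g},{self.rmsd_A[i]:.8g},{m},{s}")
        Path(path).write_text("\n".join(lines) + "\n")


def convergence_series(
    ensemble: TrajectoryEnsemble,
    reference: LigandPose,
    interval_us: float = 10.0,
    **pipeline_kwargs,
) -> ConvergenceSeries:
    """Rebuild the full pipeline on growing data prefixes and track the
    top-state pose RMSD to ``reference``.

    Checkpoint k uses exactly the first ``k × interval_us`` of aggregate
    simulation time (trajectories taken in order, the last one truncated).
    Checkpoints whose MSM retains fewer than 2 states are skipped with a
    warning.
    """
    reference.validate(ensemble.topology)
    total_us = ensemble.aggregate_time_ns / 1000.0
    n_checkpoints = int(np.floor(total_us / interval_us + 1e-9))
    if n_checkpoints < 1:
        raise ValueError("ensemble shorter than one checkpoint interval")
    times, rmsds, skipped = [], [], []
    for k in range(1, n_checkpoints + 1):
        t_us = k * interval_us
        sub = ensemble.prefix(t_us * 1000.0)
        try:
            result = run_pose_pipeline(sub, **pipeline_kwargs)
        except Exception as exc:  # noqa: BLE001 - a thin prefix may fail to model
            warnings.warn(f"checkpoint {t_us:g} us skipped: {exc}", stacklevel=2)
            skipped.append(t_us)
            continue
        if result.msm.n_states < 2:
            warnings.warn(f"checkpoint {t_us:g} us skipped: fewer than 2 states", stacklevel=2)
            skipped.append(t_us)
            continue
        diff = result.top_pose.coords - reference.coords
        rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
        times.append(t_us)
        rmsds.append(rmsd)
    if not times:
        raise ValueError("every checkpoint was skipped; not enough data to monitor convergence")
    return ConvergenceSeries(np.array(times), np.array(rmsds), interval_us, skipped)


@dataclass
class SeedSet:
    """Restart structures chosen from MSM states."""

    picks: list[tuple[int, FrameId]]  # (original state index, frame id)
    policy: str
    rng_seed: int

    def __post_init__(self) -> None:
        if not self.picks:
            raise ValueError("seed set must be non-empty")


def select_seeds(
    model: TransitionModel,
    assignments: Assignments,
    n_seeds: int,
    policy: str = "inverse-counts",
    rng_seed: int = 0,
) -> SeedSet:
    """Choose restart frames from MSM states.

    ``uniform-states``: states drawn uniformly; ``inverse-counts``: states
    drawn with probability ∝ 1/(frames observed in the state), which focuses
    new sampling on poorly sampled states.  Within a chosen state the frame
    is drawn uniformly.  Deterministic under ``rng_seed``.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if n_seeds > len(assignments.frame_ids):
        raise ValueError(f"n_seeds={n_seeds} exceeds the {len(assignments.frame_ids)} available frames")
    pools = {int(orig): assignments.frames_of_state(int(orig)) for orig in model.state_map}
    states = [s for s in pools if pools[s]]
    if not states:
        raise ValueError("no retained state has assigned frames")
    counts = np.array([len(pools[s]) for s in states], dtype=float)
    if policy == "uniform-states":
        probs = np.full(len(states), 1.0 / len(states))
    elif policy == "inverse-counts":
        probs = 1.0 / counts
        probs /= probs.sum()
    else:
        raise ValueError(f"unknown seeding policy {policy!r}")
    rng = np.random.default_rng(rng_seed)
    picks: list[tuple[int, FrameId]] = []
    chosen = rng.choice(len(states), size=n_seeds, p=probs)
    for c in chosen:
        state = states[int(c)]
        frame = pools[state][int(rng.integers(len(pools[state])))]
        picks.append((state, frame))
    return SeedSet(picks, policy, rng_seed)


def grid_pose_seeding(
    frame: np.ndarray,
    topology: Topology,
    box_extent: float = 20.0,
    grid_step: float = 5.0,
    clash_cutoff: float = 2.0,
) -> list[np.ndarray]:
    """Generate near-bound and unbound starting structures by rigid ligand
    translation over a cubic lattice of half-width ``box_extent`` (Å) around
    the ligand's current centroid, rejecting poses whose minimum ligand
    heavy-atom to protein-atom distance falls below ``clash_cutoff``.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (topology.n_atoms, 3):
        raise ValueError(f"frame has shape {frame.shape}, expected ({topology.n_atoms}, 3)")
    lig_all = topology.ligand_indices
    lig_heavy = topology.ligand_heavy_indices
    prot = topology.protein_indices
    offsets_1d = np.arange(-box_extent, box_extent + grid_step / 2, grid_step)
    poses: list[np.ndarray] = []
    for ox in offsets_1d:
        for oy in offsets_1d:
            for oz in offsets_1d:
                shift = np.array([ox, oy, oz])
                pose = frame.copy()
                pose[lig_all] += shift
                d = np.linalg.norm(
                    pose[lig_heavy][:, None, :] - pose[prot][None, :, :], axis=2
                )
                if d.min() >= clash_cutoff:
                    poses.append(pose)
    if not poses:
        raise ValueError("no clash-free poses on the translation lattice; widen the box or lower the cutoff")
    return poses
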