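"""Ground-truth generators: exact Markov chains and a toy binding simulator.

The toy binding system emulates the landscape the protocol is built for —
one deep "bound" well at a protein pocket, shallower nonspecific sites, and
a large flat unbound region — with a known Boltzmann structure.  The rigid
ligand's centroid performs a Metropolis random walk (symmetric Gaussian
proposals, acceptance ``min(1, e^{−ΔU/kT})``) over a sum-of-Gaussian-wells
potential with reflecting box walls and a hard-core exclusion around the
protein atoms.  Metropolis dynamics sample the stationary distribution
exactly, so basin populations can be checked against numerical quadrature
of the Boltzmann weight, with no integrator discretisation bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fmap import KB_KCAL_PER_MOL_K
from .topology import AtomRecord, Topology
from .trajectory import LigandPose, Trajectory, TrajectoryEnsemble

__all__ = [
    "ChainSpec",
    "sample_chain",
    "GaussianWell",
    "ToyBindingSpec",
    "simulate_toy_binding",
    "empirical_entry_mfpt",
    "brute_force_entry_mfpt",
]


# ----------------------------------------------------------------------
# discrete Markov chain sampler
# ----------------------------------------------------------------------

@dataclass
class ChainSpec:
    """Exactly specified discrete-state chain: row-stochastic P, step time."""

    transition_matrix: np.ndarray
    step_ns: float = 1.0
    seed: int = 0
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.transition_matrix, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("transition matrix must be square")
        if (p < 0).any():
            raise ValueError("transition matrix entries must be >= 0")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1 (within 1e-12)")
        self.transition_matrix = p


def sample_chain(
    spec: ChainSpec,
    n_steps: int,
    n_trajectories: int = 1,
    initial_states: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Sample exact state sequences from the chain.

    Initial states are uniform over the state space unless given;
    reproducible under the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.transition_matrix
    k = p.shape[0]
    cum = np.cumsum(p, axis=1)
    if initial_states is None:
        initial_states = rng.integers(0, k, size=n_trajectories)
    out = []
    for t in range(n_trajectories):
        seq = np.empty(n_steps, dtype=int)
        s = int(initial_states[t])
        u = rng.random(n_steps)
        for i in range(n_steps):
            seq[i] = s
            s = int(np.searchsorted(cum[s], u[i], side="right"))
            s = min(s, k - 1)  # guard against u landing on the last boundary
        out.append(seq)
    return out


# ----------------------------------------------------------------------
# toy 3-D binding simulator
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianWell:
    """Isotropic attractive well: depth (kcal/mol) > 0, width (Å)."""

    center: tuple[float, float, float]
    depth: float
    width: float


def _default_protein() -> tuple[np.ndarray, int]:
    """12 pseudo-backbone atoms on a helical arc plus 8 shell atoms.

    Returns (coords, n_backbone); the backbone atoms come first.
    """
    n_bb = 12
    theta = np.linspace(0.0, 5.0 * np.pi / 3.0, n_bb)
    z = np.linspace(-4.0, 4.0, n_bb)
    backbone = np.stack([4.0 * np.cos(theta), 4.0 * np.sin(theta), z], axis=1)
    s = 3.5
    shell = np.array(
        [[sx, sy, sz] for sx in (-s, s) for sy in (-s, s) for sz in (-s, s)], dtype=float
    )
    return np.vstack([backbone, shell]), n_bb


def _default_ligand_geometry() -> np.ndarray:
    """Rigid 3-atom ligand (Å offsets from the centroid)."""
    geom = np.array([[0.0, 0.0, 0.0], [1.4, 0.0, 0.0], [0.7, 1.2, 0.0]])
    return geom - geom.mean(axis=0)


@dataclass
class ToyBindingSpec:
    """Study conditions of the toy binding system.

    The first well is the designed bound well; its depth must strictly
    exceed every nonspecific depth, and the box must leave a shell more
    than 20 Å from every protein atom so that unbound macrostates exist.
    """

    wells: tuple[GaussianWell, ...] = (
        GaussianWell((8.0, 0.0, 0.0), depth=5.0, width=1.6),
        GaussianWell((-9.0, 0.0, 5.0), depth=2.5, width=2.0),
        GaussianWell((0.0, 10.0, -4.0), depth=2.0, width=2.0),
    )
    box_half_width: float = 26.5
    temperature: float = 300.0
    step_size: float = 2.2
    n_steps: int = 2000
    n_trajectories: int = 12
    frame_spacing_ns: float = 0.1
    core_radius: float = 2.5
    basin_radius: float = 3.0
    seed: int = 2025
    #: draw starting positions from the exact Boltzmann density (rejection
    #: sampling) instead of the bound/nonspecific/unbound mix; with
    #: stationary starts every frame samples the equilibrium distribution,
    #: which makes occupancy checks against quadrature unbiased.
    equilibrium_starts: bool = False
    protein_coords: np.ndarray = field(default_factory=lambda: _default_protein()[0])
    n_backbone: int = 12
    ligand_geometry: np.ndarray = field(default_factory=_default_ligand_geometry)

    def __post_init__(self) -> None:
        self.protein_coords = np.asarray(self.protein_coords, dtype=float)
        self.ligand_geometry = np.asarray(self.ligand_geometry, dtype=float)
        if len(self.wells) < 1:
            raise ValueError("at least one (bound) well is required")
        depths = [w.depth for w in self.wells]
        if any(d >= depths[0] for d in depths[1:]):
            raise ValueError("bound-well depth must strictly exceed all nonspecific depths")
        protein_extent = float(np.linalg.norm(self.protein_coords, axis=1).max())
        if self.box_half_width <= protein_extent + 20.0:
            raise ValueError(
                "box must extend more than 20 Å beyond the protein "
                f"(half-width {self.box_half_width} vs protein extent {protein_extent:.1f} + 20)"
            )
        for w in self.wells:
            if np.abs(np.asarray(w.center)).max() >= self.box_half_width:
                raise ValueError(f"well at {w.center} lies outside the box")

    def topology(self) -> Topology:
        atoms = []
        i = 0
        for k in range(len(self.protein_coords)):
            atoms.append(AtomRecord(i, "CA" if k < self.n_backbone else "CB", "protein", backbone=k < self.n_backbone))
            i += 1
        for _ in range(len(self.ligand_geometry)):
            atoms.append(AtomRecord(i, "C1", "ligand", heavy=True))
            i += 1
        return Topology(atoms)

    def potential(self, positions: np.ndarray) -> np.ndarray:
        """U(r) in kcal/mol for centroid positions (..., 3)."""
        positions = np.asarray(positions, dtype=float)
        u = np.zeros(positions.shape[:-1])
        for w in self.wells:
            d2 = np.sum((positions - np.asarray(w.center)) ** 2, axis=-1)
            u -= w.depth * np.exp(-d2 / (2.0 * w.width**2))
        return u

    def allowed(self, positions: np.ndarray) -> np.ndarray:
        """Hard constraints: inside the box and outside the protein core."""
        positions = np.asarray(positions, dtype=float)
        inside = (np.abs(positions) < self.box_half_width).all(axis=-1)
        d = np.linalg.norm(positions[..., None, :] - self.protein_coords[None, :, :], axis=-1)
        return inside & (d.min(axis=-1) >= self.core_radius)

    def bound_pose(self) -> LigandPose:
        return LigandPose(self.ligand_geometry + np.asarray(self.wells[0].center))


def _boltzmann_starts(spec: ToyBindingSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample starting positions from exp(-U/kT) over the box."""
    kt = KB_KCAL_PER_MOL_K * spec.temperature
    w_max = np.exp(sum(w.depth for w in spec.wells) / kt)
    starts = np.empty((spec.n_trajectories, 3))
    filled = 0
    while filled < spec.n_trajectories:
        cand = rng.uniform(-spec.box_half_width, spec.box_half_width, (256, 3))
        weight = np.exp(-spec.potential(cand) / kt) * spec.allowed(cand)
        keep = cand[rng.random(256) < weight / w_max]
        take = min(len(keep), spec.n_trajectories - filled)
        starts[filled : filled + take] = keep[:take]
        filled += take
    return starts


def _start_positions(spec: ToyBindingSpec, rng: np.random.Generator) -> np.ndarray:
    """Diverse starting structures: bound, nonspecific, and unbound starts."""
    if spec.equilibrium_starts:
        return _boltzmann_starts(spec, rng)
    starts = []
    menu: list[np.ndarray] = [np.asarray(w.center, dtype=float) for w in spec.wells]
    for t in range(spec.n_trajectories):
        if t % 2 == 0 and t // 2 < len(menu) * 2:
            base = menu[(t // 2) % len(menu)]
            pos = base + rng.normal(0.0, 0.5, 3)
            if not spec.allowed(pos):
                pos = base
        else:
            while True:
                pos = rng.uniform(-spec.box_half_width + 1.0, spec.box_half_width - 1.0, 3)
                if spec.allowed(pos):
                    break
        starts.append(pos)
    return np.stack(starts)


def simulate_toy_binding(
    spec: ToyBindingSpec,
) -> tuple[TrajectoryEnsemble, dict]:
    """Run the Metropolis walk; returns the ensemble and a ground-truth record.

    The ground-truth record carries the well definitions, the designed bound
    pose, and each basin's Boltzmann weight obtained by numerical quadrature
    of ``exp(−U/kT)`` (with the hard constraints applied) over a sphere of
    ``basin_radius`` around each well center, plus the weight of the full
    accessible box for normalisation.
    """
    rng = np.random.default_rng(spec.seed)
    kt = KB_KCAL_PER_MOL_K * spec.temperature
    top = spec.topology()
    starts = _start_positions(spec, rng)
    trajectories = []
    for t in range(spec.n_trajectories):
        pos = starts[t].copy()
        u_cur = float(spec.potential(pos))
        centroids = np.empty((spec.n_steps, 3))
        steps = rng.normal(0.0, spec.step_size, (spec.n_steps, 3))
        accept_u = rng.random(spec.n_steps)
        for i in range(spec.n_steps):
            prop = pos + steps[i]
            if spec.allowed(prop):
                u_prop = float(spec.potential(prop))
                if u_prop <= u_cur or accept_u[i] < np.exp(-(u_prop - u_cur) / kt):
                    pos, u_cur = prop, u_prop
            centroids[i] = pos
        frames = np.empty((spec.n_steps, top.n_atoms, 3))
        frames[:, : len(spec.protein_coords), :] = spec.protein_coords
        frames[:, len(spec.protein_coords) :, :] = (
            spec.ligand_geometry[None, :, :] + centroids[:, None, :]
        )
        trajectories.append(Trajectory(frames, spec.frame_spacing_ns, traj_id=f"toy-{t}"))
    ensemble = TrajectoryEnsemble(top, trajectories)
    return ensemble, ground_truth_record(spec)


def ground_truth_record(spec: ToyBindingSpec, quad_step: float = 0.5) -> dict:
    """Analytic/quadrature description of the designed landscape."""
    kt = KB_KCAL_PER_MOL_K * spec.temperature
    h = quad_step
    ax = np.arange(-spec.box_half_width + h / 2, spec.box_half_width, h)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    # evaluate in chunks to bound memory
    weight = np.empty(len(pts))
    allowed = np.empty(len(pts), dtype=bool)
    for lo in range(0, len(pts), 200_000):
        sl = slice(lo, lo + 200_000)
        allowed[sl] = spec.allowed(pts[sl])
        weight[sl] = np.exp(-spec.potential(pts[sl]) / kt)
    weight[~allowed] = 0.0
    basin_weights = []
    for w in spec.wells:
        d2 = np.sum((pts - np.asarray(w.center)) ** 2, axis=1)
        basin_weights.append(float(weight[d2 <= spec.basin_radius**2].sum() * h**3))
    total_weight = float(weight.sum() * h**3)
    return {
        "wells": [
            {"center": list(w.center), "depth_kcal_mol": w.depth, "width_A": w.width}
            for w in spec.wells
        ],
        "bound_well_index": 0,
        "bound_pose": spec.bound_pose().coords.tolist(),
        "basin_radius_A": spec.basin_radius,
        "basin_boltzmann_weights_A3": basin_weights,
        "accessible_boltzmann_weight_A3": total_weight,
        "basin_populations": [bw / total_weight for bw in basin_weights],
        "temperature_K": spec.temperature,
        "box_half_width_A": spec.box_half_width,
        "frame_spacing_ns": spec.frame_spacing_ns,
    }


def empirical_entry_mfpt(
    ensemble: TrajectoryEnsemble,
    spec: ToyBindingSpec,
    unbound_cutoff: float = 20.0,
) -> float:
    """Censoring-corrected unbound→bound mean first passage time (ns).

    Every entry of the ligand centroid into the unbound region (more than
    ``unbound_cutoff`` from all protein atoms) starts a clock that stops at
    the next entry into the bound basin, or is censored at the trajectory
    end.  Assuming near-exponential passage times, the maximum-likelihood
    mean is (total clock time, censored spells included) / (number of
    completed passages) — the naive mean over completed spells only would be
    biased far downward whenever trajectories are shorter than the MFPT.
    """
    bound_center = np.asarray(spec.wells[0].center)
    lig = ensemble.topology.ligand_heavy_indices
    total_time = 0.0
    events = 0
    for traj in ensemble.trajectories:
        centroids = traj.coords[:, lig, :].mean(axis=1)
        dprot = np.linalg.norm(
            centroids[:, None, :] - spec.protein_coords[None, :, :], axis=2
        ).min(axis=1)
        unbound = dprot > unbound_cutoff
        bound = np.linalg.norm(centroids - bound_center, axis=1) <= spec.basin_radius
        clock_start: int | None = None
        for i in range(traj.n_frames):
            if clock_start is None:
                if unbound[i]:
                    clock_start = i
            elif bound[i]:
                total_time += (i - clock_start) * traj.frame_spacing_ns
                events += 1
                clock_start = None
        if clock_start is not None:
            total_time += (traj.n_frames - 1 - clock_start) * traj.frame_spacing_ns
    if events == 0:
        raise ValueError("no completed unbound→bound passages observed in the ensemble")
    return total_time / events


def brute_force_entry_mfpt(
    spec: ToyBindingSpec,
    n_walkers: int = 64,
    max_steps: int = 200_000,
    unbound_cutoff: float = 20.0,
    seed: int = 0,
) -> float:
    """Independent first-passage oracle: mean time (ns) for Metropolis
    walkers started uniformly in the unbound region to first enter the
    bound basin.

    Uses the same dynamics as the simulator but runs each walker to
    absorption, so the estimate is free of the trajectory-length censoring
    that afflicts estimates from a fixed-length ensemble.
    """
    rng = np.random.default_rng(seed)
    kt = KB_KCAL_PER_MOL_K * spec.temperature
    bound_center = np.asarray(spec.wells[0].center)

    def unbound_ok(p: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(p[:, None, :] - spec.protein_coords[None, :, :], axis=2).min(axis=1)
        return spec.allowed(p) & (d > unbound_cutoff)

    # rejection-sample uniform unbound starting points
    starts = np.empty((n_walkers, 3))
    filled = 0
    while filled < n_walkers:
        cand = rng.uniform(-spec.box_half_width, spec.box_half_width, (4 * n_walkers, 3))
        ok = cand[unbound_ok(cand)]
        take = min(len(ok), n_walkers - filled)
        starts[filled : filled + take] = ok[:take]
        filled += take

    pos = starts.copy()
    u_cur = spec.potential(pos)
    alive = np.ones(n_walkers, dtype=bool)
    hit_step = np.full(n_walkers, -1)
    for step in range(1, max_steps + 1):
        if not alive.any():
            break
        idx = np.flatnonzero(alive)
        prop = pos[idx] + rng.normal(0.0, spec.step_size, (idx.size, 3))
        ok = spec.allowed(prop)
        u_prop = spec.potential(prop)
        acc = ok & (rng.random(idx.size) < np.exp(-np.maximum(u_prop - u_cur[idx], 0.0) / kt))
        moved = idx[acc]
        pos[moved] = prop[acc]
        u_cur[moved] = u_prop[acc]
        entered = np.linalg.norm(pos[idx] - bound_center, axis=1) <= spec.basin_radius
        done = idx[entered]
        hit_step[done] = step
        alive[done] = False
    finished = hit_step > 0
    if finished.sum() < max(2, n_walkers // 4):
        raise RuntimeError("too few walkers absorbed; raise max_steps")
    # censored-MLE mean: walkers still alive contribute their elapsed time
    total = hit_step[finished].sum() + max_steps * (~finished).sum()
    return float(total * spec.frame_spacing_ns / finished.sum())


def save_ground_truth(record: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
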