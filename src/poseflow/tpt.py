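"""Transition path theory on the MSM: committors, fluxes, pathways, rates.

The bound (sink) and unbound (source) macrostates are defined geometrically:
a state is unbound when its ligand sits more than ``unbound_cutoff`` (default
20 Å) from every protein atom, bound when its ligand RMSD to the reference
pose is below ``bound_cutoff`` (default 3 Å).  The committor q+ solves a
linear system; the reactive gross flux is ``f_ij = π_i (1−q+_i) P_ij q+_j``,
netted and decomposed into pathways by repeated extraction of the widest
(maximum-bottleneck) source→sink path.  Association kinetics come from the
mean first passage time linear system; the rate is 1/⟨MFPT⟩ with the
π-weighted average over source states.
"""

from __future__ import annotations

import heapq
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry
from .cluster import ClusterModel
from .msm import TransitionModel
from .trajectory import LigandPose, TrajectoryEnsemble

__all__ = [
    "MacrostateDefinition",
    "TPTResult",
    "define_macrostates",
    "committor",
    "net_flux",
    "top_pathways",
    "mfpt",
    "analyse",
]


@dataclass
class MacrostateDefinition:
    """Disjoint, non-empty source (unbound) and sink (bound) state sets,
    indexed over the retained states of the transition model."""

    source: np.ndarray
    sink: np.ndarray
    unbound_cutoff: float = 20.0
    bound_cutoff: float = 3.0

    def __post_init__(self) -> None:
        self.source = np.asarray(sorted(set(int(s) for s in self.source)), dtype=int)
        self.sink = np.asarray(sorted(set(int(s) for s in self.sink)), dtype=int)
        if self.source.size == 0 or self.sink.size == 0:
            raise ValueError("source and sink must be non-empty")
        if set(self.source) & set(self.sink):
            raise ValueError("source and sink must be disjoint")
        if self.unbound_cutoff <= 0 or self.bound_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


def define_macrostates(
    model: TransitionModel,
    cluster_model: ClusterModel,
    reference: LigandPose | np.ndarray,
    reference_frame: np.ndarray,
    unbound_cutoff: float = 20.0,
    bound_cutoff: float = 3.0,
    assignments=None,
    ensemble: TrajectoryEnsemble | None = None,
    strict_all_frames: bool = False,
) -> MacrostateDefinition:
    """Classify retained states into unbound source / bound sink sets.

    A state is unbound iff the minimum distance between any ligand heavy
    atom and any protein atom exceeds ``unbound_cutoff``; bound iff the
    ligand RMSD to ``reference`` (a pose in the protein-aligned frame of
    ``reference_frame``) is below ``bound_cutoff``.  By default each state
    is judged by its medoid frame; ``strict_all_frames`` requires every
    assigned frame to satisfy the criterion (needs ``assignments`` and
    ``ensemble``).
    """
    top = cluster_model.topology
    if isinstance(reference, LigandPose):
        reference.validate(top)
        ref_pose = reference.coords
    else:
        reference = np.asarray(reference, dtype=float)
        if reference.shape == (top.n_atoms, 3):
            aligned = geometry.superpose_frame(reference, reference_frame, top)
            ref_pose = aligned[top.ligand_heavy_indices]
        else:
            ref_pose = reference
    lig = top.ligand_heavy_indices
    prot = top.protein_indices

    def frame_unbound(frame: np.ndarray) -> bool:
        d = np.linalg.norm(frame[lig][:, None, :] - frame[prot][None, :, :], axis=2)
        return bool(d.min() > unbound_cutoff)

    def frame_bound(frame: np.ndarray) -> bool:
        aligned = geometry.superpose_frame(frame, reference_frame, top)
        diff = aligned[lig] - ref_pose
        rmsd = np.sqrt(np.mean(np.sum(diff * diff, axis=1)))
        return bool(rmsd < bound_cutoff)

    source, sink = [], []
    for j, orig in enumerate(model.state_map):
        if strict_all_frames:
            if assignments is None or ensemble is None:
                raise ValueError("strict_all_frames requires assignments and ensemble")
            frames = [ensemble.get_frame(fid) for fid in assignments.frames_of_state(int(orig))]
        else:
            frames = [cluster_model.center_coords[int(orig)]]
        if all(frame_unbound(f) for f in frames):
            source.append(j)
        elif all(frame_bound(f) for f in frames):
            sink.append(j)
    if not source:
        raise ValueError(
            f"no unbound states at cutoff {unbound_cutoff} Å; lower the unbound cutoff or sample farther"
        )
    if not sink:
        raise ValueError(
            f"no bound states at RMSD cutoff {bound_cutoff} Å; raise the bound cutoff or check the reference"
        )
    return MacrostateDefinition(np.array(source), np.array(sink), unbound_cutoff, bound_cutoff)


def committor(model: TransitionModel, macro: MacrostateDefinition) -> np.ndarray:
    """Forward committor q+: probability of reaching the sink before the
    source; 0 on source, 1 on sink, solves q_i = Σ_j P_ij q_j elsewhere."""
    p = model.transition_matrix
    n = p.shape[0]
    q = np.zeros(n)
    q[macro.sink] = 1.0
    inter = np.setdiff1d(np.arange(n), np.concatenate([macro.source, macro.sink]))
    if inter.size:
        a = np.eye(inter.size) - p[np.ix_(inter, inter)]
        b = p[np.ix_(inter, macro.sink)].sum(axis=1)
        try:
            q[inter] = np.linalg.solve(a, b)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"singular committor system; intermediate states {inter.tolist()} "
                "are not connected to the boundary sets"
            ) from exc
    return np.clip(q, 0.0, 1.0)


def net_flux(
    model: TransitionModel, q_plus: np.ndarray, macro: MacrostateDefinition
) -> tuple[np.ndarray, float]:
    """Net reactive flux matrix and total source→sink reactive flux.

    Gross flux ``f_ij = π_i (1−q+_i) P_ij q+_j`` (i≠j), netted as
    ``max(0, f_ij − f_ji)``; the total flux is the netted outflow of the
    source set.  Units: probability per lag time.
    """
    p, pi = model.transition_matrix, model.stationary_distribution
    f = pi[:, None] * (1.0 - q_plus)[:, None] * p * q_plus[None, :]
    np.fill_diagonal(f, 0.0)
    net = np.maximum(0.0, f - f.T)
    total = float(net[macro.source, :].sum())
    return net, total


def _widest_path(flux: np.ndarray, sources: np.ndarray, sinks: np.ndarray) -> tuple[list[int] | None, float]:
    """Maximum-bottleneck source→sink path by maximin Dijkstra; ties between
    equal-bottleneck paths resolve to the lexicographically smallest path."""
    sink_set = set(int(s) for s in sinks)
    best: dict[int, float] = {}
    heap: list[tuple[float, tuple[int, ...]]] = []
    for s in sorted(int(x) for x in sources):
        best[s] = np.inf
        heapq.heappush(heap, (-np.inf, (s,)))
    while heap:
        neg_w, path = heapq.heappop(heap)
        w = -neg_w
        node = path[-1]
        if w < best.get(node, 0.0):
            continue
        if node in sink_set:
            return list(path), w
        for j in np.flatnonzero(flux[node] > 0):
            nw = min(w, flux[node, int(j)])
            if nw > best.get(int(j), 0.0):
                best[int(j)] = nw
                heapq.heappush(heap, (-nw, path + (int(j),)))
    return None, 0.0


def top_pathways(
    flux: np.ndarray,
    macro: MacrostateDefinition,
    threshold_fraction: float = 0.5,
    max_paths: int = 100_000,
) -> list[tuple[list[int], float]]:
    """Decompose the net flux into pathways by bottleneck extraction.

    Repeatedly finds the highest-bottleneck source→sink path, records it
    with its bottleneck flux and subtracts that flux along the path.
    Extraction stops when the next path's flux falls below
    ``threshold_fraction`` times the first (maximum-flux) path's flux; a
    threshold of 0 yields the complete decomposition.
    """
    residual = flux.astype(float).copy()
    paths: list[tuple[list[int], float]] = []
    first: float | None = None
    while len(paths) < max_paths:
        path, width = _widest_path(residual, macro.source, macro.sink)
        if path is None or width <= 0:
            break
        if first is None:
            first = width
        elif width < threshold_fraction * first:
            break
        paths.append((path, float(width)))
        for a, b in zip(path, path[1:]):
            residual[a, b] = max(0.0, residual[a, b] - width)
    if not paths:
        warnings.warn("zero reactive flux: no binding pathways found", stacklevel=2)
    return paths


def mfpt(
    model: TransitionModel,
    macro: MacrostateDefinition,
) -> tuple[np.ndarray, float, float]:
    """Mean first passage times to the sink, π-weighted over the source.

    Solves ``m_i = τ + Σ_{j∉sink} P_ij m_j`` with ``m = 0`` on the sink.
    Returns (per-state MFPT vector in ns, source-averaged MFPT in ns,
    association rate 1/⟨MFPT⟩ in 1/ns).
    """
    p, pi = model.transition_matrix, model.stationary_distribution
    n = p.shape[0]
    sink = macro.sink
    not_sink = np.setdiff1d(np.arange(n), sink)
    # every non-sink state must be able to reach the sink along P>0 edges
    reach = _reaches(p, sink)
    if not reach[not_sink].all():
        bad = np.flatnonzero(~reach)
        raise ValueError(f"sink unreachable from states {bad.tolist()}")
    a = np.eye(not_sink.size) - p[np.ix_(not_sink, not_sink)]
    b = np.full(not_sink.size, model.lag_ns)
    m = np.zeros(n)
    m[not_sink] = np.linalg.solve(a, b)
    w = pi[macro.source]
    mfpt_avg = float(np.sum(w * m[macro.source]) / w.sum())
    return m, mfpt_avg, 1.0 / mfpt_avg


def _reaches(p: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Boolean vector: can each state reach the target set along P>0 edges."""
    n = p.shape[0]
    reach = np.zeros(n, dtype=bool)
    reach[targets] = True
    frontier = list(targets)
    incoming = [np.flatnonzero(p[:, j] > 0) for j in range(n)]
    while frontier:
        j = frontier.pop()
        for i in incoming[j]:
            if not reach[i]:
                reach[i] = True
                frontier.append(int(i))
    return reach


@dataclass
class TPTResult:
    """Committor, fluxes, pathways and association kinetics of one model."""

    macro: MacrostateDefinition
    committor: np.ndarray
    net_flux: np.ndarray
    total_flux: float
    pathways: list[tuple[list[int], float]]
    mfpt_ns: np.ndarray
    mfpt_source_avg_ns: float
    association_rate_per_ns: float

    def validate(self, rtol: float = 1e-10) -> None:
        q = self.committor
        if not (np.all(q[self.macro.source] == 0) and np.all(q[self.macro.sink] == 1)):
            raise AssertionError("committor boundary conditions violated")
        if ((q < 0) | (q > 1)).any():
            raise AssertionError("committor outside [0, 1]")
        f = self.net_flux
        if (f < 0).any():
            raise AssertionError("negative net flux")
        if (f * f.T > 0).any():
            raise AssertionError("net flux not antisymmetrically netted (f_ij*f_ji > 0)")
        inter = np.setdiff1d(
            np.arange(len(q)), np.concatenate([self.macro.source, self.macro.sink])
        )
        scale = max(self.total_flux, 1e-300)
        for i in inter:
            if abs(f[:, i].sum() - f[i, :].sum()) > rtol * scale * 100:
                raise AssertionError(f"flux not conserved at intermediate state {i}")

    def pathway_table(self) -> list[dict]:
        fmax = self.pathways[0][1] if self.pathways else 0.0
        return [
            {
                "rank": r + 1,
                "flux": flux,
                "fraction_of_max": flux / fmax if fmax else 0.0,
                "states": ",".join(str(s) for s in path),
            }
            for r, (path, flux) in enumerate(self.pathways)
        ]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "source": self.macro.source.tolist(),
            "sink": self.macro.sink.tolist(),
            "committor": [round(float(v), 12) for v in self.committor],
            "total_flux_per_lag": self.total_flux,
            "mfpt_source_avg_ns": self.mfpt_source_avg_ns,
            "association_rate_per_ns": self.association_rate_per_ns,
            "n_pathways": len(self.pathways),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    def pathways_to_csv(self, path: str | Path) -> None:
        lines = ["rank,flux,fraction_of_max,states"]
        for row in self.pathway_table():
            lines.append(
                f"{row['rank']},{row['flux']:.10g},{row['fraction_of_max']:.8g},\"{row['states']}\""
            )
        Path(path).write_text("\n".join(lines) + "\n")


def analyse(
    model: TransitionModel,
    macro: MacrostateDefinition,
    threshold_fraction: float = 0.5,
) -> TPTResult:
    """Full TPT analysis: committor → net flux → pathways → MFPT/rate."""
    q = committor(model, macro)
    flux, total = net_flux(model, q, macro)
    paths = top_pathways(flux, macro, threshold_fraction)
    m, mavg, rate = mfpt(model, macro)
    result = TPTResult(macro, q, flux, total, paths, m, mavg, rate)
    result.validate()
    return result
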