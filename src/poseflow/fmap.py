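"""3-D free-energy maps from MSM equilibrium populations.

Every frame is superposed into a common protein reference frame; each Markov
state gets a binary occupancy over the cells of a regular grid (1 if any
ligand heavy atom of any frame assigned to the state falls in the cell).
Cell probabilities are ``P(c_i) = Σ_j o_ij π_j``, converted to free energies
``F = −k_B T ln P`` and shifted so the occupied minimum is exactly zero.
The result is written as an OpenDX scalar field for isosurface viewers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse

from . import geometry
from .cluster import Assignments
from .msm import TransitionModel
from .topology import Topology
from .trajectory import TrajectoryEnsemble

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "GridSpec",
    "FreeEnergyGrid",
    "state_occupancy",
    "map_probabilities",
    "to_free_energy",
    "write_opendx",
    "read_opendx",
]

#: Boltzmann constant, kcal/mol/K (k_B T = 0.59616 kcal/mol at 300 K).
KB_KCAL_PER_MOL_K = 0.0019872


@dataclass
class GridSpec:
    """Regular grid definition; ``origin``/``shape`` of None means auto-fit
    to the data with one cell of padding."""

    spacing: float = 1.0
    origin: np.ndarray | None = None
    shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.origin is not None:
            self.origin = np.asarray(self.origin, dtype=float)
        if self.shape is not None and any(n < 1 for n in self.shape):
            raise ValueError("grid dimensions must be >= 1")


@dataclass
class FreeEnergyGrid:
    """Cell probabilities and (optionally) min-shifted free energies.

    ``free_energy`` is NaN on never-occupied cells; ``occupied`` is the mask
    of cells touched by at least one state.
    """

    origin: np.ndarray
    spacing: float
    probabilities: np.ndarray  # (nx, ny, nz)
    temperature: float = 300.0
    free_energy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.probabilities.shape

    @property
    def occupied(self) -> np.ndarray:
        return self.probabilities > 0

    def cell_center(self, index: tuple[int, int, int]) -> np.ndarray:
        return self.origin + (np.asarray(index) + 0.5) * self.spacing

    def minimum_cell(self) -> tuple[int, int, int]:
        """Index of the occupied cell of minimal free energy (maximal P)."""
        masked = np.where(self.occupied, self.probabilities, -np.inf)
        return tuple(int(v) for v in np.unravel_index(np.argmax(masked), self.shape))

    def validate(self) -> None:
        p = self.probabilities
        if ((p < 0) | (p > 1 + 1e-12)).any():
            raise AssertionError("cell probabilities outside [0, 1]")
        if self.free_energy is not None:
            f = self.free_energy
            occ = self.occupied
            if not occ.any():
                raise AssertionError("no occupied cells")
            if np.isnan(f[occ]).any():
                raise AssertionError("NaN free energy on an occupied cell")
            if f[occ].min() != 0.0:
                raise AssertionError("occupied free-energy minimum not shifted to 0")
            if (f[occ] < 0).any():
                raise AssertionError("negative free energy after shift")
            if not np.isnan(f[~occ]).all():
                raise AssertionError("unmasked value on a never-occupied cell")

    def to_csv(self, path: str | Path) -> None:
        lines = ["ix,iy,iz,probability,free_energy_kcal_mol"]
        occ = self.occupied
        for ix, iy, iz in zip(*np.nonzero(occ)):
            f = "" if self.free_energy is None else format(self.free_energy[ix, iy, iz], ".8g")
            lines.append(f"{ix},{iy},{iz},{self.probabilities[ix, iy, iz]:.10g},{f}")
        Path(path).write_text("\n".join(lines) + "\n")


def _cell_indices(positions: np.ndarray, origin: np.ndarray, spacing: float) -> np.ndarray:
    # half-open cells [lo, hi): a point exactly on a boundary belongs to the
    # upper cell; the epsilon keeps that true under superposition round-off
    return np.floor((positions - origin) / spacing + 1e-9).astype(int)


def state_occupancy(
    model: TransitionModel,
    assignments: Assignments,
    ensemble: TrajectoryEnsemble,
    grid_spec: GridSpec | None = None,
    reference_frame: np.ndarray | None = None,
    medoid_only_coords: np.ndarray | None = None,
) -> tuple[scipy.sparse.csr_matrix, GridSpec]:
    """Binary ligand heavy-atom occupancy of every retained state over the grid.

    Occupancy is computed over *all* frames assigned to a state (pass
    ``medoid_only_coords`` — a (K, n_atoms, 3) stack of cluster medoids —
    to use only each state's representative structure instead).
    Returns a sparse boolean matrix of shape (n_states, n_cells) with cells
    flattened in C order, plus the (possibly auto-fitted) grid spec.
    """
    top = ensemble.topology
    if reference_frame is None:
        reference_frame = ensemble.get_frame((0, 0))
    grid_spec = grid_spec or GridSpec()

    # gather ligand heavy-atom positions per retained state, in the common frame
    state_of_cluster = {int(orig): j for j, orig in enumerate(model.state_map)}
    positions: list[np.ndarray] = []
    owner: list[int] = []
    if medoid_only_coords is not None:
        for j, orig in enumerate(model.state_map):
            aligned = geometry.superpose_frame(medoid_only_coords[int(orig)], reference_frame, top)
            positions.append(aligned[top.ligand_heavy_indices])
            owner.extend([j] * top.n_ligand_heavy)
    else:
        frame_count = np.zeros(model.n_states, dtype=int)
        for fid, lab in zip(assignments.frame_ids, assignments.labels):
            j = state_of_cluster.get(int(lab))
            if j is None:
                continue  # frame belongs to an ergodically trimmed state
            frame_count[j] += 1
            aligned = geometry.superpose_frame(ensemble.get_frame(fid), reference_frame, top)
            positions.append(aligned[top.ligand_heavy_indices])
            owner.extend([j] * top.n_ligand_heavy)
        if (frame_count == 0).any():
            bad = np.flatnonzero(frame_count == 0)
            raise ValueError(f"states with zero assigned frames: {bad.tolist()} (inconsistent model)")
    pos = np.concatenate(positions)
    owner_arr = np.asarray(owner)

    if grid_spec.origin is None or grid_spec.shape is None:
        lo = np.floor(pos.min(axis=0) / grid_spec.spacing - 1) * grid_spec.spacing
        hi = np.ceil(pos.max(axis=0) / grid_spec.spacing + 1) * grid_spec.spacing
        shape = tuple(int(round((h - l) / grid_spec.spacing)) for l, h in zip(lo, hi))
        grid_spec = GridSpec(grid_spec.spacing, lo, shape)

    idx = _cell_indices(pos, grid_spec.origin, grid_spec.spacing)
    shape = grid_spec.shape
    inside = ((idx >= 0) & (idx < np.asarray(shape))).all(axis=1)
    if not inside.all():
        raise ValueError("ligand positions fall outside the explicit grid box; enlarge the box or use auto")
    flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), shape)
    n_cells = int(np.prod(shape))
    occ = scipy.sparse.csr_matrix(
        (np.ones(len(flat), dtype=np.int64), (owner_arr, flat)),
        shape=(model.n_states, n_cells),
    )
    occ.sum_duplicates()
    occ.data = np.minimum(occ.data, 1).astype(np.int8)  # binary occupancy
    return occ, grid_spec


def map_probabilities(
    occupancy: scipy.sparse.spmatrix,
    model: TransitionModel,
    grid_spec: GridSpec,
    temperature: float = 300.0,
) -> FreeEnergyGrid:
    """P(c_i) = Σ_j o_ij · π_j over the grid cells."""
    pi = model.stationary_distribution
    if occupancy.shape[0] != len(pi):
        raise ValueError("occupancy rows must match model states")
    p_cells = np.asarray(occupancy.T @ pi).ravel()
    probabilities = p_cells.reshape(grid_spec.shape)
    return FreeEnergyGrid(grid_spec.origin, grid_spec.spacing, probabilities, temperature)


def to_free_energy(grid: FreeEnergyGrid, temperature: float | None = None) -> FreeEnergyGrid:
    """Convert cell probabilities to min-shifted free energies (kcal/mol).

    ``F(c_i) = −k_B T ln P(c_i)`` on occupied cells, then shifted so the
    minimum over occupied cells is exactly 0; never-occupied cells are NaN.
    """
    t = grid.temperature if temperature is None else temperature
    occ = grid.occupied
    if not occ.any():
        raise ValueError("all cells unoccupied; cannot build a free-energy map")
    f = np.full(grid.shape, np.nan)
    with np.errstate(divide="ignore"):
        f[occ] = -KB_KCAL_PER_MOL_K * t * np.log(grid.probabilities[occ])
    f[occ] -= f[occ].min()
    f[occ] = np.maximum(f[occ], 0.0)  # clamp -0.0 / rounding at the minimum
    return FreeEnergyGrid(grid.origin, grid.spacing, grid.probabilities, t, f)


def write_opendx(grid: FreeEnergyGrid, path: str | Path, mask_sentinel: float | None = None) -> None:
    """Write the free-energy field as an OpenDX scalar file.

    Grid positions are cell centers; masked (never-occupied) cells are
    written as ``mask_sentinel`` (default: max finite value + 10 kcal/mol).
    """
    from gridData import Grid as DXGrid

    if grid.free_energy is None:
        raise ValueError("grid has no free energies; call to_free_energy first")
    values = grid.free_energy.copy()
    finite = np.isfinite(values)
    if mask_sentinel is None:
        mask_sentinel = (values[finite].max() if finite.any() else 0.0) + 10.0
    values[~finite] = mask_sentinel
    dx = DXGrid(values, origin=grid.origin + grid.spacing / 2.0, delta=[grid.spacing] * 3)
    dx.export(str(path), file_format="dx", type="double")


def read_opendx(path: str | Path, temperature: float = 300.0) -> FreeEnergyGrid:
    """Read an OpenDX scalar field back as a free-energy grid (probabilities
    are not recoverable and are set to zero)."""
    from gridData import Grid as DXGrid

    dx = DXGrid(str(path))
    spacing = float(np.atleast_1d(dx.delta.diagonal() if dx.delta.ndim == 2 else dx.delta)[0])
    origin = np.asarray(dx.origin, dtype=float) - spacing / 2.0
    grid = FreeEnergyGrid(origin, spacing, np.zeros(dx.grid.shape), temperature, np.asarray(dx.grid, dtype=float))
    return grid
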