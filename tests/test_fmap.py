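"""Free-energy grid: occupancy conventions, probability mapping, OpenDX."""

import numpy as np
import pytest
import scipy.sparse

import poseflow as pf
from poseflow import fmap
from poseflow.msm import TransitionModel
from conftest import make_1d_ensemble


def tiny_model(pi, lag=1.0):
    pi = np.asarray(pi, dtype=float)
    k = len(pi)
    return TransitionModel(np.tile(pi, (k, 1)), pi, np.array([1.0] + [0.0] * (k - 1)),
                           lag, np.arange(k), "naive")


def occupancy_matrix(rows, n_cells):
    m = np.zeros((len(rows), n_cells), dtype=np.int8)
    for i, cells in enumerate(rows):
        m[i, list(cells)] = 1
    return scipy.sparse.csr_matrix(m)


class TestOccupancy:
    def _system(self, ligand_positions, labels):
        """1-atom-ligand frames at given 3-D positions, one state label each."""
        top = pf.Topology(
            [
                pf.AtomRecord(0, "CA", "protein", backbone=True),
                pf.AtomRecord(1, "CA", "protein", backbone=True),
                pf.AtomRecord(2, "CA", "protein", backbone=True),
                pf.AtomRecord(3, "C1", "ligand", heavy=True),
            ]
        )
        base = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0], [0.0, 0, 0]])
        frames = []
        for pos in ligand_positions:
            f = base.copy()
            f[3] = pos
            frames.append(f)
        ens = pf.TrajectoryEnsemble(top, [pf.Trajectory(np.stack(frames), 1.0)])
        labels = np.asarray(labels)
        assignments = pf.Assignments([(0, i) for i in range(len(labels))], labels, 1, 1.0)
        model = tiny_model(np.full(labels.max() + 1, 1.0 / (labels.max() + 1)))
        return ens, assignments, model

    def test_single_atom_in_unit_cell(self):
        ens, asg, model = self._system([[0.5, 0.5, 0.5]], [0])
        spec = fmap.GridSpec(1.0, np.zeros(3), (2, 2, 2))
        occ, _ = fmap.state_occupancy(model, asg, ens, spec)
        dense = occ.toarray().reshape(1, 2, 2, 2)
        assert dense[0, 0, 0, 0] == 1
        assert dense.sum() == 1

    def test_boundary_atom_belongs_to_upper_cell(self):
        ens, asg, model = self._system([[1.0, 0.5, 0.5]], [0])
        spec = fmap.GridSpec(1.0, np.zeros(3), (2, 2, 2))
        occ, _ = fmap.state_occupancy(model, asg, ens, spec)
        dense = occ.toarray().reshape(1, 2, 2, 2)
        assert dense[0, 1, 0, 0] == 1
        assert dense[0, 0, 0, 0] == 0

    def test_matches_exhaustive_per_atom_scan(self):
        positions = [[0.2, 0.3, 0.1], [1.7, 0.3, 0.1], [0.2, 1.9, 0.4], [1.1, 1.1, 1.1]]
        labels = [0, 0, 1, 1]
        ens, asg, model = self._system(positions, labels)
        spec = fmap.GridSpec(1.0, np.zeros(3), (2, 2, 2))
        occ, _ = fmap.state_occupancy(model, asg, ens, spec)
        expected = np.zeros((2, 8), dtype=np.int8)
        for pos, lab in zip(positions, labels):
            cell = tuple(int(np.floor(c)) for c in pos)
            expected[lab, np.ravel_multi_index(cell, (2, 2, 2))] = 1
        assert np.array_equal(occ.toarray(), expected)

    def test_invariant_to_frame_order(self):
        positions = [[0.2, 0.3, 0.1], [1.7, 0.3, 0.1], [0.2, 1.9, 0.4], [1.1, 1.1, 1.1]]
        labels = [0, 1, 0, 1]
        spec = fmap.GridSpec(1.0, np.zeros(3), (2, 2, 2))
        ens, asg, model = self._system(positions, labels)
        occ1, _ = fmap.state_occupancy(model, asg, ens, spec)
        order = [2, 0, 3, 1]
        ens2, asg2, _ = self._system([positions[i] for i in order], [labels[i] for i in order])
        occ2, _ = fmap.state_occupancy(model, asg2, ens2, spec)
        assert np.array_equal(occ1.toarray(), occ2.toarray())

    def test_state_without_frames_rejected(self):
        ens, asg, _ = self._system([[0.5, 0.5, 0.5]], [0])
        model = tiny_model([0.5, 0.5])  # claims 2 states; only state 0 has frames
        with pytest.raises(ValueError, match="zero assigned frames"):
            fmap.state_occupancy(model, asg, ens, fmap.GridSpec(1.0, np.zeros(3), (2, 2, 2)))

    def test_auto_grid_covers_all_positions(self):
        ens, asg, model = self._system([[-3.2, 0.4, 9.7], [5.1, 2.0, -1.3]], [0, 1])
        occ, spec = fmap.state_occupancy(model, asg, ens)
        assert occ.sum() == 2
        assert (np.asarray(spec.shape) >= 1).all()


class TestProbabilityMapping:
    def test_worked_micro_example(self):
        # pi = (0.75, 0.25); state 0 occupies cell A, state 1 cells A and B
        model = tiny_model([0.75, 0.25])
        spec = fmap.GridSpec(1.0, np.zeros(3), (2, 1, 1))
        occ = occupancy_matrix([{0}, {0, 1}], 2)
        grid = fmap.map_probabilities(occ, model, spec, 300.0)
        assert grid.probabilities.ravel()[0] == pytest.approx(1.0, abs=1e-12)
        assert grid.probabilities.ravel()[1] == pytest.approx(0.25, abs=1e-12)
        out = fmap.to_free_energy(grid)
        f = out.free_energy.ravel()
        assert f[0] == 0.0
        assert f[1] == pytest.approx(0.8265, abs=1e-4)  # kT ln 4 at 300 K
        out.validate()

    def test_single_state_occupies_everything_it_touches(self):
        model = tiny_model([1.0])
        spec = fmap.GridSpec(1.0, np.zeros(3), (3, 1, 1))
        occ = occupancy_matrix([{0, 2}], 3)
        grid = fmap.map_probabilities(occ, model, spec)
        assert list(grid.probabilities.ravel()) == [1.0, 0.0, 1.0]

    def test_uniform_probability_flat_free_energy(self):
        model = tiny_model([0.5, 0.5])
        spec = fmap.GridSpec(1.0, np.zeros(3), (2, 1, 1))
        occ = occupancy_matrix([{0}, {1}], 2)
        out = fmap.to_free_energy(fmap.map_probabilities(occ, model, spec))
        assert np.allclose(out.free_energy.ravel(), [0.0, 0.0])

    def test_monotone_probability_to_energy(self):
        model = tiny_model([0.5, 0.3, 0.2])
        spec = fmap.GridSpec(1.0, np.zeros(3), (3, 1, 1))
        occ = occupancy_matrix([{0}, {0, 1}, {0, 1, 2}], 3)
        out = fmap.to_free_energy(fmap.map_probabilities(occ, model, spec))
        p = out.probabilities.ravel()
        f = out.free_energy.ravel()
        assert p[0] > p[1] > p[2] > 0
        assert f[0] < f[1] < f[2]

    def test_scaling_probabilities_preserves_differences(self):
        spec = fmap.GridSpec(1.0, np.zeros(3), (2, 1, 1))
        occ = occupancy_matrix([{0}, {1}], 2)
        g1 = fmap.to_free_energy(fmap.map_probabilities(occ, tiny_model([0.6, 0.2]), spec))
        # same ratio, different overall scale
        g2 = fmap.to_free_energy(fmap.map_probabilities(occ, tiny_model([0.3, 0.1]), spec))
        d1 = np.diff(g1.free_energy.ravel())
        d2 = np.diff(g2.free_energy.ravel())
        assert np.allclose(d1, d2, atol=1e-12)

    def test_all_unoccupied_rejected(self):
        grid = fmap.FreeEnergyGrid(np.zeros(3), 1.0, np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="unoccupied"):
            fmap.to_free_energy(grid)


class TestOpenDX:
    def _grid(self, shape=(2, 2, 2), seed=0):
        rng = np.random.default_rng(seed)
        p = rng.random(shape)
        p[0, 0, 0] = 0.0  # one masked cell
        grid = fmap.FreeEnergyGrid(np.array([-1.0, 0.0, 2.0]), 1.0, p, 300.0)
        return fmap.to_free_energy(grid)

    def test_round_trip_values_identical(self, tmp_path):
        grid = self._grid()
        path = tmp_path / "g.dx"
        fmap.write_opendx(grid, path)
        back = fmap.read_opendx(path)
        occ = grid.occupied
        assert np.abs(back.free_energy[occ] - grid.free_energy[occ]).max() <= 1e-6
        sentinel = np.nanmax(grid.free_energy) + 10.0
        assert back.free_energy[~occ] == pytest.approx(sentinel, abs=1e-6)
        assert np.allclose(back.origin, grid.origin, atol=1e-6)

    def test_header_records_origin_and_unit_spacing(self, tmp_path):
        grid = self._grid()
        path = tmp_path / "g.dx"
        fmap.write_opendx(grid, path)
        text = path.read_text()
        assert "delta  1 0 0" in text
        # grid positions are cell centers: origin + spacing/2
        assert "origin -0.500000 0.500000 2.500000" in text

    def test_single_point_grid(self, tmp_path):
        grid = fmap.FreeEnergyGrid(np.zeros(3), 1.0, np.full((1, 1, 1), 1.0), 300.0)
        out = fmap.to_free_energy(grid)
        path = tmp_path / "one.dx"
        fmap.write_opendx(out, path)
        back = fmap.read_opendx(path)
        assert back.free_energy.shape == (1, 1, 1)
        assert back.free_energy[0, 0, 0] == pytest.approx(0.0, abs=1e-12)


def test_grid_minimum_in_designed_well(toy_data, toy_pipeline, toy_spec):
    """The free-energy global minimum cell must fall inside the bound well."""
    ensemble, truth = toy_data
    res = toy_pipeline
    occ, spec = fmap.state_occupancy(res.msm, res.assignments, ensemble)
    grid = fmap.to_free_energy(fmap.map_probabilities(occ, res.msm, spec))
    grid.validate()
    center = grid.cell_center(grid.minimum_cell())
    bound_center = np.asarray(truth["wells"][0]["center"])
    assert np.linalg.norm(center - bound_center) <= truth["basin_radius_A"] + grid.spacing
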