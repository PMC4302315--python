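import numpy as np
import pytest

import poseflow as pf

#: pipeline parameters used for the toy binding system throughout the tests:
#: 3 A cluster cutoff (protocol standard), 1 ns clustering stride, 0.5 ns
#: assignment stride, 2 ns lag (validated by the implied-timescale scan for
#: this fast toy landscape).
TOY_PIPELINE = dict(cutoff=3.0, cluster_stride=10, kmedoid_iters=2, assign_stride=5, lag_ns=2.0)


@pytest.fixture(scope="session")
def toy_spec():
    """Reduced toy binding system for unit tests (fast, still metastable)."""
    return pf.ToyBindingSpec(n_steps=1500, n_trajectories=8, seed=7)


@pytest.fixture(scope="session")
def toy_data(toy_spec):
    ensemble, truth = pf.simulate_toy_binding(toy_spec)
    return ensemble, truth


@pytest.fixture(scope="session")
def toy_pipeline(toy_data):
    ensemble, _ = toy_data
    return pf.run_pose_pipeline(ensemble, **TOY_PIPELINE)


def make_1d_system(xs, ligand_y=5.0):
    """Topology + frames for a 1-atom ligand moving along x over a fixed
    3-atom (non-collinear) protein backbone; one frame per x value."""
    top = pf.Topology(
        [
            pf.AtomRecord(0, "CA", "protein", backbone=True),
            pf.AtomRecord(1, "CA", "protein", backbone=True),
            pf.AtomRecord(2, "CA", "protein", backbone=True),
            pf.AtomRecord(3, "C1", "ligand", heavy=True),
        ]
    )
    base = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, ligand_y, 0.0]])
    frames = []
    for x in xs:
        f = base.copy()
        f[3, 0] = x
        frames.append(f)
    return top, np.stack(frames)


def make_1d_ensemble(xs, spacing_ns=1.0):
    top, frames = make_1d_system(xs)
    return pf.TrajectoryEnsemble(top, [pf.Trajectory(frames, spacing_ns)])
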