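"""Transition path theory: committors, fluxes, pathway decomposition, MFPT."""

import numpy as np
import pytest
import scipy.linalg

import poseflow as pf
from poseflow import tpt
from poseflow.msm import TransitionModel


def model_from_p(p, lag=1.0, pi=None):
    p = np.asarray(p, dtype=float)
    if pi is None:
        vals, vecs = scipy.linalg.eig(p.T)
        pi = np.real(vecs[:, np.argmin(np.abs(vals - 1))])
        pi = np.abs(pi) / np.abs(pi).sum()
    eigs = np.sort(np.real(scipy.linalg.eigvals(p)))[::-1]
    return TransitionModel(p, np.asarray(pi), eigs, lag, np.arange(len(p)), "naive")


def macro(source, sink, **kw):
    return tpt.MacrostateDefinition(np.asarray(source), np.asarray(sink), **kw)


SYMMETRIC_3 = np.array([[0.8, 0.2, 0.0], [0.2, 0.6, 0.2], [0.0, 0.2, 0.8]])


class TestCommittor:
    def test_symmetric_three_state_chain(self):
        q = tpt.committor(model_from_p(SYMMETRIC_3), macro([0], [2]))
        assert np.allclose(q, [0.0, 0.5, 1.0], atol=1e-12)

    def test_boundary_values_exact(self):
        q = tpt.committor(model_from_p(SYMMETRIC_3), macro([0], [2]))
        assert q[0] == 0.0 and q[2] == 1.0

    def test_birth_death_matches_dense_oracle(self):
        p = np.array(
            [
                [0.7, 0.3, 0.0, 0.0],
                [0.2, 0.5, 0.3, 0.0],
                [0.0, 0.4, 0.4, 0.2],
                [0.0, 0.0, 0.1, 0.9],
            ]
        )
        q = tpt.committor(model_from_p(p), macro([0], [3]))
        # independent oracle: full K x K boundary-value system solved directly
        a = np.eye(4) - p
        a[0] = 0.0; a[0, 0] = 1.0
        a[3] = 0.0; a[3, 3] = 1.0
        b = np.array([0.0, 0.0, 0.0, 1.0])
        q_oracle = scipy.linalg.solve(a, b)
        assert np.abs(q - q_oracle).max() < 1e-10

    def test_monotone_along_birth_death_chain(self):
        p = np.array(
            [
                [0.8, 0.2, 0.0, 0.0, 0.0],
                [0.3, 0.4, 0.3, 0.0, 0.0],
                [0.0, 0.1, 0.8, 0.1, 0.0],
                [0.0, 0.0, 0.4, 0.3, 0.3],
                [0.0, 0.0, 0.0, 0.2, 0.8],
            ]
        )
        q = tpt.committor(model_from_p(p), macro([0], [4]))
        assert (np.diff(q) >= -1e-12).all()


class TestNetFlux:
    def test_forward_only_on_symmetric_chain(self):
        model = model_from_p(SYMMETRIC_3)
        assert np.allclose(model.stationary_distribution, 1 / 3, atol=1e-10)
        q = tpt.committor(model, macro([0], [2]))
        f, total = tpt.net_flux(model, q, macro([0], [2]))
        # hand evaluation: f_01 = (1/3)(1)(0.2)(0.5), f_12 = (1/3)(0.5)(0.2)(1)
        assert f[0, 1] == pytest.approx(1 / 30, abs=1e-12)
        assert f[1, 2] == pytest.approx(1 / 30, abs=1e-12)
        assert f[1, 0] == 0.0 and f[2, 1] == 0.0
        assert total == pytest.approx(1 / 30, abs=1e-12)

    def test_sink_rows_zero(self):
        model = model_from_p(SYMMETRIC_3)
        q = tpt.committor(model, macro([0], [2]))
        f, _ = tpt.net_flux(model, q, macro([0], [2]))
        assert np.all(f[2, :] == 0.0)

    def test_conservation_at_intermediates(self):
        model = model_from_p(SYMMETRIC_3)
        q = tpt.committor(model, macro([0], [2]))
        f, _ = tpt.net_flux(model, q, macro([0], [2]))
        assert f[:, 1].sum() == pytest.approx(f[1, :].sum(), abs=1e-12)


class TestPathways:
    def test_single_chain_single_pathway(self):
        f = np.zeros((3, 3))
        f[0, 1] = f[1, 2] = 5.0
        paths = tpt.top_pathways(f, macro([0], [2]))
        assert paths == [([0, 1, 2], 5.0)]

    def test_parallel_routes_both_above_half_max(self):
        f = np.zeros((4, 4))
        f[0, 1] = f[1, 3] = 10.0
        f[0, 2] = f[2, 3] = 6.0
        paths = tpt.top_pathways(f, macro([0], [3]), threshold_fraction=0.5)
        assert [p for p, _ in paths] == [[0, 1, 3], [0, 2, 3]]
        assert [w for _, w in paths] == [10.0, 6.0]

    def test_higher_threshold_drops_minor_route(self):
        f = np.zeros((4, 4))
        f[0, 1] = f[1, 3] = 10.0
        f[0, 2] = f[2, 3] = 6.0
        paths = tpt.top_pathways(f, macro([0], [3]), threshold_fraction=0.7)
        assert [p for p, _ in paths] == [[0, 1, 3]]

    def test_zero_flux_warns_and_returns_empty(self):
        f = np.zeros((3, 3))
        with pytest.warns(UserWarning, match="zero reactive flux"):
            assert tpt.top_pathways(f, macro([0], [2])) == []

    def test_full_decomposition_sums_to_total_flux(self):
        # reversible chain (symmetric generator): its net flux field is
        # acyclic, so bottleneck extraction decomposes the total flux exactly
        rng = np.random.default_rng(7)
        x = rng.random((5, 5)) + 0.05
        x = x + x.T
        p = x / x.sum(axis=1, keepdims=True)
        pi = x.sum(axis=1) / x.sum()
        model = model_from_p(p, pi=pi)
        m = macro([0], [4])
        q = tpt.committor(model, m)
        f, total = tpt.net_flux(model, q, m)
        paths = tpt.top_pathways(f, m, threshold_fraction=0.0)
        assert sum(w for _, w in paths) == pytest.approx(total, rel=1e-8)


class TestMFPT:
    def test_two_state_geometric(self):
        p = np.array([[0.9, 0.1], [0.5, 0.5]])
        m, avg, rate = tpt.mfpt(model_from_p(p, lag=1.0), macro([0], [1]))
        assert m[0] == pytest.approx(10.0, abs=1e-10)
        assert avg == pytest.approx(10.0, abs=1e-10)
        assert rate == pytest.approx(0.1, abs=1e-12)

    def test_source_adjacent_to_sink(self):
        p = np.array([[0.0, 1.0], [0.5, 0.5]])
        m, avg, _ = tpt.mfpt(model_from_p(p, lag=2.0), macro([0], [1]))
        assert avg == pytest.approx(2.0, abs=1e-12)

    def test_birth_death_analytic_formula(self):
        # h_i = expected steps i -> i+1: h_i = 1/p_i + (q_i/p_i) h_{i-1}
        p = np.array([[0.6, 0.4, 0.0], [0.3, 0.4, 0.3], [0.0, 0.5, 0.5]])
        h0 = 1.0 / p[0, 1]
        h1 = 1.0 / p[1, 2] + (p[1, 0] / p[1, 2]) * h0
        expected = h0 + h1
        m, _, _ = tpt.mfpt(model_from_p(p, lag=1.0), macro([0], [2]))
        assert m[0] == pytest.approx(expected, abs=1e-10)

    def test_matches_series_summation_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.random((6, 6)) + 0.05
        p = x / x.sum(axis=1, keepdims=True)
        model = model_from_p(p, lag=1.0)
        sink = np.array([5])
        m, _, _ = tpt.mfpt(model, macro([0], sink))
        # oracle: m = tau * sum_n (P_QQ)^n 1 by explicit series summation
        q_idx = np.arange(5)
        pqq = p[np.ix_(q_idx, q_idx)]
        acc = np.zeros(5)
        term = np.ones(5)
        for _ in range(100_000):
            acc += term
            term = pqq @ term
            if term.max() < 1e-16:
                break
        assert np.abs(m[q_idx] - acc).max() / acc.max() < 1e-8

    def test_unreachable_sink_rejected(self):
        p = np.array([[1.0, 0.0], [0.5, 0.5]])  # state 0 absorbing, cannot reach 1
        with pytest.raises(ValueError, match="unreachable"):
            tpt.mfpt(model_from_p(p, pi=[0.5, 0.5]), macro([0], [1]))


class TestMacrostates:
    def _setup(self):
        top = pf.Topology(
            [
                pf.AtomRecord(0, "CA", "protein", backbone=True),
                pf.AtomRecord(1, "CA", "protein", backbone=True),
                pf.AtomRecord(2, "CA", "protein", backbone=True),
                pf.AtomRecord(3, "C1", "ligand", heavy=True),
            ]
        )
        base = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0], [0.0, 0, 0]])

        def frame(lig):
            f = base.copy()
            f[3] = lig
            return f

        # state 0: 30 A away (unbound); state 1: 1.2 A from reference (bound);
        # state 2: 8 A away (intermediate)
        centers = np.stack([frame([30.0, 0, 0]), frame([1.2, 3.0, 0]), frame([8.0, 0, 0])])
        frames = np.concatenate([centers, centers])
        ens = pf.TrajectoryEnsemble(top, [pf.Trajectory(frames, 1.0)])
        assignments = pf.Assignments([(0, i) for i in range(6)], np.array([0, 1, 2, 0, 1, 2]), 1, 1.0)
        cmodel = pf.ClusterModel(top, [(0, 0), (0, 1), (0, 2)], centers, 3.0, 1, assignments)
        model = model_from_p(np.full((3, 3), 1 / 3))
        reference = pf.LigandPose(np.array([[0.0, 3.0, 0.0]]))
        return ens, cmodel, model, reference

    def test_geometric_classification(self):
        ens, cmodel, model, reference = self._setup()
        m = tpt.define_macrostates(model, cmodel, reference, ens.get_frame((0, 0)))
        assert list(m.source) == [0]   # > 20 A from every protein atom
        assert list(m.sink) == [1]     # RMSD 1.2 A < 3 A to the reference pose
        assert m.unbound_cutoff == 20.0 and m.bound_cutoff == 3.0

    def test_empty_sink_instructs_cutoff_change(self):
        ens, cmodel, model, reference = self._setup()
        with pytest.raises(ValueError, match="bound"):
            tpt.define_macrostates(model, cmodel, reference, ens.get_frame((0, 0)), bound_cutoff=0.5)

    def test_disjoint_nonempty_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            macro([0, 1], [1, 2])
        with pytest.raises(ValueError, match="non-empty"):
            macro([], [1])


def test_full_analysis_invariants_on_toy_msm(toy_data, toy_pipeline, toy_spec):
    ensemble, truth = toy_data
    res = toy_pipeline
    reference = pf.LigandPose(np.asarray(truth["bound_pose"]))
    m = tpt.define_macrostates(res.msm, res.cluster_model, reference, res.reference_frame)
    result = tpt.analyse(res.msm, m)  # validate() runs inside
    assert result.total_flux > 0
    assert result.pathways[0][0][0] in set(m.source)
    assert result.pathways[0][0][-1] in set(m.sink)
    assert result.association_rate_per_ns == pytest.approx(1.0 / result.mfpt_source_avg_ns)
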