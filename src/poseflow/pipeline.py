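"""End-to-end orchestration: cluster → MSM → rank, reused by the
convergence monitor, the CLI and the acceptance checks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cluster as _cluster
from . import msm as _msm
from .trajectory import LigandPose, TrajectoryEnsemble

__all__ = ["PipelineResult", "run_pose_pipeline"]


@dataclass
class PipelineResult:
    """Everything downstream stages need from one cluster→MSM→rank pass."""

    cluster_model: _cluster.ClusterModel
    assignments: _cluster.Assignments
    msm: _msm.TransitionModel
    ranking: list[tuple[int, float, object]]
    reference_frame: np.ndarray

    @property
    def top_state(self) -> int:
        """Original cluster index of the top-populated (predicted) state."""
        return self.ranking[0][0]

    @property
    def top_pose(self) -> LigandPose:
        return self.ranking[0][2]


def run_pose_pipeline(
    ensemble: TrajectoryEnsemble,
    cutoff: float = 3.0,
    cluster_stride: int = 100,
    kmedoid_iters: int = 3,
    rng_seed: int = 0,
    assign_stride: int | None = None,
    lag_ns: float = 10.0,
    mode: str = "reversible-mle",
    sliding: bool = True,
) -> PipelineResult:
    """Cluster the ensemble, estimate the MSM and rank states by population.

    ``assign_stride`` defaults to the clustering stride; use a smaller
    stride to count transitions on finer-grained assignments.  The
    representative pose of each state is its cluster medoid's ligand,
    expressed in the protein frame of the ensemble's first frame.
    """
    model = _cluster.kcenters(ensemble, cutoff=cutoff, stride=cluster_stride)
    if kmedoid_iters > 0:
        model = _cluster.kmedoids_refine(model, ensemble, n_iter=kmedoid_iters, rng_seed=rng_seed)
    if assign_stride is None or assign_stride == model.stride:
        assignments = model.assignments
    else:
        assignments = _cluster.assign(ensemble, model, stride=assign_stride)
    msm_result = _msm.MarkovStateModel.from_assignments(
        assignments, lag_ns, mode=mode, sliding=sliding, n_states=model.n_clusters
    ).fit()
    reference_frame = ensemble.get_frame((0, 0))
    representatives = {
        int(orig): LigandPose(model.representative_pose(int(orig), reference_frame))
        for orig in msm_result.state_map
    }
    ranking = _msm.rank_states(msm_result, representatives)
    return PipelineResult(model, assignments, msm_result, ranking, reference_frame)
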