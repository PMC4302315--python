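# poseflow

Markov state model (MSM) protocol for predicting ligand binding poses and
binding pathways from ensembles of protein–ligand binding simulations.

Long unbiased simulations of a ligand finding its binding site are
expensive, and a single trajectory rarely samples more than a handful of
binding events. The alternative implemented here pools many short,
independent trajectories into one statistical model: frames are clustered
by the ligand's position relative to the protein, transitions between
clusters are counted at a lag time τ, and the resulting Markov state model
yields equilibrium populations π, a 3-D free-energy map of ligand density,
and binding kinetics — even though no single trajectory contains the whole
story. The package is aimed at computational chemists and method developers
who want the full analysis protocol (and a synthetic ground-truth system to
validate it on) without a cluster-scale MD campaign.

## The model

1. **Metric.** Every frame is rigidly superposed onto a reference by least
   squares over the protein *backbone* atoms (Kabsch, proper rotations
   only); distances between frames are the RMSD over ligand *heavy* atoms
   with no re-fitting — "where is the ligand relative to the protein".
2. **States.** k-centers (farthest-point) clustering at a 3 Å cutoff
   guarantees every frame lies within 3 Å of a center; a hybrid k-medoids
   pass refines centers by stochastic swap proposals with greedy acceptance.
3. **MSM.** Transition counts C_ij at lag τ (sliding window, never across
   trajectory boundaries) are trimmed to the largest strongly connected
   component, then the transition matrix P_ij is estimated either by row
   normalisation or by the reversible maximum-likelihood estimator
   (detailed balance π_i P_ij = π_j P_ji enforced via the standard
   self-consistent iteration). Lag validity is checked with implied
   timescales t_i = −τ / ln μ_i, which must be lag-independent for a
   Markovian model.
4. **Pose prediction.** States ranked by π; the top state's medoid is the
   predicted pose. Equilibrium populations are mapped onto a 1 Å grid by
   binary ligand-heavy-atom occupancy, P(c) = Σ_j o_cj π_j, converted to
   free energies F = −k_B T ln P, min-shifted, and written as OpenDX.
5. **Kinetics.** Transition path theory between unbound states (ligand
   > 20 Å from the protein) and bound states (ligand RMSD < 3 Å to the
   reference pose): committor q+, net reactive flux
   f_ij = π_i (1 − q+_i) P_ij q+_j, pathway decomposition by repeated
   widest-path extraction (reported down to 50% of the maximum-flux path),
   and association rate 1/⟨MFPT⟩ from the first-passage linear system.
6. **Adaptive loop.** The RMSD of the top-populated pose to a reference is
   monitored at fixed aggregate-time checkpoints (rolling mean/std over 2
   points); if not converged, new restart structures are drawn from MSM
   states (uniform or inverse-count weighting), or generated around a
   complex by grid translation with steric-clash rejection.

A synthetic ground-truth module makes all of this testable without MD: an
exact discrete-chain sampler, and a 3-D toy binding system (rigid 3-atom
ligand, static mini-protein, Gaussian energy wells — one deep bound well,
two shallow nonspecific sites, a large flat unbound region) sampled by a
Metropolis walk whose stationary distribution is known exactly.

## Worked example

```python
import numpy as np
import poseflow as pf
from poseflow import tpt

spec = pf.ToyBindingSpec()            # default study conditions, fixed seed
ensemble, truth = pf.simulate_toy_binding(spec)
result = pf.run_pose_pipeline(ensemble, cutoff=3.0, cluster_stride=10,
                              kmedoid_iters=2, assign_stride=5, lag_ns=2.0)
print(result.msm.summary())

state, pop, pose = result.ranking[0]
well = np.array(truth["wells"][0]["center"])
print(f"top state {state}: population {pop:.4f}, centroid distance "
      f"to designed well {np.linalg.norm(pose.coords.mean(0) - well):.2f} A")

macro = tpt.define_macrostates(result.msm, result.cluster_model,
                               spec.bound_pose(), result.reference_frame)
r = tpt.analyse(result.msm, macro)
print(f"MFPT(unbound->bound) = {r.mfpt_source_avg_ns:.0f} ns, "
      f"association rate = {r.association_rate_per_ns*1e3:.2f} / us")
```

prints

```
Markov state model
==================
states (retained)    : 1117
lag time             : 2 ns
estimator            : reversible-mle
top populations      : state 0: 0.1421, state 1022: 0.0344, state 1028: 0.0062, state 809: 0.0053, state 1095: 0.0032
implied timescales   : 55.7 ns, 22.2 ns, 18.9 ns, 17.6 ns, 12 ns
top state 0: population 0.1421, centroid distance to designed well 0.87 A
MFPT(unbound->bound) = 299 ns, association rate = 3.34 / us
```

The top-populated state carries 14% of the equilibrium probability — four
times the runner-up — and its medoid sits 0.9 Å from the center of the
designed bound well, i.e. the protocol recovers the planted pose. The
association rate is the reciprocal of the π-weighted mean first passage
time from the unbound states.

## Command line

The same protocol is exposed as stages of a CLI
(`poseflow --config config.yaml --outdir out <stage>`), with stages
`simulate`, `cluster`, `msm`, `timescales`, `rank`, `fmap`, `tpt`,
`converge`, `seed`. Each stage consumes the previous stage's plain-text
artifacts from the output directory and records input/output hashes in
`manifest.json`. Exit codes: 0 ok, 1 usage/config error, 2 data error.

Trajectories are read from multi-model PDB or XYZ files; the atom
selection file is plain text, one atom per line:

```
# index name role flag
0 CA protein backbone
1 CA protein backbone
2 CA protein backbone
3 C1 ligand heavy
```

`role` is `protein` or `ligand`; `flag` is `backbone` (protein atoms used
for superposition), `heavy` (ligand atoms entering the RMSD metric and the
occupancy grid) or `-`.

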