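# Methods

This note documents the models and numerical procedures implemented in
poseflow, the choices made where the design was genuinely open, and what
the synthetic validation system does and does not establish.

## Structural metric

All state definitions rest on one metric: the RMSD over ligand heavy atoms
after rigid superposition of the protein backbone. The superposition is a
closed-form least-squares fit (Kabsch via SVD) with the determinant
correction that excludes reflections; it requires at least 3 backbone atoms
and rejects collinear backbones, whose rotation about the line is
undetermined. The metric is directional — frame a is aligned onto frame b —
but exactly symmetric for rigid backbone motions and near-symmetric
(≤ 1e-6 Å in the tests) otherwise. Ligand atom correspondence is
positional (topology order); no symmetry-corrected RMSD is attempted.
Batched evaluation stacks the 3×3 SVDs so clustering and assignment use the
exact pairwise metric, not an aligned-to-common-reference approximation.

## State decomposition

k-centers clustering starts from the globally first frame (deterministic)
and repeatedly promotes the frame farthest from the existing centers until
the covering radius drops to the cutoff (default 3 Å). This guarantees
every clustered frame lies within the cutoff of its center and is a
2-approximation of the optimal covering. The hybrid k-medoids refinement
then proposes, per cluster and sweep, one uniformly random member as the
new medoid, accepting whenever the within-cluster sum of distances does not
increase, and reassigns all frames afterwards; the objective is therefore
non-increasing. Refinement keeps K fixed except that clusters emptied by
reassignment (possible when two medoids coincide) are dropped. Clustering
operates on strided frames (default every 100th); the full-resolution data
are assigned to the fixed centers afterwards, ties to the lowest index.
Note the refinement can raise the covering radius slightly above the
k-centers cutoff; the covering guarantee is a statement about k-centers
termination.

## MSM estimation

Transitions are counted per trajectory (never across boundaries) at a lag
that must be an integer multiple of the frame spacing; sliding-window
counting is the default for maximal data use, with independent-pair
counting behind a flag. Counts are restricted to the largest strongly
connected component of the transition graph (largest by state count, ties
by total counts) before estimation; a single-state component is accepted
with a degeneracy warning.

The reversible maximum-likelihood estimator iterates the standard
self-consistent fixed point on symmetrised counts,
x_ij ← (C_ij + C_ji) / (c_i/x_i + c_j/x_j), and returns
P_ij = x_ij / x_i, π_i = x_i / Σx. Convergence is declared when the
largest element change, measured relative to the largest element of x,
falls below 1e-10 within 10,000 sweeps. The relative criterion matters:
the normalised x entries scale like 1/K², so an absolute threshold would
declare false non-convergence on large thin count matrices. The fixed
point approaches its limit with a power-law tail on such matrices; a
residual still below 1e-6 after the sweep budget is accepted with a
warning, anything worse is an error. The reversible spectrum is computed
from the symmetrised similarity transform (real by construction); the
naive estimator's possibly complex eigenvalues are ordered by modulus with
real part breaking ties, so a periodic −1 never displaces the stationary
eigenvalue.

Implied timescales t_i(τ) = −τ/ln μ_i(τ) are reported for the top
min(10, K−1) non-unit eigenvalues across a lag scan; complex or
out-of-range eigenvalues are flagged (`complex`, `nonpositive`, `unit`)
rather than silently dropped, and an estimation failure at one lag is
recorded without aborting the others. Lag-independence of the timescales
is the Markovianity diagnostic; the package defaults to a 10 ns lag for
real data and 2 ns for the fast toy landscape (chosen from the flat region
of the toy's own implied-timescale curve).

States are ranked by π descending, ties by original cluster index; the
top state's medoid is the predicted pose. Both estimators are exposed
because published equilibrium populations of this protocol family may come
from either; reversible-MLE is the default.

## Free-energy map

Each retained state receives a binary occupancy over a regular grid
(default 1 Å): a cell is occupied if any ligand heavy atom of any frame
assigned to the state falls inside it, with half-open cell intervals (a
point exactly on a boundary belongs to the upper cell; an epsilon of 1e-9 Å
keeps this stable under superposition round-off). A medoid-only occupancy
mode exists for comparison. Cell probabilities P(c) = Σ_j o_cj π_j are
converted as F = −k_B T ln P (k_B = 0.0019872 kcal/mol/K, default 300 K)
and min-shifted to zero over occupied cells; never-occupied cells are
masked (NaN internally, a sentinel of max+10 kcal/mol in OpenDX output so
isosurface viewers render a closed surface). The sign convention is the
physical one: high probability means low free energy. Grids auto-expand to
bound the data with one cell of padding when no box is given. The suggested
reporting contour is 1.0 kcal/mol.

## Transition path theory

Macrostates are geometric: a state is unbound when its ligand sits more
than 20 Å from every protein atom (any protein atom — no surface
determination is attempted), bound when its ligand RMSD to the reference
pose is below 3 Å. States are judged by their medoid frame by default; a
strict all-frames mode is available. The committor solves the interior
linear system with q+ = 0 on the source and 1 on the sink; net flux is
max(0, f_ij − f_ji) of the gross reactive flux
f_ij = π_i (1 − q+_i) P_ij q+_j, and the total flux is the netted source
outflow. Pathways are extracted by repeatedly finding the
maximum-bottleneck source→sink path (Dijkstra-style maximin search with a
deterministic lexicographic tie-break), subtracting its bottleneck flux,
and stopping when the next path falls below 50% of the first — the
complete decomposition (threshold 0) reproduces the total flux exactly for
the acyclic net-flux field of a reversible model, which is the estimator
the pipeline uses. MFPTs solve m = τ + P m off the sink; the association
rate is 1/⟨MFPT⟩ with the π-weighted average over source states
(rates and mean passage times are reciprocal; the average of the times is
taken first). Times are physical (lag in ns), and no concentration
correction to a second-order rate constant is applied.

## Adaptive workflow

The convergence monitor rebuilds the entire pipeline on data prefixes of
k × interval aggregate time (trajectories in order, the last truncated —
never any later frames) and records the top-state pose RMSD to the
reference, with rolling mean and standard deviation over a 2-point window.
Convergence is declared when the last two checkpoints differ by less than
0.5 Å (a package decision, exposed in config; visual inspection of the
series remains the primary tool). Checkpoints whose model retains fewer
than two states are skipped with a warning. For targets without a
reference pose, the monitor can track distances to a user-listed residue
set instead. Seed selection for new rounds samples states uniformly or
with probability ∝ 1/(frames in state) — the latter pushes sampling toward
poorly explored regions — then a uniform member frame; pose seeding
translates the ligand over a cubic lattice (default ±20 Å, 5 Å steps,
giving tens of starting poses) and rejects poses with any ligand
heavy-atom–protein distance below 2 Å. The module emits restart
structures; it never launches simulations.

## Synthetic ground truth

The discrete-chain sampler draws exact trajectories from a given
row-stochastic matrix and anchors every MSM and TPT oracle test.

The toy binding system is a rigid 3-atom ligand diffusing around a static
20-atom mini-protein (12 backbone atoms on a helical arc, 8 shell atoms)
in a cubic box, under a potential that is a sum of isotropic Gaussian
wells: one bound well at the pocket (5.0 kcal/mol deep, 1.6 Å wide) and
two nonspecific sites (2.5 and 2.0 kcal/mol, 2.0 Å), flat elsewhere, at
300 K. Dynamics are a Metropolis walk of the ligand centroid (Gaussian
proposals, hard walls at the box and a 2.5 Å core exclusion around protein
atoms) rather than a discretised Langevin integrator: the walk satisfies
detailed balance by construction, so its stationary distribution is the
Boltzmann density exactly and basin populations can be validated against
numerical quadrature of exp(−U/kT) with no integrator bias. One step is
booked as 0.1 ns.

Conditions were sized so that the default ensemble (12 trajectories ×
2000 steps = 2.4 μs aggregate) contains on the order of ten complete
unbound→bound binding events: the box half-width is 26.5 Å (the smallest
leaving a > 20 Å unbound shell beyond the 6.1 Å protein) and the step
2.2 Å. A first parameterisation with a larger box and smaller steps
produced so few binding events that the bound state was ergodically
trimmed at intermediate convergence checkpoints; the protocol being
modelled presupposes abundant binding events, so the conditions were
corrected once and then frozen. Trajectory starts mix bound, nonspecific
and random unbound positions (the diverse-initial-ensemble strategy); an
equilibrium-start mode (Boltzmann rejection sampling) exists for unbiased
occupancy validation.

The ground-truth record carries the well definitions, the designed bound
pose, and each basin's Boltzmann weight from quadrature on a 0.5 Å grid
(basin = 3 Å sphere around a well center). Designed entry kinetics are
measured, not closed-form: a brute-force first-passage simulation runs
independent walkers from uniform unbound starts to absorption in the bound
basin (censored-MLE mean for stragglers). The MSM association rate is
required to agree with this oracle within a factor of 3 — a documented
tolerance covering MSM discretisation bias plus the sampling error of both
estimates; observed ratios at the tested seeds are 0.9–2.2. A
censoring-corrected estimator from the fixed-length ensemble itself is
also provided (total observed waiting time / completed passages), because
the naive mean over completed passages is biased far downward whenever
trajectories are shorter than the true MFPT.

What the toy system does not emulate: protein flexibility, ligand internal
degrees of freedom and orientation (the RMSD of a rigid translated ligand
reduces to a centroid distance), solvent, anisotropic wells, and realistic
energy barriers between sites. Passing tests therefore establish the
correctness of the analysis machinery on a landscape with known answers,
not force-field-level realism.

## Problem sizes and determinism

Default test/validation sizes are desk-scale by design: 2.4 μs of toy data
(24,000 frames), clustering on a 1 ns stride, assignment on a 0.5 ns
stride, ~1100 states, convergence checkpoints every 0.4 μs. Every random
choice (chain sampling, Metropolis walk, medoid proposals, seed selection)
flows from an explicit integer seed, and re-running any stage with
unchanged inputs reproduces byte-identical artifacts (CSV/JSON float
formats are pinned).

## Known limitations

- No Bayesian error bars on π or rates; no PCCA/metastable lumping (states
  are clusters); no hidden Markov models.
- Pathway decomposition assumes the acyclic net flux of a reversible
  estimate; on a non-reversible matrix the residual after extraction can
  retain cyclic flux.
- The unbound criterion uses all protein atoms, not a computed surface;
  with deeply buried atoms the effective cutoff is slightly conservative.
- PDB/XYZ/plain-text formats only; no binary trajectory readers.
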