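# Methods

## Model

A *branching SDE* describes a population of cells in a gene-expression space
`X ⊂ R^g`.  Each cell's state follows the Itô diffusion

    dX_t = -∇Ψ(t, X_t) dt + √τ dB_t,

with a scalar potential Ψ and constant diffusivity τ, and each cell carries
an independent exponential clock: at rate `b(t, x)` it divides into two cells
at its current position, at rate `d(t, x)` it dies.  Observation at a time
`t_i` is destructive and keeps each living cell independently with a
probability `q(t_i)` (subsampling).  The data at `t_i` are the observed
leaves of `K_i` independent lineage trees, each labelled by its state and by
its *observable generation number* m̃ — the number of divisions on its root
path for which **both** daughter subtrees contain at least one observed leaf.
When nothing dies and `q ≡ 1`, m̃ equals the true generation number m.

The central identity the package is built on: if ρ(m) denotes the
generation-resolved intensity of the branching population, which solves

    ∂_t ρ(m) = div(ρ(m)∇Ψ) + (τ/2)Δρ(m) + 2b ρ(m-1) - (b+d) ρ(m),

then the dyadically reweighted sum ρ̄ = Σ_m 2^(-m) ρ(m) solves
`∂_t ρ̄ = L*ρ̄ - d ρ̄`.  With `d = 0`, ρ̄ is exactly the law of the SDE
without branching: weighting each observed cell by `2^(-m̃)` "deconvolves"
proliferation.  Its empirical counterpart is exact at the level of single
trees: the observed, collapsed tree is full binary, so `Σ_leaves 2^(-m̃) = 1`
(Kraft equality), and the reweighted empirical measure (weights
`2^(-m̃)/K_i`) has mass one identically, even with death and subsampling.

With death or subsampling the reweighted population instead follows a biased
SDE: writing `S^{t_i}(t, x)` for the probability that a cell at `(t, x)` has
at least one observed descendant at `t_i`, the bias enters as an additive
potential `Ψ^{t_i} = -τ ln S^{t_i}`, i.e. a drift `τ∇ln S^{t_i}` pulling
cells toward regions of high survival, plus a reweighting `S^{t_i}(0,·)` of
the initial law.

## Reference models

The exact reference models of the original study are not published in the
text available to us, so the package defines two models from the described
constraints, calibrated only against the described features (leaf counts per
tree at the horizon, qualitative well structure and occupancy contrast) and
then frozen:

* **doublewell** — `Ψ = (x1² - 1)² + x2²`, τ = 0.25, T = 3, no death,
  `b = 0.35 + 1.05 σ(2 x1)` (σ the logistic-type `(1+tanh)/2`): two wells at
  x1 = ±1 with a four-fold birth-rate asymmetry.  Founders start at the
  saddle, N((0,0), 0.3²).  25 trees yield ≈ 650 leaves at T, ≈ 92% in the
  right well, against ≈ 52% for the SDE alone.
* **shallowwell** — Gaussian wells at x1 = 1 (depth 0.12, σ 0.8) and x1 = 6
  (depth 0.30, σ 1.5, lower curvature — "shallow"), a weak confinement
  `0.005 (x1-3)²`, `0.25 x2²`, τ = 0.9, T = 4, no death,
  `b = 1.1 + 2.5 exp(-|x-(6,0)|²/(2·1.2²))`.  Rare lineages cross the
  barrier; because the birth rate peaks in the shallow well, crossers
  dominate the branching population (≈ 37% beyond x1 = 4 at T versus ≈ 6%
  for the SDE alone), which is the regime where reweighting matters most.
  25 trees yield ≈ 4000 leaves at T.

Subsampling schedules decrease linearly from `q(0) = 1` to a configured
`q(T)` (a geometric variant is available).  The linear shape keeps the
subsampling-adequacy margin `q(t)·exp(∫(b-d)) - 1` nonnegative much longer
than a geometric decay with the same endpoint, which matters because once
the margin goes negative the observable generation numbers collapse and the
reweighted measure degrades to the plain one with fewer cells.

## Simulator

Euler–Maruyama with per-step Bernoulli thinning of the division/death clocks
(probabilities `b·dt`, `d·dt` per step, rejected as "dt too large" if their
sum reaches 0.5 anywhere).  Daughters start at the mother's position.  The
domain box reflects.  Default `dt = min(0.005, T/200)`; the per-step
thinning is unbiased to O(dt).  RNG streams are split per (timepoint, tree)
from one seed, so time courses are reproducible and snapshots independent.
Trees record every division and death; `collapse_observed` prunes a tree to
what lineage tracing reconstructs (observed leaves, both-sided-observed
divisions), on which leaf depth equals m̃.

`K_i` in the reweighted measure counts trees with at least one observed
cell: trees that leave no observation are invisible to an experimenter.

## Distances

Accuracy is the rooted (RMS) energy distance
`sqrt(2E|X-Y| - E|X-X'| - E|Y-Y'|)` between normalised weighted clouds, with
exact O(n²) weighted estimators; "cumulated" distances over a time course
are sums over timepoints.  Ground-truth clouds are independent simulations
of the SDE without branching (500 cells per timepoint unless stated).

## PDE oracles

1D/2D uniform-grid finite-volume solvers validate the stochastic machinery:
Scharfetter–Gummel exponential fitting for the advection–diffusion fluxes
(making the Gibbs density `e^{-2Ψ/τ}` exactly stationary discretely),
no-flux walls, Heun (RK2) time stepping, explicit stability bound
`dt ≲ cfl/(τ/h² + |v|/h + rates)`.  The generation ladder is truncated at
`M_max` (default 40) with a 1e-3 relative tail-mass check.

The branch-survival probability solves a backward reaction–diffusion
equation: the non-survival probability `u(s, x)` (s = time before the
measurement) satisfies

    ∂_s u = -∇Ψ·∇u + (τ/2)Δu + b u² + d - (b+d) u,   u(0,·) = 1 - q(t_i),

because a division leaves no observed branch iff both daughters leave none
(hence u²), and then `S = 1 - u`.  It is validated against the closed-form
linear birth–death extinction probability and against Monte-Carlo branch
survival frequencies.  The biased generation system uses the drift
`-∇Ψ + τ∇ln S` (log-gradients computed at cell faces) with birth rate `bS`
and no death; its dyadic sum is checked against the biased Fokker–Planck
equation, which is the grid-level statement of the bias characterisation.

## Trajectory inference (mean-field Langevin)

The law of the underlying SDE is recovered from the reweighted marginals by
minimising the marginal-penalised entropic objective

    τ H(R | W^τ) + (1/λ) Σ_i Δt_i · H(ρ̂_{t_i} | Φ_h * R_{t_i})

over path measures represented by N clouds of M uniform particles.  The
discretisation: the path-entropy term becomes the chain of entropic OT costs
between consecutive clouds with regulariser `ε_i = 2τΔt_i` (the scale at
which the Gibbs kernel `exp(-|x-y|²/ε)` equals the Brownian transition
density over Δt_i); the data term is the cross-entropy of each observed
cloud under the Gaussian-kernel-smoothed particle density (kernel width h);
the entropic regularisation over particle positions is realised by Langevin
noise `sqrt(2·temperature·step)` per iteration.  Gradients of the OT terms
use the converged plans (envelope theorem on the Schrödinger duals); Sinkhorn
runs in the log domain with ε-annealing on cold starts, warm-started duals
across iterations and a bounded per-iteration budget; the final couplings
are re-solved tightly and rounded onto the transportation polytope so their
uniform marginals hold to 1e-6.  The Langevin temperature is annealed to
zero over the final third of the iterations so the returned clouds
approximate a minimiser rather than a sample.  Particle displacements are
clipped at 3h per iteration for stability.

Defaults (all exposed in `MFLConfig`): `h = 0.2 ×` median pairwise data
distance, `λ = 0.05 ×` data span, `temperature = 0.1 τ λ`, step 0.02, 400
iterations, M = 100.  λ trades data fidelity against temporal coherence: the
experiments in `examples/` use λ ≈ 0.3 when the goal is marginal accuracy
and λ ≈ 2.4 when the goal is drift estimation from the couplings, where
temporal smoothing suppresses the sampling noise of consecutive independent
snapshots.

## Drift and birth-rate estimation

On the fitted clouds, the drift at particle `x_j` of timepoint i is the
coupling-conditional mean displacement per unit time; it is exact in the
dense-timepoint limit.  At finite Δt it is diluted within steep potential
wells by the factor `(1 - e^{-kΔt})/(kΔt)` (k the local curvature), a known
finite-difference effect that bounds the attainable per-coordinate
correlation with the true drift on the doublewell's steep x1 axis.

The birth rate re-inflates the particle masses with fractional generation
numbers m̄ transferred from the observed cells by exact quadratic-cost
transport (LP for up to 500 atoms, lightly entropic above):
`ρ* = 2^{m̄}/M`, and `b* = ln E_π[ρ*_{next}/ρ*] / Δt` along the couplings.
The estimator is invariant to global rescalings of ρ*.

The subsampling-adequacy check integrates `b - d` along deterministic
characteristics `φ' = -∇Ψ` from draws of the initial law and reports the
margin `min_probes q(t)·exp(∫(b-d)) - 1`, monotone in q.

## Bias control

For each interval, the later snapshot's collapsed trees are cut at `t_i`.
Each crossing branch is an ancestor; its state estimate is the Gaussian-tree
posterior mean of its observed descendants under Brownian motion with
diffusivity τ (upward message passing; drift is ignored across one
interval), and its generation label counts the visible divisions before
`t_i`.  Ancestors from all trees are pooled and matched to the cells
actually observed at `t_i` by a *semi-relaxed* entropic assignment
(quadratic cost, softness 0.05 × median squared distance) in which only the
ancestor marginal is constrained — a balanced matching would force every
observed cell to receive mass, contradicting the purpose of dropping cells
whose branch died.  Reweighting both sides by `2^(-m̃)` yields a pair of
probability measures compatible with the drift `-∇(Ψ + Ψ^{t_{i+1}})`.

`interval_incompatibility` scores a pair by pushing samples of the first
marginal through the SDE with a supplied drift and measuring the energy
distance to the second.  Note one structural consequence of the
construction: the corrected earlier marginal is built *from the same trees*
as the later one, so its incompatibility can fall below the noise floor of
two independent snapshots — the corrected arm can score at or below the
no-subsampling reference, rather than strictly between it and the
uncorrected arm.

## Synthetic data: what it does and does not emulate

The generator produces exact branching-SDE realisations with perfect state
observation and error-free trees.  It does not emulate scRNA-seq read-count
noise, barcode saturation or tree-reconstruction errors, doublets, or
non-gradient drifts; passing tests therefore validate the mathematical
machinery (reweighting, inference, bias control) under the model's own
assumptions, not robustness to measurement noise.  Real data would also
require dimension reduction (the methods are practical up to ~10
dimensions); the reference experiments are 2D.

## Problem sizes

The shipped experiments are desk-scale by design: 5–25 trees per timepoint,
8–12 timepoints, 60–100 particles, 500–1000 ground-truth cells, 10
replicate seeds for stochastic properties, 1D grids of ~241 nodes and ~65
saved survival time-slices for the PDE oracles.
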