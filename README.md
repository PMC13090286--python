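# lineagetraj

Trajectory inference for branching stochastic differential equation (SDE)
models of cell differentiation, using the generation numbers recorded by
CRISPR-based lineage tracing.

## The problem

Single-cell RNA-sequencing measures snapshots of a differentiating cell
population, but the measurement is destructive: one sees independent samples
of the population at a handful of times, never a cell's trajectory.
Trajectory inference reconstructs the law of the underlying stochastic
process from those snapshots.  Proliferation is the classical obstacle —
regions of gene-expression space where cells divide quickly accumulate cells
for reasons that have nothing to do with the differentiation dynamics, and
snapshot methods cannot tell the two apart without knowing the division
rates in advance.

Lineage tracing changes the picture.  When cells carry continuously mutating
CRISPR barcodes, each snapshot comes with reconstructed lineage trees, and
each observed cell has an *observable generation number* m̃: the number of
divisions on its ancestral path that left observed descendants on both
sides.  The key identity this package is built on: weighting each observed
cell by `2^(-m̃)` (and normalising by the number of observed trees) turns
the branching population back into the law of the branch-free SDE

    dX_t = -∇Ψ(t, X_t) dt + √τ dB_t ,

exactly when no cell dies and every leaf is observed — per individual tree,
the weights sum to one (Kraft equality on the full binary observed tree).
With death or subsampling, the reweighted population follows a biased SDE
whose drift distortion is `τ∇ln S`, with `S(t,x)` the probability that a
cell at `(t,x)` leaves at least one observed descendant.

## What the package does

* **simulate** branching SDEs with full lineage recording, death,
  subsampling, and observable generation numbers (`lineagetraj.simulate`),
  with two built-in reference landscapes (`builtin_model("doublewell")`,
  `builtin_model("shallowwell")`);
* **reweight** snapshots into probability measures (`reweighted_measure`),
  and compare weighted clouds with the rooted energy distance;
* **infer** the time-varying law of the underlying SDE from the reweighted
  marginals by mean-field Langevin minimisation of the marginal-penalised
  entropic objective `τH(R|W^τ) + (1/λ)Σ Δt_i H(ρ̂_i | Φ_h * R_i)`
  (`mfl_fit`), with per-interval entropic couplings;
* **estimate** the drift field `v*(t_i,x) = E[(X_{t_{i+1}}-X_{t_i})/Δt | X_{t_i}=x]`
  and the birth rate `b* = ln E[ρ*_{next}/ρ*]/Δt` from the fitted path
  measure (`estimate_drift`, `estimate_birth_rate`), plus the
  subsampling-adequacy margin `q(t)e^{∫(b-d)} ≥ 1`;
* **quantify and correct the observation bias**: finite-difference solvers
  for the generation-resolved master equations and the branch-survival
  probability (`lineagetraj.pde`), and a lineage-based correction that cuts
  the later snapshot's trees at the earlier time, estimates surviving
  ancestors by Gaussian message passing, and re-selects the earlier cells by
  transport matching (`lineagetraj.biascontrol`).

Snapshots round-trip through plain-text formats (Newick trees + TSV cell
tables + JSON metadata, `lineagetraj.io`), and a thin `lineagetraj` CLI
chains the stages (`simulate | reweight | infer | estimate | correct | eval`).

## Worked example

`examples/02_reweighting_deconvolves_growth.py` simulates 25 lineage trees
per model, builds the reweighted and the plain empirical measures at the
final time, and measures both against an independent simulation of the SDE
without branching:

```
doublewell: 659 cells from 25 trees (92% in the proliferative region)
  energy distance to SDE truth: reweighted 0.105  plain 0.763  -> reweighting wins
shallowwell: 4033 cells from 25 trees (37% in the proliferative region)
  energy distance to SDE truth: reweighted 0.116  plain 0.757  -> reweighting wins
```

The branching population sits overwhelmingly in the high-birth-rate region
(92% versus the 52% a symmetric SDE would give for the two-well model); the
`2^(-m̃)` weights undo that bias almost entirely, cutting the distance to
the true law by a factor of ~7 — without using the birth rate anywhere.

The other examples walk through simulation and Kraft sums (01), trajectory
inference and the three-way comparison against the known-growth-rate
heuristic (03), drift/birth-rate estimation (04), the survival-probability
PDE and the bias potential (05), and the lineage-based bias correction (06).

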