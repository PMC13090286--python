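"""Heuristic correction of the death/subsampling bias between timepoints.

When branches die out or are subsampled, the reweighted marginals at
consecutive timepoints are *not* compatible with any single SDE: each
timepoint carries its own drift bias τ∇ln S^{t_i}.  This module rebuilds,
for every interval (t_i, t_{i+1}), the distribution of cells at t_i that
have at least one observed descendant at t_{i+1} — the pair then becomes
compatible with the drift -∇(Ψ + Ψ^{t_{i+1}}).

Two steps, mirroring ancestor estimation and matching in lineage-resolved
optimal transport:

1.  Cut the collapsed observed trees of the t_{i+1} snapshot at t_i.  Each
    crossing branch is one surviving ancestor; its state is the Gaussian
    (Brownian-bridge) posterior mean of its observed descendants — the
    inverse-variance-weighted leaf average from upward message passing with
    per-unit-time variance τ — and its generation label counts the visible
    divisions before t_i.
2.  Match the estimated ancestors against the cells actually observed at
    t_i with (semi-relaxed, ancestor-marginal) optimal transport, which
    re-selects and re-weights the observed cells; cells whose branch died
    receive (near) zero weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measures import WeightedPointCloud, energy_distance, reweighted_measure
from .ot import sq_cost
from .simulate import DIVISION, LineageTree, Snapshot, collapse_observed

__all__ = ["AncestorEstimate", "estimate_ancestors", "correct_snapshot",
           "compatible_pair", "interval_incompatibility"]


@dataclass
class AncestorEstimate:
    """Estimated states at t_i of branches surviving to t_{i+1}."""

    t_cut: float
    states: np.ndarray          # (n_ancestors, g)
    m_tilde: np.ndarray         # visible divisions before t_cut, per ancestor
    n_desc: np.ndarray          # observed descendant leaves per ancestor
    tree_index: np.ndarray


def _subtree_message(tree: LineageTree, nid: int, tau: float) -> tuple[np.ndarray, float]:
    """Upward Gaussian message (mean, variance) at node ``nid`` from its
    observed descendant leaves, under Brownian motion with diffusivity tau."""
    node = tree.nodes[nid]
    if node.children is None:
        return np.asarray(node.state_at_end, dtype=float), 0.0
    means, variances = [], []
    for c in tree.nodes[nid].children:
        mu, var = _subtree_message(tree, c, tau)
        child = tree.nodes[c]
        variances.append(var + tau * (child.end_time - child.birth_time))
        means.append(mu)
    v0, v1 = variances
    m0, m1 = means
    if v0 == 0.0 and v1 == 0.0:
        return 0.5 * (m0 + m1), 0.0
    w0, w1 = 1.0 / max(v0, 1e-300), 1.0 / max(v1, 1e-300)
    return (w0 * m0 + w1 * m1) / (w0 + w1), 1.0 / (w0 + w1)


def estimate_ancestors(snapshot_next: Snapshot, t_cut: float, tau: float) -> AncestorEstimate:
    """Cut the collapsed trees of the later snapshot at ``t_cut`` and estimate
    each crossing branch's state there (pooled over trees)."""
    if t_cut >= snapshot_next.time:
        raise ValueError("t_cut must precede the snapshot time")
    states, ms, nd, ti = [], [], [], []
    for k, tree in enumerate(snapshot_next.trees):
        col = collapse_observed(tree)
        if col is None:
            continue
        ctree, _ = col
        counts = ctree.retained_counts()

        def visit(nid: int, m_before: int):
            node = ctree.nodes[nid]
            if node.birth_time <= t_cut <= node.end_time:
                mu, var = _subtree_message(ctree, nid, tau)
                # propagate the node message up the edge to the cut time
                mu_cut = mu  # Brownian posterior mean is time-shift invariant
                states.append(mu_cut)
                ms.append(m_before)
                nd.append(int(counts[nid]))
                ti.append(k)
                return
            if node.children is not None:
                nxt = m_before + (1 if node.end_event == DIVISION else 0)
                for c in node.children:
                    visit(c, nxt)

        visit(ctree.root, 0)
    if not states:
        raise ValueError("no branch of the later snapshot crosses the cut time")
    return AncestorEstimate(
        t_cut=t_cut,
        states=np.asarray(states, dtype=float),
        m_tilde=np.asarray(ms, dtype=int),
        n_desc=np.asarray(nd, dtype=int),
        tree_index=np.asarray(ti, dtype=int),
    )


def correct_snapshot(
    ancestors: AncestorEstimate,
    snapshot_i: Snapshot,
    epsilon_scale: float = 0.05,
) -> tuple[WeightedPointCloud, np.ndarray]:
    """Re-select the cells observed at t_i by matching them to the estimated
    surviving ancestors.

    Uses a semi-relaxed entropic assignment: each (uniform-mass) ancestor
    distributes its mass over the observed cells by distance, with softness
    ``epsilon_scale`` x the median squared distance; only the ancestor
    marginal is constrained, so observed cells whose branch left no observed
    descendant at t_{i+1} receive (near) zero mass.  Returns the corrected
    generation-labelled cloud (weights sum to 1) plus the per-cell fractional
    generation labels transferred from the ancestors.
    """
    if not snapshot_i.observed_cells:
        raise ValueError("empty observed snapshot at the earlier timepoint")
    X = snapshot_i.states()
    C = sq_cost(ancestors.states, X)
    eps = epsilon_scale * float(np.median(C)) + 1e-12
    logits = -C / eps
    logits -= logits.max(axis=1, keepdims=True)
    P = np.exp(logits)
    P /= P.sum(axis=1, keepdims=True)
    P /= len(ancestors.states)                    # uniform ancestor masses
    w = P.sum(axis=0)                             # matched mass per observed cell
    m_num = P.T @ ancestors.m_tilde.astype(float)
    m_bar = np.where(w > 1e-300, m_num / np.where(w > 0, w, 1.0),
                     snapshot_i.m_tildes().astype(float))
    cloud = WeightedPointCloud(X, w, time=snapshot_i.time)
    return cloud, m_bar


def compatible_pair(
    corrected: tuple[WeightedPointCloud, np.ndarray],
    snapshot_next: Snapshot,
) -> tuple[WeightedPointCloud, WeightedPointCloud]:
    """Apply generation-number reweighting to both sides of the interval.

    Returns mass-1 clouds (p̂^s_{t_i}, p̂_{t_{i+1}}) that are compatible for
    the SDE with drift -∇(Ψ + Ψ^{t_{i+1}}).
    """
    cloud, m_bar = corrected
    w = cloud.weights * 2.0 ** (-np.asarray(m_bar, dtype=float))
    if w.sum() <= 0:
        raise ValueError("corrected cloud has no mass after reweighting")
    first = WeightedPointCloud(cloud.points, w / w.sum(), time=cloud.time)
    second = reweighted_measure(snapshot_next)
    return first, second


def interval_incompatibility(
    pair: tuple[WeightedPointCloud, WeightedPointCloud],
    drift,
    tau: float,
    n_cells: int = 400,
    dt: float = 0.01,
    seed: int = 0,
    reflect=None,
) -> float:
    """Forward-simulation check of a marginal pair.

    Samples cells from the first cloud, pushes them through the SDE with the
    supplied ``drift(t, x)`` over the interval, and returns the energy
    distance to the second cloud.  Compatible pairs score at the sampling
    noise floor; incompatible pairs score above it.
    """
    first, second = pair
    a = first.normalized()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(a.points), size=n_cells, p=a.weights)
    x = a.points[idx].copy()
    t0, t1 = first.time, second.time
    if t0 is None or t1 is None or t1 <= t0:
        raise ValueError("pair must carry increasing times")
    t = t0
    while t < t1 - 1e-12:
        step = min(dt, t1 - t)
        x = x + np.asarray(drift(t, x), dtype=float) * step \
            + rng.normal(size=x.shape) * np.sqrt(tau * step)
        if reflect is not None:
            x = reflect(x)
        t += step
    return energy_distance(WeightedPointCloud.uniform(x), second)
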