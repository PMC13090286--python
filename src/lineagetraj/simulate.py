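"""Branching-SDE simulator with full lineage recording.

Cells follow Euler–Maruyama dynamics for ``dX = -∇Ψ dt + sqrt(τ) dB`` with
reflection at the domain box, and divide / die by per-step Bernoulli thinning
of their exponential clocks (probability ``b dt`` / ``d dt`` per step).  Every
division and death event is recorded in a :class:`LineageTree`; observation
applies subsampling and computes, for each retained leaf, the *observable*
generation number m̃: the number of divisions on its root path for which both
daughter subtrees still contain at least one retained leaf.  When nothing
dies and every leaf is retained, m̃ equals the true generation number m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import BranchingSDEModel, InitialLaw

__all__ = ["LineageNode", "LineageTree", "Snapshot", "ObservedCell",
           "simulate_tree", "observe_tree", "simulate_timecourse"]

DIVISION = "division"
DEATH = "death"
SAMPLED = "sampled"


@dataclass
class LineageNode:
    id: int
    parent: int | None
    birth_time: float
    end_time: float = np.nan
    end_event: str = SAMPLED
    state_at_end: np.ndarray | None = None
    children: tuple[int, int] | None = None
    observed: bool = False  # leaves only: retained by subsampling


@dataclass
class LineageTree:
    """A rooted binary tree of one founder cell's descendants."""

    nodes: list[LineageNode]
    root: int
    t0: float
    t_sample: float

    def leaves(self, event: str = SAMPLED) -> list[LineageNode]:
        return [n for n in self.nodes if n.children is None and n.end_event == event]

    def observed_leaves(self) -> list[LineageNode]:
        return [n for n in self.nodes if n.observed]

    def n_alive(self) -> int:
        return len(self.leaves(SAMPLED))

    def root_path(self, node_id: int) -> list[int]:
        """Node ids from the root down to (excluding) ``node_id``."""
        path = []
        nid = self.nodes[node_id].parent
        while nid is not None:
            path.append(nid)
            nid = self.nodes[nid].parent
        return path[::-1]

    def generation_number(self, node_id: int) -> int:
        """True generation number m: divisions on the root path."""
        return sum(1 for a in self.root_path(node_id)
                   if self.nodes[a].end_event == DIVISION)

    def retained_counts(self) -> np.ndarray:
        """Number of observed leaves in each node's subtree."""
        counts = np.zeros(len(self.nodes), dtype=int)
        # nodes are created in birth order, so children follow parents;
        # a reversed sweep accumulates counts bottom-up.
        for n in reversed(self.nodes):
            if n.children is None:
                counts[n.id] = int(n.observed)
            else:
                counts[n.id] = counts[n.children[0]] + counts[n.children[1]]
        return counts

    def observable_generation_numbers(self) -> dict[int, int]:
        """m̃ for every observed leaf, keyed by node id.

        A division counts toward m̃ only if both of its daughter subtrees
        contain at least one observed leaf.
        """
        counts = self.retained_counts()
        out: dict[int, int] = {}
        for leaf in self.observed_leaves():
            m = 0
            for a in self.root_path(leaf.id):
                node = self.nodes[a]
                if node.end_event == DIVISION:
                    c0, c1 = node.children
                    if counts[c0] >= 1 and counts[c1] >= 1:
                        m += 1
            out[leaf.id] = m
        return out


@dataclass(frozen=True)
class ObservedCell:
    tree_index: int
    node_id: int
    state: np.ndarray
    m_tilde: int
    m_true: int


@dataclass
class Snapshot:
    """One destructive measurement: independent trees plus observed cells."""

    time: float
    trees: list[LineageTree]
    observed_cells: list[ObservedCell] = field(default_factory=list)
    q: float = 1.0

    @property
    def n_observed_trees(self) -> int:
        """K_i: trees contributing at least one observed cell."""
        return len({c.tree_index for c in self.observed_cells})

    def states(self) -> np.ndarray:
        return np.asarray([c.state for c in self.observed_cells], dtype=float)

    def m_tildes(self) -> np.ndarray:
        return np.asarray([c.m_tilde for c in self.observed_cells], dtype=int)


def simulate_tree(
    model: BranchingSDEModel,
    x0: np.ndarray,
    t0: float,
    t1: float,
    dt: float,
    rng: np.random.Generator,
) -> LineageTree:
    """Simulate one founder cell and its descendants from ``t0`` to ``t1``.

    Surviving cells become ``sampled`` leaves at ``t1`` (not yet subsampled).
    Raises ``ValueError`` if ``(b + d) dt`` reaches 0.5 anywhere visited,
    which signals that ``dt`` is too coarse for the rates.
    """
    if dt <= 0 or t1 <= t0:
        raise ValueError("need dt > 0 and t0 < t1")
    x0 = np.asarray(x0, dtype=float)
    nodes = [LineageNode(id=0, parent=None, birth_time=t0)]
    # alive cells tracked as (node_id, state); all advance in lock-step.
    alive_ids = [0]
    states = x0[None, :].copy()
    t = t0
    sqrt_tau = np.sqrt(model.diffusivity)
    while t < t1 - 1e-12 and alive_ids:
        step = min(dt, t1 - t)
        drift = model.drift(t, states)
        noise = rng.normal(size=states.shape) * (sqrt_tau * np.sqrt(step))
        states = model.reflect(states + drift * step + noise)
        t += step
        b = np.asarray(model.birth_rate(t, states)) * step
        d = np.asarray(model.death_rate(t, states)) * step
        if np.any(b + d >= 0.5):
            raise ValueError("dt too large: (b + d) * dt >= 0.5 at a visited state")
        u = rng.random(len(alive_ids))
        divide = u < b
        die = (~divide) & (u < b + d)
        if not (np.any(divide) or np.any(die)):
            continue
        next_ids, next_states = [], []
        for j, nid in enumerate(alive_ids):
            node = nodes[nid]
            if divide[j]:
                node.end_time = t
                node.end_event = DIVISION
                node.state_at_end = states[j].copy()
                c0, c1 = len(nodes), len(nodes) + 1
                node.children = (c0, c1)
                nodes.append(LineageNode(id=c0, parent=nid, birth_time=t))
                nodes.append(LineageNode(id=c1, parent=nid, birth_time=t))
                next_ids.extend([c0, c1])
                next_states.extend([states[j], states[j]])
            elif die[j]:
                node.end_time = t
                node.end_event = DEATH
                node.state_at_end = states[j].copy()
            else:
                next_ids.append(nid)
                next_states.append(states[j])
        alive_ids = next_ids
        states = np.asarray(next_states, dtype=float).reshape(len(next_ids), x0.size)
    for j, nid in enumerate(alive_ids):
        node = nodes[nid]
        node.end_time = t1
        node.end_event = SAMPLED
        node.state_at_end = states[j].copy()
    return LineageTree(nodes=nodes, root=0, t0=t0, t_sample=t1)


def observe_tree(
    tree: LineageTree, q: float, rng: np.random.Generator
) -> tuple[list[int], dict[int, int]]:
    """Retain each sampled leaf independently with probability ``q``.

    Returns the retained node ids and their observable generation numbers m̃.
    Marks ``observed`` flags on the tree in place.
    """
    leaves = tree.leaves(SAMPLED)
    if not leaves:
        return [], {}
    keep = rng.random(len(leaves)) < q
    for n in tree.nodes:
        n.observed = False
    for leaf, k in zip(leaves, keep):
        leaf.observed = bool(k)
    retained = [leaf.id for leaf, k in zip(leaves, keep) if k]
    return retained, tree.observable_generation_numbers()


def simulate_timecourse(
    model: BranchingSDEModel,
    initial: InitialLaw | None,
    times: np.ndarray,
    trees_per_time: int | list[int],
    dt: float | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> list[Snapshot]:
    """Simulate independent snapshots at each requested time.

    Each snapshot grows ``K_i`` fresh trees from t = 0 (the measurement is
    destructive, so snapshots share nothing).  The RNG stream is split per
    (timepoint, tree) so a single seed reproduces everything.  A timepoint
    where no tree leaves any observation still yields a Snapshot, just with
    an empty ``observed_cells`` list.
    """
    initial = initial or model.initial_law
    if initial is None:
        raise ValueError("no initial law supplied and model has none")
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if isinstance(trees_per_time, int):
        trees_per_time = [trees_per_time] * len(times)
    if dt is None:
        dt = min(0.005, float(times[-1]) / 200.0)
    root = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    streams = root.spawn(len(times))
    snapshots = []
    for i, (t_i, K_i) in enumerate(zip(times, trees_per_time)):
        q = float(model.subsampling(float(t_i)))
        tree_streams = streams[i].spawn(K_i)
        trees, cells = [], []
        for k in range(K_i):
            rng = np.random.default_rng(tree_streams[k])
            x0 = initial.sampler(rng)
            tree = simulate_tree(model, x0, 0.0, float(t_i), dt, rng)
            retained, m_tilde = observe_tree(tree, q, rng)
            trees.append(tree)
            for nid in retained:
                cells.append(ObservedCell(
                    tree_index=k,
                    node_id=nid,
                    state=np.asarray(tree.nodes[nid].state_at_end, dtype=float),
                    m_tilde=m_tilde[nid],
                    m_true=tree.generation_number(nid),
                ))
        snapshots.append(Snapshot(time=float(t_i), trees=trees, observed_cells=cells, q=q))
    return snapshots


def collapse_observed(tree: LineageTree) -> tuple[LineageTree, dict[int, int]] | None:
    """Collapse a lineage tree to what lineage tracing reconstructs.

    Keeps only observed leaves and the divisions visible to an experimenter
    (those with at least one observed leaf on *both* sides); death branches
    and one-sided divisions are spliced out, their durations absorbed into
    the surviving edge.  Returns the collapsed tree plus a map from collapsed
    leaf ids to original node ids, or ``None`` if nothing was observed.

    In the collapsed tree every leaf's plain generation number equals its
    observable generation number m̃ in the original tree.
    """
    counts = tree.retained_counts()
    if counts[tree.root] == 0:
        return None

    def next_visible(nid: int) -> int:
        # walk down single-survivor chains until a visible division or leaf
        while True:
            node = tree.nodes[nid]
            if node.children is None:
                return nid
            c0, c1 = node.children
            alive = [c for c in (c0, c1) if counts[c] >= 1]
            if len(alive) == 2:
                return nid
            nid = alive[0]

    new_nodes: list[LineageNode] = []
    leaf_map: dict[int, int] = {}

    def build(start_nid: int, start_time: float, parent_new: int | None) -> int:
        nid = next_visible(start_nid)
        node = tree.nodes[nid]
        new_id = len(new_nodes)
        new = LineageNode(id=new_id, parent=parent_new, birth_time=start_time,
                          end_time=node.end_time,
                          end_event=DIVISION if node.children else SAMPLED,
                          state_at_end=None if node.children is None else None)
        new.state_at_end = (np.asarray(node.state_at_end, dtype=float)
                            if node.state_at_end is not None else None)
        new_nodes.append(new)
        if node.children is None:
            new.observed = True
            leaf_map[new_id] = nid
        else:
            kids = tuple(build(c, node.end_time, new_id) for c in node.children)
            new.children = kids
        return new_id

    root_id = build(tree.root, tree.t0, None)
    return (LineageTree(nodes=new_nodes, root=root_id, t0=tree.t0,
                        t_sample=tree.t_sample), leaf_map)


def simulate_sde_cloud(
    model: BranchingSDEModel,
    initial: InitialLaw | None,
    t: float,
    n_cells: int,
    dt: float | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Sample ``n_cells`` independent trajectories of the *non-branching* SDE
    at time ``t`` — the ground truth the reweighted measures should match."""
    initial = initial or model.initial_law
    if dt is None:
        dt = min(0.005, t / 200.0) if t > 0 else 0.005
    rng = np.random.default_rng(seed)
    x = initial.sample(rng, n_cells)
    sqrt_tau = np.sqrt(model.diffusivity)
    s = 0.0
    while s < t - 1e-12:
        step = min(dt, t - s)
        x = model.reflect(x + model.drift(s, x) * step
                          + rng.normal(size=x.shape) * (sqrt_tau * np.sqrt(step)))
        s += step
    return x
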