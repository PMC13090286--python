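import numpy as np
import pytest

from lineagetraj.measures import reweighted_measure
from lineagetraj.simulate import (DIVISION, SAMPLED, collapse_observed,
                                  observe_tree, simulate_timecourse,
                                  simulate_tree)

from conftest import make_model


def yule_tree(b, T, seed, dt=0.002):
    model = make_model(b=b, T=T)
    rng = np.random.default_rng(seed)
    return simulate_tree(model, np.array([0.0]), 0.0, T, dt, rng)


def test_no_branching_single_lineage(rng):
    model = make_model()
    tree = simulate_tree(model, np.array([0.0]), 0.0, 1.0, 0.01, rng)
    leaves = tree.leaves(SAMPLED)
    assert len(leaves) == 1
    assert tree.generation_number(leaves[0].id) == 0


def test_yule_mean_leaf_count_matches_exponential_growth():
    # E[leaves at T] = e^{bT} for a pure birth process
    b, T, n_rep = 1.2, 1.0, 300
    counts = [yule_tree(b, T, seed) .n_alive() for seed in range(n_rep)]
    mean, se = np.mean(counts), np.std(counts) / np.sqrt(n_rep)
    assert abs(mean - np.exp(b * T)) <= 3 * se + 0.05 * np.exp(b * T)


def test_death_dominates_most_trees_extinct():
    model = make_model(d=5.0, T=1.0)
    rng = np.random.default_rng(0)
    extinct = sum(
        simulate_tree(model, np.array([0.0]), 0.0, 1.0, 0.002, rng).n_alive() == 0
        for _ in range(50))
    assert extinct >= 45


def test_dt_too_large_raises():
    model = make_model(b=30.0)
    with pytest.raises(ValueError, match="dt too large"):
        simulate_tree(model, np.array([0.0]), 0.0, 1.0, 0.05,
                      np.random.default_rng(0))


def test_generation_numbers_equal_when_fully_observed(rng):
    tree = yule_tree(1.5, 1.2, seed=7)
    retained, m_tilde = observe_tree(tree, 1.0, rng)
    assert len(retained) == tree.n_alive()
    for nid in retained:
        assert m_tilde[nid] == tree.generation_number(nid)


def test_observable_generation_skips_one_sided_divisions(rng):
    # root divides at t=0.2 into A,B; A divides at 0.5 into A1,A2.
    # If only A1,A2 are retained, the root division is invisible: m_tilde=1.
    from lineagetraj.simulate import LineageNode, LineageTree
    nodes = [
        LineageNode(0, None, 0.0, 0.2, DIVISION, np.zeros(1), (1, 2)),
        LineageNode(1, 0, 0.2, 0.5, DIVISION, np.zeros(1), (3, 4)),
        LineageNode(2, 0, 0.2, 1.0, SAMPLED, np.zeros(1)),
        LineageNode(3, 1, 0.5, 1.0, SAMPLED, np.zeros(1)),
        LineageNode(4, 1, 0.5, 1.0, SAMPLED, np.zeros(1)),
    ]
    tree = LineageTree(nodes, root=0, t0=0.0, t_sample=1.0)
    for n in nodes:
        n.observed = n.id in (3, 4)
    mt = tree.observable_generation_numbers()
    assert mt == {3: 1, 4: 1}
    # with all three leaves observed, the full depths are visible
    for n in nodes:
        n.observed = n.children is None
    mt = tree.observable_generation_numbers()
    assert mt == {2: 1, 3: 2, 4: 2}


@pytest.mark.parametrize("q,d", [(1.0, 0.0), (0.5, 0.0), (1.0, 0.5), (0.4, 0.4)])
def test_kraft_equality_under_death_and_subsampling(q, d):
    # each observed tree's dyadic weights sum to exactly one
    model = make_model(b=1.5, d=d, q=q, T=1.2)
    snaps = simulate_timecourse(model, None, [1.2], 40, dt=0.004, seed=3)
    snap = snaps[0]
    seen = {}
    for c in snap.observed_cells:
        seen.setdefault(c.tree_index, 0.0)
        seen[c.tree_index] += 2.0 ** (-c.m_tilde)
    assert seen, "need at least one observed tree"
    for total in seen.values():
        assert total == pytest.approx(1.0, abs=1e-12)
    assert reweighted_measure(snap).mass == pytest.approx(1.0, abs=1e-12)


def test_timecourse_reproducible_and_independent():
    model = make_model(b=1.0, T=1.0)
    a = simulate_timecourse(model, None, [0.5, 1.0], 5, seed=42)
    b = simulate_timecourse(model, None, [0.5, 1.0], 5, seed=42)
    for sa, sb in zip(a, b):
        assert len(sa.observed_cells) == len(sb.observed_cells)
        np.testing.assert_array_equal(sa.states(), sb.states())
    c = simulate_timecourse(model, None, [0.5, 1.0], 5, seed=43)
    assert not np.array_equal(a[1].states(), c[1].states())


def test_single_cells_when_no_branching():
    model = make_model()
    snaps = simulate_timecourse(model, None, [0.8], 5, seed=9)
    assert len(snaps[0].observed_cells) == 5
    assert np.all(snaps[0].m_tildes() == 0)


def test_collapse_observed_full_binary_and_depths():
    model = make_model(b=1.5, d=0.5, q=0.6, T=1.2)
    snaps = simulate_timecourse(model, None, [1.2], 30, dt=0.004, seed=5)
    snap = snaps[0]
    mt_by_tree = {}
    for c in snap.observed_cells:
        mt_by_tree.setdefault(c.tree_index, []).append(c.m_tilde)
    for k, tree in enumerate(snap.trees):
        col = collapse_observed(tree)
        if col is None:
            assert k not in mt_by_tree
            continue
        ctree, leaf_map = col
        # collapsed tree is full binary: every internal node has 2 children
        for n in ctree.nodes:
            assert n.children is None or len(n.children) == 2
        # leaf depth in the collapsed tree equals m_tilde
        depths = sorted(ctree.generation_number(nid) for nid in leaf_map)
        assert depths == sorted(mt_by_tree[k])
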