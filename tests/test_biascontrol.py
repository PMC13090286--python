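import numpy as np
import pytest

from lineagetraj.biascontrol import (compatible_pair, correct_snapshot,
                                     estimate_ancestors,
                                     interval_incompatibility)
from lineagetraj.measures import WeightedPointCloud, reweighted_measure
from lineagetraj.simulate import (DIVISION, SAMPLED, LineageNode, LineageTree,
                                  ObservedCell, Snapshot, simulate_timecourse)

from conftest import make_model


def two_leaf_tree(split_time, t_sample, states, t0=0.0):
    nodes = [
        LineageNode(0, None, t0, split_time, DIVISION, np.zeros(1), (1, 2)),
        LineageNode(1, 0, split_time, t_sample, SAMPLED,
                    np.atleast_1d(np.asarray(states[0], float))),
        LineageNode(2, 0, split_time, t_sample, SAMPLED,
                    np.atleast_1d(np.asarray(states[1], float))),
    ]
    for n in nodes[1:]:
        n.observed = True
    return LineageTree(nodes, root=0, t0=t0, t_sample=t_sample)


def snapshot_of(trees, time):
    cells = []
    for k, tree in enumerate(trees):
        mt = tree.observable_generation_numbers()
        for nid, m in mt.items():
            cells.append(ObservedCell(k, nid, tree.nodes[nid].state_at_end, m, m))
    return Snapshot(time=time, trees=trees, observed_cells=cells)


class TestAncestorEstimation:
    def test_single_lineage_carries_state_back(self):
        nodes = [LineageNode(0, None, 0.0, 1.0, SAMPLED, np.array([0.7]))]
        nodes[0].observed = True
        tree = LineageTree(nodes, root=0, t0=0.0, t_sample=1.0)
        snap = snapshot_of([tree], 1.0)
        anc = estimate_ancestors(snap, 0.5, tau=0.3)
        np.testing.assert_allclose(anc.states, [[0.7]])
        assert anc.m_tilde.tolist() == [0]

    def test_split_exactly_at_cut_equal_branches(self):
        tree = two_leaf_tree(0.5, 1.0, [0.0, 2.0])
        snap = snapshot_of([tree], 1.0)
        anc = estimate_ancestors(snap, 0.5, tau=0.3)
        assert len(anc.states) == 1
        np.testing.assert_allclose(anc.states, [[1.0]], atol=1e-12)
        assert anc.m_tilde.tolist() == [0]

    def test_split_after_cut_unequal_gaussian_posterior(self):
        # three leaves: (a) splits at 0.8 into leaves at x=0 and 2; (b) leaf
        # at x=5.  Cut at 0.4.  Oracle: GLS posterior mean on the 3-leaf
        # Brownian covariance.
        nodes = [
            LineageNode(0, None, 0.0, 0.6, DIVISION, np.zeros(1), (1, 2)),
            LineageNode(1, 0, 0.6, 0.8, DIVISION, np.zeros(1), (3, 4)),
            LineageNode(2, 0, 0.6, 1.0, SAMPLED, np.array([5.0])),
            LineageNode(3, 1, 0.8, 1.0, SAMPLED, np.array([0.0])),
            LineageNode(4, 1, 0.8, 1.0, SAMPLED, np.array([2.0])),
        ]
        for n in nodes:
            n.observed = n.children is None
        tree = LineageTree(nodes, root=0, t0=0.0, t_sample=1.0)
        snap = snapshot_of([tree], 1.0)
        tau, t_cut = 0.5, 0.4
        anc = estimate_ancestors(snap, t_cut, tau=tau)
        assert len(anc.states) == 1
        # brute-force GLS: cov_ij = tau * shared time from t_cut; mean of
        # X_{t_cut} given leaves = 1' C^{-1} x / 1' C^{-1} 1
        # conditional on the state at the cut, leaf deviations are Gaussian
        # with covariance tau * (shared tree time below the cut)
        C = np.array([
            [0.6, 0.4, 0.2],   # leaves 3,4 share [0.4, 0.8]; all share [0.4, 0.6]
            [0.4, 0.6, 0.2],
            [0.2, 0.2, 0.6],
        ]) * tau
        x = np.array([0.0, 2.0, 5.0])
        Ci = np.linalg.inv(C)
        ones = np.ones(3)
        want = ones @ Ci @ x / (ones @ Ci @ ones)
        np.testing.assert_allclose(anc.states[0][0], want, rtol=1e-9)

    def test_permutation_invariance(self):
        t1 = two_leaf_tree(0.6, 1.0, [0.0, 2.0])
        t2 = two_leaf_tree(0.6, 1.0, [2.0, 0.0])
        a1 = estimate_ancestors(snapshot_of([t1], 1.0), 0.3, tau=0.2)
        a2 = estimate_ancestors(snapshot_of([t2], 1.0), 0.3, tau=0.2)
        np.testing.assert_allclose(a1.states, a2.states)

    def test_counts_only_divisions_before_cut(self):
        # division at 0.3 (before cut at 0.5), then at 0.7 (after)
        nodes = [
            LineageNode(0, None, 0.0, 0.3, DIVISION, np.zeros(1), (1, 2)),
            LineageNode(1, 0, 0.3, 0.7, DIVISION, np.zeros(1), (3, 4)),
            LineageNode(2, 0, 0.3, 1.0, SAMPLED, np.array([3.0])),
            LineageNode(3, 1, 0.7, 1.0, SAMPLED, np.array([0.0])),
            LineageNode(4, 1, 0.7, 1.0, SAMPLED, np.array([1.0])),
        ]
        for n in nodes:
            n.observed = n.children is None
        tree = LineageTree(nodes, root=0, t0=0.0, t_sample=1.0)
        anc = estimate_ancestors(snapshot_of([tree], 1.0), 0.5, tau=0.2)
        assert sorted(anc.m_tilde.tolist()) == [1, 1]
        assert sorted(anc.n_desc.tolist()) == [1, 2]


class TestCorrection:
    def test_no_death_correction_is_near_identity(self):
        model = make_model(b=1.2, q=1.0, T=1.0)
        snaps = simulate_timecourse(model, None, [0.5, 1.0], 8, seed=31)
        anc = estimate_ancestors(snaps[1], 0.5, tau=model.diffusivity)
        cloud, m_bar = correct_snapshot(anc, snaps[0])
        assert cloud.mass == pytest.approx(1.0, abs=1e-9)
        # every observed cell at t_0 has surviving descendants: no cell is
        # dropped outright
        assert (cloud.weights > 1e-4).mean() >= 0.9

    def test_dead_branch_cell_gets_no_mass(self):
        # ancestors all near x=0; one observed cell sits far away at x=10
        anc_snap = snapshot_of([two_leaf_tree(0.6, 1.0, [0.0, 0.2])], 1.0)
        anc = estimate_ancestors(anc_snap, 0.5, tau=0.2)
        cells = [
            ObservedCell(0, 0, np.array([0.1]), 0, 0),
            ObservedCell(1, 0, np.array([10.0]), 0, 0),
        ]
        snap0 = Snapshot(time=0.5, trees=[], observed_cells=cells)
        cloud, m_bar = correct_snapshot(anc, snap0)
        assert cloud.weights[1] <= 1e-6
        assert cloud.weights[0] == pytest.approx(1.0, abs=1e-6)

    def test_compatible_pair_masses_one(self):
        model = make_model(b=1.2, d=0.4, q=0.7, T=1.0)
        snaps = simulate_timecourse(model, None, [0.5, 1.0], 12, seed=33)
        anc = estimate_ancestors(snaps[1], 0.5, tau=model.diffusivity)
        pair = compatible_pair(correct_snapshot(anc, snaps[0]), snaps[1])
        assert pair[0].mass == pytest.approx(1.0, abs=1e-9)
        assert pair[1].mass == pytest.approx(1.0, abs=1e-12)

    def test_hand_built_two_tree_weights(self):
        # two trees at t1: one with two leaves (m=1 each), one single leaf;
        # reweighting gives (1/4,1/4,1/2) on the later side
        trees = [two_leaf_tree(0.6, 1.0, [0.0, 0.4])]
        single = LineageTree([LineageNode(0, None, 0.0, 1.0, SAMPLED,
                                          np.array([1.0]))], 0, 0.0, 1.0)
        single.nodes[0].observed = True
        trees.append(single)
        snap1 = snapshot_of(trees, 1.0)
        rw = reweighted_measure(snap1)
        np.testing.assert_allclose(sorted(rw.weights), [0.25, 0.25, 0.5])
        assert rw.mass == pytest.approx(1.0)


class TestIntervalIncompatibility:
    def test_exact_marginals_score_noise_floor_and_wrong_drift_scores_high(self, rng):
        # OU pair: exact conditional evolution vs a grossly wrong drift
        tau, dt = 0.2, 0.5
        x0 = rng.normal(0, 1.0, size=(500, 1))
        x1 = x0 * np.exp(-dt) + rng.normal(size=(500, 1)) * np.sqrt(
            tau / 2 * (1 - np.exp(-2 * dt)))
        pair = (WeightedPointCloud.uniform(x0, time=0.0),
                WeightedPointCloud.uniform(x1, time=dt))
        good = interval_incompatibility(pair, lambda t, x: -x, tau, seed=5)
        bad = interval_incompatibility(pair, lambda t, x: +3 * x, tau, seed=5)
        assert good < 0.12
        assert bad > 3 * good
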