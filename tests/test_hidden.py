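import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm

from treedelay.decision import DecisionParams, cumulative_hazard, decision_density, hazard
from treedelay.delay import DelayParams, transient_generator
from treedelay.genealogy import FateLabel, Genealogy
from treedelay.hidden import (
    HiddenTree,
    TreeLikelihoodEngine,
    _pruned_ids,
    enumerate_hidden_trees,
    likelihood_subtree,
    likelihood_tree,
    likelihood_tree_enumerated,
    likelihood_undiff,
    map_hidden_tree,
    predicted_decision_generation,
    snap_tree,
)

from conftest import make_tree

THETA = DecisionParams(0.06, -0.0005)
ETA = DelayParams(alpha=0.8, gamma=0.02, x_star=10)


# -- scenario enumeration ---------------------------------------------------

class TestEnumeration:
    def test_single_onset_cell_forced_cover(self, single_onset_tree):
        scen = enumerate_hidden_trees(single_onset_tree)
        assert len(scen) == 1
        assert scen[0].decision_cells == frozenset({"1"})

    def test_cherry_with_two_onset_daughters(self, cherry_onset_tree):
        scen = enumerate_hidden_trees(cherry_onset_tree)
        covers = {s.decision_cells for s in scen}
        assert covers == {frozenset({"1"}), frozenset({"10", "11"})}

    def test_depth2_all_onset_leaves_has_five_scenarios(self):
        spec = {
            "1": (None, 0.0, 8.0, "division", None),
            "10": ("1", 8.0, 16.0, "division", None),
            "11": ("1", 8.0, 16.0, "division", None),
        }
        for leaf in ("100", "101", "110", "111"):
            spec[leaf] = (leaf[:-1], 16.0, 30.0, "lost", 25.0)
        tree = make_tree(spec)
        # cover-counting recursion: f(leaf)=1, f(v)=1+f(l)*f(r) => 1+2*2=5
        assert len(enumerate_hidden_trees(tree)) == 5

    def test_size_guard(self, default_sim):
        big = max(default_sim.trees, key=lambda t: t.n_cells())
        with pytest.raises(ValueError, match="enumeration"):
            enumerate_hidden_trees(big, max_cells=10)

    def test_no_onset_tree_allows_empty_scenario(self):
        tree = make_tree({"1": (None, 0.0, 20.0, "movie_end", None)})
        covers = {s.decision_cells for s in enumerate_hidden_trees(tree)}
        assert covers == {frozenset(), frozenset({"1"})}

    def test_antichain_property(self, small_sim_trees):
        for tree in small_sim_trees:
            if len(_pruned_ids(tree)) > 13:
                continue
            for s in enumerate_hidden_trees(tree):
                for a in s.decision_cells:
                    for b in s.decision_cells:
                        if a != b:
                            assert not b.startswith(a)  # heap ids: prefix = ancestor


# -- undecided-part likelihood ---------------------------------------------

class TestUndiff:
    def test_zero_hazard_gives_probability_one(self, small_sim_trees):
        tree = small_sim_trees[0]
        assert likelihood_undiff(tree, tree.cells, DecisionParams(0.0, 0.0)) == 0.0

    def test_single_cell_constant_hazard_closed_form(self):
        tree = make_tree({"1": (None, 0.0, 7.5, "movie_end", None)})
        ll = likelihood_undiff(tree, ["1"], DecisionParams(0.2, 0.0))
        assert ll == pytest.approx(-0.2 * 7.5, rel=1e-12)

    def test_additivity_over_cells(self, small_sim_trees):
        tree = max(small_sim_trees, key=lambda t: t.n_cells())
        ids = list(tree.cells)
        total = likelihood_undiff(tree, ids, THETA)
        parts = sum(likelihood_undiff(tree, [c], THETA) for c in ids)
        assert total == pytest.approx(parts, rel=1e-12)


# -- decision-rooted subtree likelihood vs quadrature oracles ---------------

class TestSubtreeOracles:
    def test_single_cell_matches_direct_convolution(self):
        # decision in [0, t_on], first passage at t_on: independent oracle
        # integrates phi(t') * psi_0(t_on - t') with adaptive quadrature
        t_on = 6.0
        tree = make_tree({"1": (None, 0.0, t_on, "lost", t_on)})
        eta = DelayParams(alpha=1.5, gamma=0.1, x_star=6)
        a = transient_generator(eta)
        e0 = np.zeros(6)
        e0[0] = 1.0

        def integrand(tp):
            psi = eta.alpha * (e0 @ expm(a * (t_on - tp)))[-1]
            return decision_density(tp, THETA) * psi

        oracle, err = quad(integrand, 0.0, t_on, limit=300)
        ll = likelihood_subtree(tree, "1", THETA, eta, h=0.01)
        assert np.exp(ll) == pytest.approx(oracle, rel=5e-5)

    def test_three_cell_subtree_matches_nested_quadrature(self):
        # mother decides at t', divides at c; both daughters show onsets.
        # The oracle marginalises the mother's expression state at
        # division jointly — daughters are independent only GIVEN that
        # state, so a product-of-marginals shortcut would be wrong.
        c, t1, t2 = 5.0, 9.0, 11.0
        tree = make_tree(
            {
                "1": (None, 0.0, c, "division", None),
                "10": ("1", c, t1, "lost", t1),
                "11": ("1", c, t2, "lost", t2),
            }
        )
        eta = DelayParams(alpha=1.2, gamma=0.08, x_star=5)
        n = eta.x_star
        a = transient_generator(eta)
        e0 = np.zeros(n)
        e0[0] = 1.0

        psi1 = eta.alpha * expm(a * (t1 - c))[:, -1]
        psi2 = eta.alpha * expm(a * (t2 - c))[:, -1]

        def integrand(tp, shortcut=False):
            at_div = e0 @ expm(a * (c - tp))  # state distribution at division
            if shortcut:
                val = float(at_div @ psi1) * float(at_div @ psi2)
            else:
                val = float(at_div @ (psi1 * psi2))
            return decision_density(tp, THETA) * val

        oracle, _ = quad(integrand, 0.0, c, limit=300)
        wrong, _ = quad(lambda tp: integrand(tp, shortcut=True), 0.0, c, limit=300)
        ll = likelihood_subtree(tree, "1", THETA, eta, h=0.0125)
        assert np.exp(ll) == pytest.approx(oracle, rel=5e-5)
        # treating the daughters as independent of the mother's division
        # state is a different (wrong) quantity
        assert np.exp(ll) != pytest.approx(wrong, rel=1e-4)

    def test_dead_marker_with_onset_is_impossible(self, single_onset_tree):
        eta = DelayParams(alpha=0.0, gamma=0.1, x_star=5)
        ll = likelihood_subtree(single_onset_tree, "1", THETA, eta, h=0.25)
        assert ll == -np.inf


# -- dynamic program vs explicit enumeration --------------------------------

class TestDynamicProgram:
    def test_dp_equals_enumeration_on_simulated_trees(self, small_sim_trees):
        checked = 0
        for tree in small_sim_trees:
            if len(_pruned_ids(tree)) > 15:
                continue
            dp = likelihood_tree(tree, THETA, ETA, h=0.5).log_likelihood
            en = likelihood_tree_enumerated(tree, THETA, ETA, h=0.5)
            if np.isinf(en):
                assert np.isinf(dp)
            else:
                assert dp == pytest.approx(en, rel=1e-10)
            checked += 1
        assert checked >= 10

    def test_tree_with_onset_but_zero_hazard(self, single_onset_tree):
        res = likelihood_tree(single_onset_tree, DecisionParams(0.0, 0.0), ETA)
        assert res.log_likelihood == -np.inf

    def test_tree_without_onsets_and_zero_hazard(self):
        tree = make_tree(
            {
                "1": (None, 0.0, 10.0, "division", None),
                "10": ("1", 10.0, 25.0, "movie_end", None),
                "11": ("1", 10.0, 25.0, "movie_end", None),
            }
        )
        res = likelihood_tree(tree, DecisionParams(0.0, 0.0), ETA)
        assert res.log_likelihood == pytest.approx(0.0, abs=1e-12)

    def test_likelihood_invariant_to_relabelling_and_child_swap(self, cherry_onset_tree):
        base = likelihood_tree(cherry_onset_tree, THETA, ETA).log_likelihood
        relabeled = make_tree(
            {
                "1": (None, 0.0, 10.0, "division", None),
                # children swapped and renamed
                "10": ("1", 10.0, 24.0, "lost", 20.0),
                "11": ("1", 10.0, 22.0, "lost", 18.0),
            }
        )
        assert likelihood_tree(relabeled, THETA, ETA).log_likelihood == pytest.approx(
            base, rel=1e-12
        )

    def test_sum_dominates_max_dominates_members(self, small_sim_trees):
        for tree in small_sim_trees[:8]:
            if len(_pruned_ids(tree)) > 13:
                continue
            total = likelihood_tree(tree, THETA, ETA, h=0.5).log_likelihood
            ranked = map_hidden_tree(tree, THETA, ETA, k=3, h=0.5)
            scores = [s for _, s in ranked]
            assert all(scores[i] >= scores[i + 1] for i in range(len(scores) - 1))
            assert total >= scores[0] - 1e-9
            _, members = likelihood_tree_enumerated(
                tree, THETA, ETA, h=0.5, return_scenarios=True
            )
            for _, ll in members:
                assert scores[0] >= ll - 1e-9


class TestMapScenarios:
    def test_single_onset_cell_unique_scenario(self, single_onset_tree):
        ranked = map_hidden_tree(single_onset_tree, THETA, ETA)
        assert len(ranked) == 1
        assert ranked[0][0].decision_cells == frozenset({"1"})

    def test_rank1_agrees_with_bruteforce(self, small_sim_trees):
        agree = checked = 0
        for tree in small_sim_trees:
            if len(_pruned_ids(tree)) > 13:
                continue
            _, members = likelihood_tree_enumerated(
                tree, THETA, ETA, h=0.5, return_scenarios=True
            )
            best = max(members, key=lambda m: m[1])
            got = map_hidden_tree(tree, THETA, ETA, k=1, h=0.5)[0]
            if not np.isfinite(best[1]):
                continue
            checked += 1
            assert got[1] == pytest.approx(best[1], abs=1e-9)
            if got[0].decision_cells == best[0].decision_cells:
                agree += 1
        assert checked >= 10 and agree == checked

    def test_k_must_be_positive(self, single_onset_tree):
        with pytest.raises(ValueError):
            map_hidden_tree(single_onset_tree, THETA, ETA, k=0)


def test_predicted_decision_generations(cherry_onset_tree):
    root_dec = HiddenTree(cherry_onset_tree.tree_id, frozenset({"1"}))
    assert predicted_decision_generation(root_dec, cherry_onset_tree) == {"1": 0}
    daughters = HiddenTree(cherry_onset_tree.tree_id, frozenset({"10", "11"}))
    assert predicted_decision_generation(daughters, cherry_onset_tree) == {
        "10": 1,
        "11": 1,
    }


def test_undiff_cells_partition(cherry_onset_tree):
    ht = HiddenTree(cherry_onset_tree.tree_id, frozenset({"10", "11"}))
    assert ht.undiff_cells(cherry_onset_tree) == frozenset({"1"})
    ht_root = HiddenTree(cherry_onset_tree.tree_id, frozenset({"1"}))
    assert ht_root.undiff_cells(cherry_onset_tree) == frozenset()


def test_engine_per_tree_matches_single_tree(small_sim_trees):
    trees = small_sim_trees[:6]
    engine = TreeLikelihoodEngine(trees, h=0.5)
    engine.set_eta(ETA)
    per_tree = engine.per_tree_loglik(THETA)
    for tree, tl in zip(trees, per_tree):
        solo = likelihood_tree(tree, THETA, ETA, h=0.5)
        assert tl.log_likelihood == pytest.approx(solo.log_likelihood, rel=1e-12)
    total = engine.loglik(THETA)
    assert total == pytest.approx(sum(t.log_likelihood for t in per_tree), rel=1e-12)


def test_quadrature_grid_refinement_converges(small_sim_trees):
    # on a grid-aligned tree, halving the step refines only the
    # quadrature and propagator resolution, so values must converge
    tree = snap_tree(
        next(t for t in small_sim_trees if t.onset_cells() and t.n_cells() > 3), 1.0
    )
    vals = [
        likelihood_tree(tree, THETA, ETA, h=h).log_likelihood for h in (1.0, 0.5, 0.25, 0.125)
    ]
    diffs = np.abs(np.diff(vals))
    assert diffs[-1] < diffs[0]
    assert diffs[-1] < 0.05
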