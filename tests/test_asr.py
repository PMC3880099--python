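"""Mk1 ancestral-state reconstruction: likelihood, marginals, transitions."""

import itertools

import numpy as np
import pytest

import divshift as ds
from divshift.asr import _assign_states, _check_traits, _loglik


def brute_force(tree, states, q):
    """Oracle: sum the likelihood over all internal-state assignments."""
    nodes = tree.internal_nodes
    total = 0.0
    marg = np.zeros((len(nodes), 2))
    for assign in itertools.product([0, 1], repeat=len(nodes)):
        amap = {nd.cindex: s for nd, s in zip(nodes, assign)}
        p = 0.5  # flat root prior
        for nd in tree.root.preorder_iter():
            if nd is tree.root:
                continue
            ps = amap[nd.parent_node.cindex]
            cs = states[nd.taxon.label] if nd.is_leaf() else amap[nd.cindex]
            p *= ds.mk_transition_prob(q, nd.parent_node.age - nd.age)[ps, cs]
        total += p
        for i, s in enumerate(assign):
            marg[i, s] += p
    return np.log(total), marg[:, 1] / marg.sum(axis=1)


class TestTransitionProb:
    def test_zero_time_is_identity(self):
        np.testing.assert_allclose(ds.mk_transition_prob(0.7, 0.0), np.eye(2))

    def test_closed_form_value(self):
        P = ds.mk_transition_prob(0.5, 1.0)
        assert P[0, 1] == pytest.approx((1 - np.exp(-1)) / 2, rel=1e-12)
        assert P[0, 1] == pytest.approx(0.31606, abs=5e-6)

    def test_stationary_limit_and_rows(self):
        P = ds.mk_transition_prob(10.0, 100.0)
        np.testing.assert_allclose(P, np.full((2, 2), 0.5), atol=1e-9)
        np.testing.assert_allclose(ds.mk_transition_prob(0.3, 2.0).sum(axis=1),
                                   [1, 1])


class TestLikelihood:
    def test_matches_brute_force(self):
        for seed in (1, 2, 3):
            tree = ds.simulate_pure_birth(9, 0.5, seed=seed)
            states = ds.simulate_mk_trait(tree, 0.3, 0, seed=seed + 50)
            states[tree.tip_labels[0]] = 1 - states[tree.tip_labels[0]]
            for q in (0.05, 0.4, 2.0):
                ll_o, _ = brute_force(tree, states, q)
                ll = _loglik(tree, _check_traits(tree, states), q)
                assert ll == pytest.approx(ll_o, rel=1e-10)

    def test_two_tip_symmetry(self):
        t = ds.parse_tree("(A:1,B:1);")
        for q in (0.1, 0.7):
            la = _loglik(t, {"A": 0, "B": 1}, q)
            lb = _loglik(t, {"A": 1, "B": 0}, q)
            assert la == pytest.approx(lb, rel=1e-12)

    def test_q_zero_monomorphic_is_root_prior(self, balanced8):
        states = {lb: 1 for lb in balanced8.tip_labels}
        assert _loglik(balanced8, states, 0.0) == pytest.approx(np.log(0.5))

    def test_rescale_invariance(self):
        # stretching time by c while dividing q by c leaves the likelihood fixed
        import re

        tree = ds.simulate_pure_birth(12, 0.5, seed=5)
        states = ds.simulate_mk_trait(tree, 0.3, 0, seed=55)
        states[tree.tip_labels[0]] = 1 - states[tree.tip_labels[0]]
        c = 7.3
        nwk = re.sub(r":([0-9.eE+-]+)",
                     lambda m: ":" + repr(float(m.group(1)) * c),
                     tree.to_newick(digits=17))
        tree_c = ds.parse_tree(nwk)
        ll1 = _loglik(tree, _check_traits(tree, states), 0.4)
        ll2 = _loglik(tree_c, _check_traits(tree_c, states), 0.4 / c)
        assert ll2 == pytest.approx(ll1, rel=1e-9)


class TestFit:
    def test_monomorphic_warns_lower_bound(self, balanced8):
        states = {lb: 0 for lb in balanced8.tip_labels}
        with pytest.warns(UserWarning, match="unidentified"):
            res = ds.mk_fit(balanced8, states)
        assert res["q_hat"] == pytest.approx(1e-6 / balanced8.root_age)

    def test_q_recovery(self):
        # true q = 0.05 on ~120-tip trees: the ML estimate concentrates
        q_hats = []
        s = 0
        while len(q_hats) < 40:
            tree = ds.simulate_pure_birth(120, 0.25, seed=s)
            states = ds.simulate_mk_trait(tree, 0.05, 0, seed=700 + s)
            s += 1
            if len(set(states.values())) < 2:
                continue
            q_hats.append(ds.mk_fit(tree, states)["q_hat"])
        assert 0.03 <= np.median(q_hats) <= 0.08

    def test_missing_tip_state_raises(self, three_tip):
        with pytest.raises(KeyError):
            ds.mk_fit(three_tip, {"A": 0, "B": 1})


class TestMarginals:
    def test_matches_brute_force(self):
        for seed in (4, 5):
            tree = ds.simulate_pure_birth(8, 0.5, seed=seed)
            states = ds.simulate_mk_trait(tree, 0.4, 0, seed=seed + 60)
            states[tree.tip_labels[0]] = 1 - states[tree.tip_labels[0]]
            for q in (0.1, 0.8):
                _, marg_o = brute_force(tree, states, q)
                marg = ds.marginal_states(tree, states, q)
                got = np.array([marg[nd.cindex] for nd in tree.internal_nodes])
                np.testing.assert_allclose(got, marg_o, rtol=1e-9)

    def test_two_tip_opposite_states_root_half(self):
        t = ds.parse_tree("(A:1,B:1);")
        marg = ds.marginal_states(t, {"A": 0, "B": 1}, 0.3)
        assert marg[0] == pytest.approx(0.5)

    def test_cherry_of_state1_certain_when_q_small(self, balanced8):
        states = {lb: 0 for lb in balanced8.tip_labels}
        states["A"] = states["B"] = 1
        marg = ds.marginal_states(balanced8, states, 0.001)
        cherry = balanced8.mrca(["A", "B"])
        assert marg[cherry.cindex] > 0.99


class TestTransitionNode:
    def test_none_when_all_benthic(self, balanced8):
        states = {lb: 0 for lb in balanced8.tip_labels}
        marg = ds.marginal_states(balanced8, states, 0.01)
        assert ds.find_transition_node(balanced8, marg) is None

    def test_root_returned_when_root_pelagic(self, balanced8):
        states = {lb: 1 for lb in balanced8.tip_labels}
        marg = ds.marginal_states(balanced8, states, 0.01)
        assert ds.find_transition_node(balanced8, marg) is balanced8.root

    def test_most_ancestral_wins(self, balanced8):
        # one pelagic cherry: its MRCA is the oldest node above threshold
        states = {lb: 0 for lb in balanced8.tip_labels}
        states["A"] = states["B"] = 1
        marg = ds.marginal_states(balanced8, states, 0.001)
        node = ds.find_transition_node(balanced8, marg)
        assert node.tipset == frozenset({"A", "B"})


class TestCountTransitions:
    def test_monomorphic_zero(self, balanced8):
        states = {lb: 0 for lb in balanced8.tip_labels}
        marg = ds.marginal_states(balanced8, states, 0.01)
        counts = ds.count_transitions(balanced8, _assign_states(balanced8, marg),
                                      states)
        assert counts == {"n_0to1": 0, "n_1to0": 0}

    def test_single_gain_for_one_cherry(self, balanced8):
        states = {lb: 0 for lb in balanced8.tip_labels}
        states["A"] = states["B"] = 1
        res = ds.Mk1(balanced8, states).fit()
        assert (res.n_0to1, res.n_1to0) in {(1, 0), (2, 0)}
        # with a small fixed q the single-gain history is forced
        marg = ds.marginal_states(balanced8, states, 0.001)
        counts = ds.count_transitions(balanced8, _assign_states(balanced8, marg),
                                      states)
        assert counts == {"n_0to1": 1, "n_1to0": 0}


class TestMk1Facade:
    def test_fit_summary_and_consistency(self):
        p = ds.SimParams(lambda0=0.1, lambda1=0.4, q01=0.01, q10=0.0,
                         n_target=60, seed=31)
        st = ds.simulate_state_dependent(p)
        res = ds.Mk1(st.tree, st.tip_state).fit()
        assert res.loglik <= 0
        for v in res.node_prob.values():
            assert 0 <= v <= 1
        txt = res.summary()
        assert "q_hat" in txt and "transition" in txt
        table = res.node_table()
        assert len(table.splitlines()) == len(st.tree.internal_nodes) + 1
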