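import numpy as np
import pytest

from umbelevo import synth
from umbelevo.mk import (
    aicc,
    assemble_Q,
    build_combined_spec,
    build_rate_spec,
    fit_mk,
    marginal_ancestral,
    mk_loglik,
    model_table,
    transition_matrices,
)
from umbelevo.tree import Phylogeny, parse_newick

from conftest import PSEUDO_STATES, enumeration_loglik, enumeration_marginals, random_tree


class TestRateSpecs:
    @pytest.mark.parametrize("structure,ordered,expected", [
        ("ARD", True, 4), ("ARD", False, 6),
        ("SYM", True, 2), ("SYM", False, 3),
        ("ER", True, 1), ("ER", False, 1),
    ])
    def test_three_state_parameter_counts(self, structure, ordered, expected):
        spec = build_rate_spec(structure, ordered, PSEUDO_STATES)
        assert spec.n_params == expected

    @pytest.mark.parametrize("structure,correlated,expected", [
        ("ARD", True, 24), ("ARD", False, 8),
        ("SYM", True, 12), ("SYM", False, 4),
    ])
    def test_combined_nine_state_counts(self, structure, correlated, expected):
        spec = build_combined_spec(structure, correlated)
        assert spec.n_states == 9
        assert len(spec.param_index) == 24  # one-step moves in one character
        assert spec.n_params == expected

    def test_ordered_excludes_direct_jumps(self):
        spec = build_rate_spec("ARD", True, PSEUDO_STATES)
        assert (0, 2) not in spec.param_index
        assert (2, 0) not in spec.param_index


class TestAssembleQ:
    def test_zero_params_zero_matrix(self):
        spec = build_rate_spec("ER", False, PSEUDO_STATES)
        assert np.all(assemble_Q(spec, [0.0]) == 0.0)

    def test_er_full_graph(self):
        spec = build_rate_spec("ER", False, ("a", "b", "c"))
        Q = assemble_Q(spec, [0.7])
        off = Q[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.7)
        assert np.allclose(np.diag(Q), -1.4)

    def test_negative_rate_rejected(self):
        spec = build_rate_spec("ER", False, ("a", "b"))
        with pytest.raises(ValueError):
            assemble_Q(spec, [-1.0])

    @pytest.mark.parametrize("seed", range(20))
    def test_expQt_row_stochastic(self, seed):
        rng = np.random.default_rng(seed)
        structure = ["ER", "SYM", "ARD"][seed % 3]
        k = int(rng.integers(2, 6))
        spec = build_rate_spec(structure, bool(seed % 2), tuple(map(str, range(k))))
        Q = assemble_Q(spec, rng.uniform(0.01, 2.0, spec.n_params))
        for t in (0.1, 1.0, 10.0):
            P = transition_matrices(Q, [t])[0]
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(P >= -1e-12) and np.all(P <= 1 + 1e-12)


class TestLoglik:
    def test_single_tip_equal_prior(self):
        t = Phylogeny(np.array([-1, 0]), np.array([0.0, 1.0]), [None, "A"])
        Q = assemble_Q(build_rate_spec("ER", True, PSEUDO_STATES), [0.3])
        ll = mk_loglik(t, {"A": {"absent"}}, Q, root="equal", states=PSEUDO_STATES)
        assert np.isclose(ll, np.log(1 / 3))

    def test_zero_rate_matrix(self, three_tip_tree):
        Q = np.zeros((3, 3))
        tips = {l: {"absent"} for l in three_tip_tree.tip_labels}
        ll = mk_loglik(three_tip_tree, tips, Q, root="equal", states=PSEUDO_STATES)
        assert np.isclose(ll, np.log(1 / 3))
        tips["A"] = {"floral"}
        assert mk_loglik(three_tip_tree, tips, Q, root="equal",
                         states=PSEUDO_STATES) == -np.inf

    @pytest.mark.parametrize("seed", range(8))
    def test_pruning_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        t = random_tree(rng, n)
        states = ("0", "1", "2")
        spec = build_rate_spec("ARD", False, states)
        Q = assemble_Q(spec, rng.uniform(0.02, 0.8, 6))
        tips = {lab: {states[rng.integers(3)]} for lab in t.tip_labels}
        if seed % 3 == 0:  # include an ambiguous tip
            lab = t.tip_labels[0]
            tips[lab] = {"0", "1"}
        ll = mk_loglik(t, tips, Q, root="equal", states=states)
        assert np.isclose(ll, enumeration_loglik(t, tips, Q, states), atol=1e-10)

    def test_tip_missing_from_data_raises(self, three_tip_tree):
        Q = assemble_Q(build_rate_spec("ER", True, PSEUDO_STATES), [0.1])
        with pytest.raises(ValueError, match="C"):
            mk_loglik(three_tip_tree, {"A": {"absent"}, "B": {"absent"}}, Q,
                      states=PSEUDO_STATES)

    def test_tip_reorder_invariance(self):
        a = parse_newick("((A:1,B:1):1,C:2):0;")
        b = parse_newick("(C:2,(B:1,A:1):1):0;")
        Q = assemble_Q(build_rate_spec("SYM", True, PSEUDO_STATES), [0.2, 0.4])
        tips = {"A": {"floral"}, "B": {"absent"}, "C": {"hyperfloral"}}
        for root in ("equal", "stationary", "fitzjohn"):
            assert np.isclose(mk_loglik(a, tips, Q, root, PSEUDO_STATES),
                              mk_loglik(b, tips, Q, root, PSEUDO_STATES))


class TestMarginals:
    def test_zero_rate_constant_character(self, three_tip_tree):
        Q = np.zeros((3, 3))
        tips = {l: {"absent"} for l in three_tip_tree.tip_labels}
        marg = marginal_ancestral(three_tip_tree, tips, Q, states=PSEUDO_STATES)
        for probs in marg.values():
            assert np.isclose(probs[1], 1.0)

    def test_symmetric_cherry_root_half_half(self):
        t = parse_newick("(A:1,B:1):0;")
        Q = assemble_Q(build_rate_spec("ER", False, ("0", "1")), [0.5])
        marg = marginal_ancestral(t, {"A": {"0"}, "B": {"1"}}, Q, states=("0", "1"))
        assert np.allclose(marg[t.root], [0.5, 0.5])

    @pytest.mark.parametrize("seed", [3, 11])
    def test_equals_clamped_enumeration(self, seed, four_tip_tree):
        rng = np.random.default_rng(seed)
        states = ("0", "1", "2")
        Q = assemble_Q(build_rate_spec("ARD", False, states),
                       rng.uniform(0.05, 0.6, 6))
        tips = {lab: {states[rng.integers(3)]} for lab in four_tip_tree.tip_labels}
        marg = marginal_ancestral(four_tip_tree, tips, Q, states=states)
        brute = enumeration_marginals(four_tip_tree, tips, Q, states)
        for v, probs in brute.items():
            assert np.allclose(marg[v], probs, atol=1e-10)
            assert np.isclose(marg[v].sum(), 1.0)


class TestAICc:
    @pytest.mark.parametrize("lnL,k,n,expected", [
        (-337.1, 1, 847, 676.2),
        (-2707.4, 14, 847, 5443.3),
        (0.0, 0, 10, 0.0),
    ])
    def test_values(self, lnL, k, n, expected):
        assert round(aicc(lnL, k, n), 1) == expected

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestFit:
    def test_nesting_er_sym_ard(self, yule50):
        rng = np.random.default_rng(5)
        states = PSEUDO_STATES
        Q = assemble_Q(build_rate_spec("ARD", True, states), [0.1, 0.5, 0.2, 0.3])
        tips, _ = synth.simulate_mk_history(yule50, Q, "absent", seed=9,
                                            states=states)
        fits = [fit_mk(yule50, tips, build_rate_spec(s, True, states),
                       n_starts=3, seed=1) for s in ("ER", "SYM", "ARD")]
        assert fits[2].lnL >= fits[1].lnL - 1e-6
        assert fits[1].lnL >= fits[0].lnL - 1e-6
        table = model_table(fits)
        assert table[0]["dAICc"] == 0.0
        assert [r["AICc"] for r in table] == sorted(r["AICc"] for r in table)

    def test_constant_character_boundary(self, yule50):
        tips = {l: {"absent"} for l in yule50.tip_labels}
        spec = build_rate_spec("ER", True, PSEUDO_STATES)
        fit = fit_mk(yule50, tips, spec, n_starts=2, seed=0)
        assert np.isclose(fit.lnL, np.log(1 / 3), atol=1e-3)
        assert fit.rates[0] < 1e-6

    def test_model_table_requires_same_n(self, yule50):
        tips = {l: {"absent"} for l in yule50.tip_labels}
        spec = build_rate_spec("ER", True, PSEUDO_STATES)
        f1 = fit_mk(yule50, tips, spec, n_starts=1, seed=0)
        f2 = fit_mk(yule50, tips, spec, n_starts=1, seed=0)
        f2.n = 99
        with pytest.raises(ValueError):
            model_table([f1, f2])

    def test_model_table_tie_flags_both(self, yule50):
        tips = {l: {"absent"} for l in yule50.tip_labels}
        spec = build_rate_spec("ER", True, PSEUDO_STATES)
        f1 = fit_mk(yule50, tips, spec, n_starts=1, seed=0)
        f2 = fit_mk(yule50, tips, spec, n_starts=1, seed=1)
        table = model_table([f1, f2])
        assert all(r["best"] for r in table)


def test_uncorrelated_combined_fit_decomposes(yule50):
    """Independently evolving characters: combined uncorrelated lnL ~ sum of
    the two single-character lnLs at the ML."""
    states_a = PSEUDO_STATES
    states_b = ("small", "medium", "large")
    Qa = assemble_Q(build_rate_spec("SYM", True, states_a), [0.15, 0.3])
    Qb = assemble_Q(build_rate_spec("SYM", True, states_b), [0.4, 0.2])
    tips_a, _ = synth.simulate_mk_history(yule50, Qa, "absent", seed=31,
                                          states=states_a)
    tips_b, _ = synth.simulate_mk_history(yule50, Qb, "medium", seed=32,
                                          states=states_b)
    fa = fit_mk(yule50, tips_a, build_rate_spec("SYM", True, states_a),
                n_starts=2, seed=1)
    fb = fit_mk(yule50, tips_b, build_rate_spec("SYM", True, states_b),
                n_starts=2, seed=1)
    combined = build_combined_spec("SYM", correlated=False,
                                   states_a=states_a, states_b=states_b)
    tips_ab = {lab: {f"{next(iter(tips_a[lab]))}|{next(iter(tips_b[lab]))}"}
               for lab in yule50.tip_labels}
    fab = fit_mk(yule50, tips_ab, combined, n_starts=3, seed=1)
    assert fab.k == 4
    assert np.isclose(fab.lnL, fa.lnL + fb.lnL, atol=0.5)
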