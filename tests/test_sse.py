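import numpy as np
import pytest

from umbelevo import synth
from umbelevo.mk import assemble_Q, build_rate_spec, mk_loglik
from umbelevo.sse import (
    bd_tree_loglik,
    build_model_set_binary,
    build_model_set_multistate,
    build_mucid,
    build_muhisse,
    build_musse,
    fit_sse,
    lambda_mu_from_turnover,
    sse_loglik,
    unresolved_clade_loglik,
)

from conftest import PSEUDO_STATES

SF1 = {s: 1.0 for s in PSEUDO_STATES}


class TestTurnover:
    def test_simple_values(self):
        assert lambda_mu_from_turnover(1.0, 0.0) == (1.0, 0.0)
        lam, mu = lambda_mu_from_turnover(1.5, 0.5)
        assert np.isclose(lam, 1.0) and np.isclose(mu, 0.5)

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        tau = rng.uniform(0.01, 5, 1000)
        eps = rng.uniform(0, 2, 1000)
        lam, mu = lambda_mu_from_turnover(tau, eps)
        assert np.allclose(lam + mu, tau)
        assert np.allclose(mu / lam, eps)


class TestModelCounts:
    """Diversification / transition parameter counts of the 12-model set."""

    def test_multistate_set(self):
        models = {m.name: m for m in build_model_set_multistate(SF1)}
        expect = {
            "MuSSE equivalent (constrained eps)": (4, 4),
            "MuSSE equivalent": (6, 4),
            "MuCID-3 (constrained eps)": (4, 18),
            "MuCID-3": (6, 18),
            "MuHiSSE absent (constrained eps)": (5, 6),
            "MuHiSSE absent": (8, 6),
            "MuHiSSE floral (constrained eps)": (5, 6),
            "MuHiSSE floral": (8, 6),
            "MuHiSSE hyperfloral (constrained eps)": (5, 6),
            "MuHiSSE hyperfloral": (8, 6),
            "MuHiSSE all states (constrained eps)": (7, 10),
            "MuHiSSE all states": (12, 10),
        }
        assert len(models) == 12
        for name, (ndiv, ntrans) in expect.items():
            assert (models[name].n_div, models[name].n_trans) == (ndiv, ntrans), name

    def test_binary_set(self):
        models = {m.name: m for m in build_model_set_binary({"absent": 1.0,
                                                             "present": 1.0})}
        assert set(models) == {"BiSSE-like", "CID-2", "CID-4", "HiSSE"}
        bisse = models["BiSSE-like"]
        assert bisse.n_tau == 2 and bisse.n_trans == 2

    def test_cid_symmetry_under_label_swap(self):
        """CID turnover depends only on the hidden class, so swapping the
        observed tip labels leaves the likelihood unchanged."""
        tree = synth.simulate_bd_tree(1.0, 0.0, n_tips=20, seed=6)
        sf = {"absent": 1.0, "present": 1.0}
        cid2 = [m for m in build_model_set_binary(sf) if m.name == "CID-2"][0]
        # symmetric observed transitions: relabeling is then a pure symmetry
        params = np.concatenate([[1.0, 1.6], [0.3], [0.15] * cid2.n_trans])
        tips = {lab: {"absent" if i % 2 else "present"}
                for i, lab in enumerate(tree.tip_labels)}
        swapped = {lab: {"present" if "absent" in s else "absent"}
                   for lab, s in tips.items()}
        a = sse_loglik(tree, tips, cid2, params)
        b = sse_loglik(tree, swapped, cid2, params)
        assert np.isclose(a, b, atol=1e-8)

    def test_hisse_collapses_to_bisse(self):
        """Zero hidden-switch rates and duplicated classes reduce HiSSE to
        the BiSSE likelihood."""
        tree = synth.simulate_bd_tree(1.0, 0.0, n_tips=25, seed=9)
        sf = {"absent": 1.0, "present": 1.0}
        models = {m.name: m for m in build_model_set_binary(sf)}
        hisse, bisse = models["HiSSE"], models["BiSSE-like"]
        tips = {lab: {"absent" if i % 3 else "present"}
                for i, lab in enumerate(tree.tip_labels)}
        tau_a, tau_p, eps, q_ap, q_pa = 1.2, 1.6, 0.3, 0.1, 0.2
        pb = np.array([tau_a, tau_p, eps, q_ap, q_pa])
        # hisse params: taus per (obs, class) duplicated; switch rates 0
        taus = []
        for (o, _c) in hisse.states:
            taus.append(tau_a if o == "absent" else tau_p)
        qmap = {}
        for (i, j), pid in hisse.trans_spec.param_index.items():
            oi, ci = hisse.states[i]
            oj, cj = hisse.states[j]
            if oi == oj:
                qmap[pid] = 0.0  # hidden switch
            else:
                qmap[pid] = q_ap if oi == "absent" else q_pa
        qs = [qmap[p] for p in range(hisse.n_trans)]
        ph = np.concatenate([taus, [eps], qs])
        a = sse_loglik(tree, tips, hisse, ph, step_scale=0.02)
        b = sse_loglik(tree, tips, bisse, pb, step_scale=0.02)
        assert np.isclose(a, b, atol=1e-6)


class TestLoglik:
    def test_yule_closed_form(self, yule50):
        tips = {lab: {"s"} for lab in yule50.tip_labels}
        model = build_musse({"s": 1.0}, obs_states=("s",), n_tau=1,
                            ordered=False)
        lam = 0.8
        ll = sse_loglik(yule50, tips, model, [lam, 1e-9], step_scale=0.01)
        assert np.isclose(ll, bd_tree_loglik(yule50, lam, 0.0), atol=1e-6)

    def test_bd_closed_form(self, yule50):
        tips = {lab: {"s"} for lab in yule50.tip_labels}
        model = build_musse({"s": 1.0}, obs_states=("s",), n_tau=1,
                            ordered=False)
        tau, eps = 1.4, 0.6
        lam, mu = lambda_mu_from_turnover(tau, eps)
        ll = sse_loglik(yule50, tips, model, [tau, eps], step_scale=0.01)
        assert np.isclose(ll, bd_tree_loglik(yule50, float(lam), float(mu)),
                          atol=1e-6)

    def test_equal_rates_factorization(self):
        """Equal diversification across states and full sampling: the SSE
        likelihood splits into (birth-death tree) x (Mk character)."""
        tree = synth.simulate_bd_tree(1.0, 0.2, n_tips=50, seed=17)
        spec = build_rate_spec("ARD", True, PSEUDO_STATES)
        qrates = [0.05, 0.2, 0.15, 0.08]
        Q = assemble_Q(spec, qrates)
        tips, _ = synth.simulate_mk_history(tree, Q, "absent", seed=18,
                                            states=PSEUDO_STATES)
        model = build_musse(SF1, n_tau=1, constrained_eps=True)
        tau, eps = 1.2, 0.25
        lam, mu = lambda_mu_from_turnover(tau, eps)
        ll = sse_loglik(tree, tips, model,
                        np.concatenate([[tau], [eps], qrates]),
                        step_scale=0.02)
        expected = (bd_tree_loglik(tree, float(lam), float(mu))
                    + mk_loglik(tree, tips, Q, root="fitzjohn",
                                states=PSEUDO_STATES))
        assert np.isclose(ll, expected, atol=1e-6)

    def test_matches_fine_step_integration(self):
        tree = synth.simulate_bd_tree(1.0, 0.3, n_tips=5, seed=23)
        model = build_musse(SF1, constrained_eps=True)
        tips = {lab: {PSEUDO_STATES[i % 3]}
                for i, lab in enumerate(tree.tip_labels)}
        params = np.array([0.9, 1.3, 1.1, 0.4, 0.1, 0.25, 0.2, 0.15])
        coarse = sse_loglik(tree, tips, model, params, step_scale=0.05)
        fine = sse_loglik(tree, tips, model, params, step_scale=0.002,
                          min_steps=64)
        assert np.isclose(coarse, fine, atol=1e-8)

    def test_child_order_invariance(self, yule50):
        model = build_musse(SF1, constrained_eps=True)
        tips = {lab: {PSEUDO_STATES[i % 3]}
                for i, lab in enumerate(yule50.tip_labels)}
        params = np.array([1.0, 1.2, 0.9, 0.3, 0.1, 0.2, 0.15, 0.12])
        ll = sse_loglik(yule50, tips, model, params)
        flipped = yule50.copy()
        flipped._children = None
        # reverse children order everywhere
        ch = [list(reversed(c)) for c in yule50.children]
        flipped._children = ch
        flipped._postorder = None
        assert np.isclose(sse_loglik(flipped, tips, model, params), ll,
                          atol=1e-9)

    def test_non_ultrametric_rejected(self, four_tip_tree):
        model = build_musse(SF1, constrained_eps=True)
        tips = {lab: {"absent"} for lab in four_tip_tree.tip_labels}
        with pytest.raises(ValueError):
            sse_loglik(four_tip_tree, tips, model, np.ones(model.n_params))

    def test_sampling_fraction_enters_tips(self, yule50):
        sf = {s: 0.5 for s in PSEUDO_STATES}
        m_full = build_musse(SF1, constrained_eps=True)
        m_half = build_musse(sf, constrained_eps=True)
        tips = {lab: {"absent"} for lab in yule50.tip_labels}
        params = np.array([1.0, 1.0, 1.0, 0.2, 0.1, 0.1, 0.1, 0.1])
        assert not np.isclose(sse_loglik(yule50, tips, m_full, params),
                              sse_loglik(yule50, tips, m_half, params))


class TestUnresolvedClades:
    def test_yule_singleton(self):
        lam, t = 0.7, 3.0
        assert np.isclose(unresolved_clade_loglik(1, t, lam, 0.0), -lam * t)

    def test_short_stem_limit(self):
        assert np.isclose(np.exp(unresolved_clade_loglik(1, 1e-9, 1.0, 0.0)),
                          1.0, atol=1e-6)

    @pytest.mark.parametrize("lam,mu,t", [(1.0, 0.0, 2.0), (0.8, 0.3, 1.5)])
    def test_series_sums_to_survival(self, lam, mu, t):
        from umbelevo.sse import _bd_xEphi

        total = sum(np.exp(unresolved_clade_loglik(n, t, lam, mu))
                    for n in range(1, 4000))
        E, _ = _bd_xEphi(t, lam, mu)
        assert np.isclose(total, 1.0 - float(E), atol=1e-8)


class TestFit:
    def test_single_regime_recovery(self):
        """With full sampling and one state, fitted (lambda, mu) land near
        the generating values."""
        errs = []
        for i in range(3):
            tree = synth.simulate_bd_tree(1.0, 0.3, n_tips=150, seed=60 + i)
            tips = {lab: {"s"} for lab in tree.tip_labels}
            model = build_musse({"s": 1.0}, obs_states=("s",), n_tau=1,
                                ordered=False)
            fit = fit_sse(tree, tips, model, n_starts=2, seed=i, maxiter=200)
            lam, mu = lambda_mu_from_turnover(*fit.params)
            errs.append(abs(float(lam) - 1.0) / 1.0)
        assert np.median(errs) < 0.25

    def test_nested_model_never_beats_superset(self, yule50):
        tips = {lab: {PSEUDO_STATES[i % 3]}
                for i, lab in enumerate(yule50.tip_labels)}
        null = build_musse(SF1, n_tau=1, constrained_eps=True)
        full = build_musse(SF1, constrained_eps=True)
        f0 = fit_sse(yule50, tips, null, n_starts=1, seed=0, maxiter=60,
                     step_scale=0.2, ftol=1e-6)
        f1 = fit_sse(yule50, tips, full, n_starts=1, seed=0, maxiter=60,
                     step_scale=0.2, ftol=1e-6)
        assert f1.lnL >= f0.lnL - 0.05  # optimizer tolerance
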