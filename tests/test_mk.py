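import numpy as np
import pytest

from oracles import mk_loglik_enumerate, mk_marginals_enumerate
from traitdiv.coding import OBSERVED_CODES
from traitdiv.mk import (MkModelSpec, build_rate_matrix, fit_mk, marginal_asr,
                         mk_loglik)
from traitdiv.simulate import simulate_mk_traits, yule_tree
from traitdiv.tree import read_tree

SML = ("S", "M", "L")


class TestRateStructures:
    @pytest.mark.parametrize("model,constrained,k", [
        ("ER", False, 1),
        ("SYM", False, 3),
        ("ARD", False, 6),
        ("ARD", True, 4),
        ("SYM", True, 2),
    ])
    def test_free_parameter_counts(self, model, constrained, k):
        spec = build_rate_matrix(SML, model, constrained=constrained)
        assert spec.n_params == k

    def test_constrained_masks_extreme_cells(self):
        spec = build_rate_matrix(SML, "ARD", constrained=True)
        Q = spec.rate_matrix([0.1, 0.2, 0.3, 0.4])
        s, m, l = 0, 1, 2
        assert Q[s, l] == 0 and Q[l, s] == 0
        assert Q[s, m] > 0 and Q[l, m] > 0

    def test_rows_sum_to_zero(self):
        spec = build_rate_matrix("ABCD", "ARD")
        Q = spec.rate_matrix(np.arange(1, 13) / 10)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_constrained_needs_three_states(self):
        with pytest.raises(ValueError):
            build_rate_matrix("AB", "ARD", constrained=True)


class TestLikelihood:
    def test_zero_rates_uniform_root(self, tree3):
        spec = build_rate_matrix(SML, "ER", root="uniform")
        tips = {"A": "S", "B": "S", "C": "S"}
        assert mk_loglik(tree3, tips, spec, [0.0]) == pytest.approx(
            np.log(1.0 / 3.0))

    @pytest.mark.parametrize("model,constrained,rates", [
        ("ER", False, [0.3]),
        ("SYM", False, [0.2, 0.5, 0.05]),
        ("ARD", False, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]),
        ("ARD", True, [0.15, 0.25, 0.35, 0.45]),
    ])
    @pytest.mark.parametrize("root", ["fitzjohn", "uniform"])
    def test_matches_enumeration(self, tree4, model, constrained, rates, root):
        spec = build_rate_matrix(SML, model, constrained=constrained,
                                 root=root)
        tips = {"A": "S", "B": "M", "C": "L", "D": "M"}
        assert mk_loglik(tree4, tips, spec, rates) == pytest.approx(
            mk_loglik_enumerate(tree4, tips, spec, rates), abs=1e-8)

    def test_ambiguous_tip_matches_enumeration(self, tree3):
        spec = build_rate_matrix(SML, "ER")
        tips = {"A": "S", "B": None, "C": "L"}
        assert mk_loglik(tree3, tips, spec, [0.4]) == pytest.approx(
            mk_loglik_enumerate(tree3, tips, spec, [0.4]), abs=1e-8)

    def test_long_branch_limit_is_stationary(self):
        # as branches grow, tips become independent draws from pi
        t = read_tree("(A:10000.0,B:10000.0);")
        spec = build_rate_matrix(SML, "ARD", root="stationary")
        rates = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        pi = spec.stationary(rates)
        tips = {"A": "S", "B": "L"}
        expected = np.log(pi[0]) + np.log(pi[2])
        assert mk_loglik(t, tips, spec, rates) == pytest.approx(expected,
                                                                abs=1e-6)

    def test_negative_rate_rejected(self, tree3):
        spec = build_rate_matrix(SML, "ER")
        with pytest.raises(ValueError):
            mk_loglik(tree3, {"A": "S", "B": "S", "C": "S"}, spec, [-0.1])

    def test_missing_tip_rejected(self, tree3):
        spec = build_rate_matrix(SML, "ER")
        with pytest.raises(KeyError):
            mk_loglik(tree3, {"A": "S", "B": "S"}, spec, [0.1])


@pytest.fixture(scope="module")
def simulated():
    tree = yule_tree(64, rng=7)
    spec = build_rate_matrix(SML, "ARD", constrained=True)
    Q = spec.rate_matrix([0.8, 0.5, 0.6, 0.4]) / tree.depth.max()
    tips, _, _ = simulate_mk_traits(tree, Q, rng=8, labels=list(SML))
    return tree, tips


class TestFitting:

    def test_nested_models_order_loglik(self, simulated):
        tree, tips = simulated
        lls = {}
        for model in ("ER", "SYM", "ARD"):
            spec = build_rate_matrix(SML, model)
            lls[model] = fit_mk(tree, tips, spec, n_starts=3, seed=0).loglik
        assert lls["ARD"] >= lls["SYM"] - 1e-6
        assert lls["SYM"] >= lls["ER"] - 1e-6

    def test_constraint_never_improves_loglik(self, simulated):
        tree, tips = simulated
        free = fit_mk(tree, tips, build_rate_matrix(SML, "ARD"),
                      n_starts=3, seed=0)
        constr = fit_mk(tree, tips, build_rate_matrix(SML, "ARD",
                                                      constrained=True),
                        n_starts=3, seed=0)
        assert constr.loglik <= free.loglik + 1e-6

    def test_er_rate_recovery(self):
        # median relative error across replicates stays moderate
        errs = []
        for rep in range(12):
            tree = yule_tree(150, rng=100 + rep)
            true = 1.2 / tree.depth.max()
            spec = build_rate_matrix(SML, "ER")
            Q = spec.rate_matrix([true])
            tips, _, _ = simulate_mk_traits(tree, Q, rng=200 + rep,
                                            labels=list(SML))
            fit = fit_mk(tree, tips, spec, n_starts=2, seed=rep)
            errs.append(abs(fit.rates[0] - true) / true)
        assert np.median(errs) < 0.30

    def test_single_state_warns(self, tree3):
        spec = build_rate_matrix(SML, "ER")
        with pytest.warns(UserWarning):
            fit_mk(tree3, {"A": "S", "B": "S", "C": "S"}, spec, n_starts=1)


class TestMarginals:
    def test_identical_tips_low_rate(self):
        t = read_tree("(A:1.0,B:1.0);")
        spec = build_rate_matrix(SML, "ER")
        marg = marginal_asr(t, {"A": "S", "B": "S"}, spec, [1e-8])
        assert marg[t.root] == pytest.approx([1.0, 0.0, 0.0], abs=1e-6)

    def test_symmetric_split_on_star(self, star16):
        spec = build_rate_matrix(("A", "B"), "ER", root="uniform")
        tips = {lab: ("A" if i < 8 else "B")
                for i, lab in enumerate(star16.tip_labels)}
        marg = marginal_asr(star16, tips, spec, [0.3])
        assert marg[star16.root] == pytest.approx([0.5, 0.5], abs=1e-8)

    def test_matches_enumeration_posterior(self, tree3):
        spec = build_rate_matrix(SML, "ARD", constrained=True)
        rates = [0.3, 0.2, 0.4, 0.1]
        tips = {"A": "S", "B": "M", "C": "L"}
        internal, oracle = mk_marginals_enumerate(tree3, tips, spec, rates)
        marg = marginal_asr(tree3, tips, spec, rates)
        assert marg[internal] == pytest.approx(oracle, abs=1e-8)

    def test_invariant_to_compensated_rescaling(self, tree4):
        # multiplying Q by c and dividing branch lengths by c changes nothing
        from traitdiv.tree import TimeTree

        spec = build_rate_matrix(SML, "ARD", constrained=True)
        rates = np.array([0.3, 0.2, 0.4, 0.1])
        tips = {"A": "S", "B": "M", "C": "L", "D": "M"}
        a = marginal_asr(tree4, tips, spec, rates)
        c = 3.7
        shrunk = TimeTree(tree4.parent, tree4.brlen / c, tree4.labels,
                          tree4.n_tips)
        b = marginal_asr(shrunk, tips, spec, rates * c)
        assert a == pytest.approx(b, abs=1e-9)

    def test_rows_sum_to_one(self, tree4):
        spec = build_rate_matrix(SML, "SYM")
        marg = marginal_asr(tree4, {"A": "S", "B": "M", "C": "L", "D": "M"},
                            spec, [0.2, 0.3, 0.1])
        assert np.allclose(marg.sum(axis=1), 1.0, atol=1e-8)
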