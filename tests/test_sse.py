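import numpy as np
import pytest

from oracles import sse_loglik_rk4
from traitdiv.coding import OBSERVED_CODES
from traitdiv.mk import MkModelSpec, mk_loglik
from traitdiv.simulate import SimScenario, simulate_sse_tree
from traitdiv.sse import (SSEModelSpec, akaike_weights, build_model_set,
                          fit_sse, marginal_reconstruction_sse,
                          model_average_rates, observed_marginals,
                          rank_models, ranking_frame, sse_loglik)
from traitdiv.tree import read_tree


def single_state_spec(**kw):
    """All composites share one (tau, eps); no transitions."""
    return SSEModelSpec(name="single", description="", hidden=1,
                        tau_share=[0, 0, 0], eps_share=[0, 0, 0],
                        q_share=np.full((3, 3), -1), rho=[1.0, 1.0, 1.0], **kw)


@pytest.fixture(scope="module")
def models():
    return {m.name: m for m in build_model_set("size")}


class TestModelSet:

    def test_eight_models(self, models):
        assert len(models) == 8

    def test_dull_has_fewest_parameters(self, models):
        kmin = min(m.n_params for m in models.values())
        assert models['"Dull"'].n_params == kmin

    def test_relaxed_is_muhisse_plus_one(self, models):
        assert (models["MuHiSSE Relaxed"].n_params
                == models["MuHiSSE"].n_params + 1)

    def test_cid3_is_cid2_plus_two(self, models):
        assert models["CID3"].n_params == models["CID2"].n_params + 2

    def test_dull_shares_all_diversification(self, models):
        d = models['"Dull"']
        assert d.n_tau == 1 and d.n_eps == 1

    def test_cid_ties_diversification_to_hidden_only(self, models):
        cid = models["CID2"]
        tau = cid.tau_share
        # same hidden class -> same parameter, regardless of observed state
        assert len(set(tau[:3])) == 1 and len(set(tau[3:])) == 1
        assert tau[0] != tau[3]

    def test_large_absorbing_masks_all_large_exits(self, models):
        spec = models["Large Absorbing"]
        large = OBSERVED_CODES.index("10")
        inter = OBSERVED_CODES.index("11")
        for h in range(spec.hidden):
            assert spec.q_share[h * 3 + large, h * 3 + inter] == -1
        # but large composites can still switch hidden class
        assert spec.q_share[large, 3 + large] >= 0

    def test_constrained_mask_everywhere(self, models):
        for m in models.values():
            a = OBSERVED_CODES.index("01")
            b = OBSERVED_CODES.index("10")
            for h in range(m.hidden):
                assert m.q_share[h * 3 + a, h * 3 + b] == -1
                assert m.q_share[h * 3 + b, h * 3 + a] == -1

    def test_no_simultaneous_observed_hidden_jumps(self, models):
        m = models["MuHiSSE"]
        for i in range(m.n_states):
            for j in range(m.n_states):
                if m.q_share[i, j] >= 0:
                    same_obs = i % 3 == j % 3
                    same_hidden = i // 3 == j // 3
                    assert same_obs != same_hidden

    def test_turnover_identities(self, models):
        m = models["MuSSE"]
        theta = np.concatenate([[0.5, 0.7, 0.9], [0.2, 0.4, 0.6],
                                np.full(m.n_q, 0.05)])
        lam, mu, _ = m.rates(theta)
        assert lam + mu == pytest.approx([0.5, 0.7, 0.9], abs=1e-12)
        assert mu / lam == pytest.approx([0.2, 0.4, 0.6], abs=1e-12)

    def test_unknown_trait_rejected(self):
        with pytest.raises(ValueError):
            build_model_set("diet")


class TestLikelihoodOracles:
    def test_yule_closed_form(self):
        t5 = read_tree("((((A:1,B:1):1,C:2):1,D:3):1,E:4);")
        lam = 0.7
        spec = single_state_spec()
        tips = {lab: "11" for lab in t5.tip_labels}
        ll = sse_loglik(t5, tips, spec, np.array([lam, 1e-12]))
        closed = (5 - 2) * np.log(lam) - lam * t5.total_branch_length
        assert ll == pytest.approx(closed, abs=1e-6)

    def test_factorizes_when_diversification_state_independent(self, tree6):
        codes = {"A": "01", "B": "11", "C": "10", "D": "11", "E": "01",
                 "F": "10"}
        qsh = np.full((3, 3), -1)
        qsh[0, 2], qsh[2, 0], qsh[1, 2], qsh[2, 1] = 0, 1, 2, 3
        spec = SSEModelSpec(name="eq", description="", hidden=1,
                            tau_share=[0, 0, 0], eps_share=[0, 0, 0],
                            q_share=qsh, rho=[1, 1, 1])
        qv = np.array([0.11, 0.23, 0.07, 0.19])
        theta = np.concatenate([[0.5], [0.4], qv])
        ll = sse_loglik(tree6, codes, spec, theta)
        ll_bd = sse_loglik(tree6, {lab: "11" for lab in tree6.tip_labels},
                           single_state_spec(), np.array([0.5, 0.4]))
        share = np.full((3, 3), -1)
        share[0, 2], share[2, 0], share[1, 2], share[2, 1] = 0, 1, 2, 3
        mk = MkModelSpec(states=OBSERVED_CODES, share=share, root="fitzjohn")
        ll_mk = mk_loglik(tree6, codes, mk, qv)
        assert ll == pytest.approx(ll_bd + ll_mk, abs=1e-5)

    def test_two_tip_independent_integrator(self):
        t2 = read_tree("(A:1.3,B:1.3);")
        spec = next(m for m in build_model_set("ecotype")
                    if m.name == "MuHiSSE")
        rng = np.random.default_rng(7)
        theta = np.exp(rng.uniform(np.log(0.05), np.log(1.0),
                                   size=spec.n_params))
        ll = sse_loglik(t2, {"A": "01", "B": "11"}, spec, theta)
        oracle = sse_loglik_rk4(t2, {"A": "01", "B": "11"}, spec, theta,
                                step=1e-5)
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_extinction_free_process_has_zero_E(self):
        # mu = 0 and full sampling: extinction probability stays 0, so the
        # conditioned likelihood differs from the raw one by exactly log(lam)
        t = read_tree("((A:1,B:1):1,C:2);")
        spec = single_state_spec()
        tips = {lab: "11" for lab in t.tip_labels}
        lam = 0.5
        cond = sse_loglik(t, tips, spec, np.array([lam, 1e-12]))
        raw_spec = single_state_spec(condition_on_survival=False)
        raw = sse_loglik(t, tips, raw_spec, np.array([lam, 1e-12]))
        assert raw - cond == pytest.approx(np.log(lam), abs=1e-7)

    def test_extinction_probability_monotone_backward(self):
        # with mu > 0, E grows going rootward along a branch; with mu = 0
        # and full sampling it stays identically zero
        from traitdiv.sse._kernels import integrate_branch

        K = 3
        q = np.zeros((K, K))
        y0 = np.concatenate([np.zeros(K), np.ones(K)])
        lam = np.full(K, 0.4)
        for mu_val, cmp in ((0.15, np.greater), (0.0, np.equal)):
            mu = np.full(K, mu_val)
            prev = y0[:K]
            for t in (0.5, 1.0, 2.0, 4.0):
                y = integrate_branch(y0.copy(), t, lam, mu, q, q.sum(1),
                                     1e-8, 1e-10)
                assert np.all(cmp(y[:K], prev) | np.isclose(y[:K], prev,
                                                            atol=1e-12))
                assert cmp is np.equal or np.all(y[:K] > prev)
                prev = y[:K]

    def test_unobservable_code_rejected(self, tree4):
        spec = single_state_spec()
        with pytest.raises(ValueError, match="00"):
            sse_loglik(tree4, {"A": "00", "B": "11", "C": "11", "D": "11"},
                       spec, np.array([0.5, 0.1]))


@pytest.fixture(scope="module")
def musse_data():
    q = np.array([[0.0, 0.0, 0.06], [0.0, 0.0, 0.06], [0.06, 0.06, 0.0]])
    sc = SimScenario(tau=[0.12, 0.3, 0.2], eps=[0.2, 0.2, 0.2], q=q,
                     target_tips=150, state_labels=("01", "10", "11"))
    sim = simulate_sse_tree(sc, rng=31)
    return sim.tree, sim.tip_states


class TestFitting:

    def test_optimum_at_least_generating_params(self, musse_data):
        tree, tips = musse_data
        spec = next(m for m in build_model_set("size", rho=[1, 1, 1])
                    if m.name == "MuSSE")
        theta_true = np.concatenate([[0.12, 0.3, 0.2], [0.2, 0.2, 0.2],
                                     np.full(spec.n_q, 0.06)])
        fit = fit_sse(tree, tips, spec, n_starts=3, seed=0)
        assert fit.loglik >= sse_loglik(tree, tips, spec, theta_true) - 1e-3

    def test_seed_determinism(self, musse_data):
        tree, tips = musse_data
        spec = next(m for m in build_model_set("size", rho=[1, 1, 1])
                    if m.name == '"Dull"')
        a = fit_sse(tree, tips, spec, n_starts=2, seed=5)
        b = fit_sse(tree, tips, spec, n_starts=2, seed=5)
        assert a.loglik == b.loglik
        assert np.array_equal(a.theta, b.theta)


class TestRanking:
    def test_single_model(self):
        f = _fake_fit("only", 100.0)
        ranked = rank_models([f])
        assert ranked[0].weight == pytest.approx(1.0)
        assert ranked[0].delta_aic == 0.0

    def test_weights_sum_to_one_and_order(self):
        fits = [_fake_fit(f"m{i}", aic) for i, aic in
                enumerate([10.0, 12.0, 11.0, 30.0])]
        ranked = rank_models(fits)
        assert sum(f.weight for f in ranked) == pytest.approx(1.0, abs=1e-10)
        assert [f.name for f in ranked[:2]] == ["m0", "m2"]
        assert ranked[0].delta_aic == 0.0

    def test_invariant_to_loglik_shift(self):
        fits_a = [_fake_fit(f"m{i}", a) for i, a in enumerate([5.0, 9.0])]
        fits_b = [_fake_fit(f"m{i}", a + 1000.0)
                  for i, a in enumerate([5.0, 9.0])]
        wa = [f.weight for f in rank_models(fits_a)]
        wb = [f.weight for f in rank_models(fits_b)]
        assert wa == pytest.approx(wb, abs=1e-12)

    def test_frame_schema(self):
        ranked = rank_models([_fake_fit("a", 1.0), _fake_fit("b", 3.0)])
        df = ranking_frame(ranked)
        assert list(df.columns) == ["model", "description", "free_parameters",
                                    "lnL", "AIC", "AICc", "delta_AIC",
                                    "weight"]


def _fake_fit(name, aic, spec=None, theta=None):
    from traitdiv.sse.fit import ModelFitResult

    spec = spec or single_state_spec()
    theta = theta if theta is not None else np.array([0.5, 0.1])
    return ModelFitResult(name=name, description="", loglik=-aic / 2,
                          n_params=0, aic=aic, aicc=aic, theta=theta,
                          spec=spec, n_tips=10)


class TestReconstructionAndAveraging:
    def test_low_transition_rate_concentrates_root(self):
        t = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        qsh = np.full((3, 3), -1)
        qsh[0, 2], qsh[2, 0], qsh[1, 2], qsh[2, 1] = 0, 0, 0, 0
        spec = SSEModelSpec(name="m", description="", hidden=1,
                            tau_share=[0, 0, 0], eps_share=[0, 0, 0],
                            q_share=qsh, rho=[1, 1, 1])
        codes = {k: "11" for k in "ABCD"}
        marg = marginal_reconstruction_sse(t, codes, spec,
                                           np.array([0.5, 0.1, 1e-8]))
        assert marg[t.root, OBSERVED_CODES.index("11")] >= 0.99

    def test_marginals_normalised(self, tree4):
        spec = next(m for m in build_model_set("ecotype")
                    if m.name == "MuHiSSE")
        rng = np.random.default_rng(3)
        theta = np.exp(rng.uniform(np.log(0.05), np.log(0.8),
                                   size=spec.n_params))
        codes = {"A": "01", "B": "11", "C": "10", "D": "11"}
        marg = marginal_reconstruction_sse(tree4, codes, spec, theta)
        assert np.allclose(marg.sum(axis=1), 1.0, atol=1e-8)
        obs = observed_marginals(marg, spec.hidden)
        assert np.allclose(obs.sum(axis=1), 1.0, atol=1e-8)

    def test_single_model_average_is_identity(self, tree4):
        spec = single_state_spec()
        theta = np.array([0.5, 0.2])
        codes = {k: "11" for k in "ABCD"}
        fit = _fake_fit("m", 10.0, spec=spec, theta=theta)
        rank_models([fit])
        marg = marginal_reconstruction_sse(tree4, codes, spec, theta)
        df = model_average_rates([fit], {"m": marg})
        lam, mu, _ = spec.rates(theta)
        assert df["net_diversification"].to_numpy() == pytest.approx(
            np.full(tree4.n_nodes, lam[0] - mu[0]), abs=1e-9)

    def test_average_bounded_by_contributors(self, tree4):
        codes = {"A": "01", "B": "11", "C": "10", "D": "11"}
        specs = [m for m in build_model_set("size", rho=[1, 1, 1])
                 if m.name in ('"Dull"', "MuSSE")]
        fits = [fit_sse(tree4, codes, s, n_starts=2, seed=i)
                for i, s in enumerate(specs)]
        ranked = rank_models(fits)
        recons = {f.name: marginal_reconstruction_sse(tree4, codes, f.spec,
                                                      f.theta)
                  for f in ranked}
        df = model_average_rates(ranked, recons)
        per_model = []
        for f in ranked:
            lam, mu, _ = f.spec.rates(f.theta)
            nd = recons[f.name] @ (lam - mu)
            per_model.append(nd)
        lo = np.minimum(*per_model) - 1e-9
        hi = np.maximum(*per_model) + 1e-9
        avg = df["net_diversification"].to_numpy()
        assert np.all(avg >= lo) and np.all(avg <= hi)

    def test_missing_reconstruction_for_heavy_model_errors(self):
        fits = rank_models([_fake_fit("a", 1.0), _fake_fit("b", 1.5)])
        marg = np.full((3, 3), 1 / 3)
        with pytest.raises(ValueError, match="no reconstruction"):
            model_average_rates(fits, {"a": marg})


class TestAkaikeWeights:
    def test_delta_and_normalisation(self):
        delta, w = akaike_weights([100.0, 102.0, 110.0])
        assert delta == pytest.approx([0.0, 2.0, 10.0])
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
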