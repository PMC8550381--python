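import json

import numpy as np
import pytest

from traitdiv.simulate import (ScenarioError, SimScenario, make_fixture_suite,
                               shared_path_matrix, simulate_continuous_traits,
                               simulate_mk_traits, simulate_sse_tree,
                               simulate_trait_table, yule_tree)
from traitdiv.tree import check_ultrametric


class TestYule:
    def test_exact_tip_count_and_ultrametric(self):
        t = yule_tree(50, rng=0)
        assert t.n_tips == 50
        assert check_ultrametric(t)[0]

    def test_seed_reproducibility(self):
        assert yule_tree(20, rng=5).to_newick() == yule_tree(20, rng=5).to_newick()


class TestSSESimulator:
    def test_pure_birth_expected_tip_count(self):
        lam, t_stop = 1.0, 1.2
        counts = []
        rng = np.random.default_rng(1)
        for _ in range(400):
            sc = SimScenario(tau=[lam], eps=[0.0], q=None, t_stop=t_stop)
            try:
                sim = simulate_sse_tree(sc, rng=rng)
                counts.append(sim.tree.n_tips + sim.n_unsampled)
            except ScenarioError:
                pass
        expected = 2 * np.exp(lam * t_stop)
        assert np.mean(counts) == pytest.approx(expected, rel=0.1)

    def test_no_speciation_rejected(self):
        sc = SimScenario(tau=[0.0], eps=[0.0], q=None, target_tips=10,
                         max_tries=5)
        with pytest.raises(ScenarioError):
            simulate_sse_tree(sc, rng=0)

    def test_symmetric_states_near_uniform(self):
        q = np.full((3, 3), 0.5)
        freqs = np.zeros(3)
        rng = np.random.default_rng(2)
        for _ in range(300):
            sc = SimScenario(tau=[1.0] * 3, eps=[0.1] * 3, q=q,
                             target_tips=20, tip_window=0.5)
            sim = simulate_sse_tree(sc, rng=rng)
            for s in sim.tip_states.values():
                freqs[int(s[1])] += 1
        freqs /= freqs.sum()
        assert np.all(np.abs(freqs - 1 / 3) < 0.05)

    def test_transition_counts_match_rate_expectation(self):
        q = np.array([[0.0, 0.25, 0.1], [0.2, 0.0, 0.15], [0.1, 0.3, 0.0]])
        tot_counts = np.zeros((3, 3))
        exp_counts = np.zeros((3, 3))
        rng = np.random.default_rng(3)
        for _ in range(400):
            sc = SimScenario(tau=[1.0] * 3, eps=[0.2] * 3, q=q,
                             target_tips=25, tip_window=0.6)
            sim = simulate_sse_tree(sc, rng=rng)
            tot_counts += sim.transition_counts
            exp_counts += q * sim.state_times[:, None]
        np.fill_diagonal(exp_counts, 0)
        ratio = tot_counts.sum() / exp_counts.sum()
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_sampling_fraction_thins_tips(self):
        rng = np.random.default_rng(4)
        kept, unsampled = 0, 0
        for _ in range(50):
            sc = SimScenario(tau=[1.0], eps=[0.0], q=None, t_stop=2.0,
                             rho=[0.5])
            try:
                sim = simulate_sse_tree(sc, rng=rng)
            except ScenarioError:
                continue
            kept += sim.tree.n_tips
            unsampled += sim.n_unsampled
        frac = kept / (kept + unsampled)
        assert frac == pytest.approx(0.5, abs=0.1)


class TestMkTraits:
    def test_zero_rate_all_root_state(self, yule64):
        Q = np.zeros((3, 3))
        tips, nodes, counts = simulate_mk_traits(yule64, Q, rng=0,
                                                 root_state=1)
        assert set(tips.values()) == {"1"}
        assert counts.sum() == 0

    def test_two_state_disagreement_probability(self):
        # single branch of length t: P(tip != root) = (1 - e^{-2rt}) / 2
        from traitdiv.tree import read_tree
        r, t = 0.4, 1.0
        tree = read_tree(f"(A:{t},B:{t});")
        Q = np.array([[-r, r], [r, -r]])
        rng = np.random.default_rng(6)
        dis = 0
        n = 4000
        for _ in range(n):
            tips, nodes, _ = simulate_mk_traits(tree, Q, rng=rng, root_state=0)
            dis += tips["A"] != "0"
        assert dis / n == pytest.approx((1 - np.exp(-2 * r * t)) / 2,
                                        abs=0.02)

    def test_masked_transitions_never_occur(self, yule64):
        Q = np.array([[-0.5, 0.5, 0.0], [0.3, -0.6, 0.3], [0.0, 0.5, -0.5]])
        _, _, counts = simulate_mk_traits(yule64, Q, rng=7)
        assert counts[0, 2] == 0 and counts[2, 0] == 0


class TestContinuousTraits:
    def test_bm_sample_covariance_converges(self):
        t = yule_tree(24, rng=8)
        C = shared_path_matrix(t)
        xs = simulate_continuous_traits(t, 1.7, 1.0, rng=9, size=2000)
        S = np.cov(xs.T)
        # remove the phylogenetic-mean offset sensitivity by comparing scale
        err = np.linalg.norm(S - 1.7 * C) / np.linalg.norm(1.7 * C)
        assert err < 0.10

    def test_lambda_zero_uncorrelated(self):
        t = yule_tree(24, rng=10)
        xs = simulate_continuous_traits(t, 1.0, 0.0, rng=11, size=2000)
        R = np.corrcoef(xs.T)
        off = R[~np.eye(24, dtype=bool)]
        assert np.abs(off).mean() < 0.05

    def test_seed_reproducibility(self, yule64):
        a = simulate_continuous_traits(yule64, 1.0, 0.5, rng=12)
        b = simulate_continuous_traits(yule64, 1.0, 0.5, rng=12)
        assert np.array_equal(a, b)


class TestTraitTable:
    def test_complete_and_valid(self, yule64):
        tt = simulate_trait_table(yule64, rng=13)
        assert tt.species == yule64.tip_labels
        assert (tt.data["total_length_cm"] > 0).all()
        assert tt.data["ecotype"].isin(
            ["benthic", "pelagic", "intermediate"]).all()


class TestFixtureSuite:
    def test_regeneration_is_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        make_fixture_suite(a, seed=99)
        make_fixture_suite(b, seed=99)
        for fa in sorted(a.iterdir()):
            assert (b / fa.name).read_bytes() == fa.read_bytes()

    def test_manifest_lists_every_file(self, tmp_path):
        manifest = make_fixture_suite(tmp_path, seed=99)
        files = {p.name for p in tmp_path.iterdir()} - {"manifest.json"}
        assert files == set(manifest["files"])
        on_disk = json.loads((tmp_path / "manifest.json").read_text())
        assert set(on_disk["files"]) == files

    def test_state_counts_self_consistent(self, tmp_path):
        manifest = make_fixture_suite(tmp_path, seed=99)
        recorded = manifest["files"]["sse300_states.csv"]["tip_state_counts"]
        lines = (tmp_path / "sse300_states.csv").read_text().strip().split("\n")
        from collections import Counter
        actual = Counter(line.split(",")[1] for line in lines[1:])
        assert dict(actual) == recorded
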