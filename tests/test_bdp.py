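"""Birth-death kernel, pruning likelihood, Viterbi reconstruction and
fast-family statistics, checked against independent oracles (closed forms,
exhaustive enumeration, Gillespie forward simulation)."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lignevo import bdp, synth
from lignevo.coreio import read_newick


def enumerate_loglik(tree, obs, model):
    """Brute-force likelihood: sum over every internal-state assignment."""
    Ps = {i: bdp.transition_matrix(model.lam, float(tree.blen[i]), model.n_max)
          for i in range(1, tree.n_nodes)}
    internals = tree.internal_indices
    tot = 0.0
    for assign in itertools.product(range(model.n_max + 1),
                                    repeat=len(internals)):
        st = dict(zip(internals, assign))
        for name, c in obs.items():
            st[tree.index_of(name)] = c
        p = model.root_prior[st[0]]
        for i in range(1, tree.n_nodes):
            p *= Ps[i][st[tree.parent[i]], st[i]]
        tot += p
    return np.log(tot)


def enumerate_viterbi(tree, obs, model):
    """Brute-force max-product assignment probability."""
    Ps = {i: bdp.transition_matrix(model.lam, float(tree.blen[i]), model.n_max)
          for i in range(1, tree.n_nodes)}
    internals = tree.internal_indices
    best = -np.inf
    for assign in itertools.product(range(model.n_max + 1),
                                    repeat=len(internals)):
        st = dict(zip(internals, assign))
        for name, c in obs.items():
            st[tree.index_of(name)] = c
        p = model.root_prior[st[0]]
        for i in range(1, tree.n_nodes):
            p *= Ps[i][st[tree.parent[i]], st[i]]
        best = max(best, p)
    return np.log(best)


def gillespie_tip_freqs(s0, lam, t, n_draws, seed, support):
    """Forward-simulate the continuous-time linear birth-death process."""
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(support))
    for _ in range(n_draws):
        n, clock = s0, 0.0
        while n > 0:
            clock += rng.exponential(1.0 / (2 * lam * n))
            if clock >= t:
                break
            n = n + 1 if rng.random() < 0.5 else n - 1
        if n < len(support):
            counts[n] += 1
    return counts / n_draws


class TestTransitionKernel:
    def test_zero_time_identity(self):
        assert bdp.transition_prob(3, 3, 0.0, 0.5) == 1.0
        assert bdp.transition_prob(3, 2, 0.0, 0.5) == 0.0

    def test_closed_forms(self):
        # alpha = lam*t/(1+lam*t) = 1/3
        assert bdp.transition_prob(1, 1, 1.0, 0.5) == pytest.approx((2 / 3) ** 2)
        assert bdp.transition_prob(1, 0, 1.0, 0.5) == pytest.approx(1 / 3)

    def test_zero_is_absorbing(self):
        P = bdp.transition_matrix(0.7, 2.0, 8)
        assert P[0, 0] == 1.0
        assert P[0, 1:].sum() == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            bdp.transition_prob(-1, 0, 1.0, 0.5)
        with pytest.raises(ValueError):
            bdp.transition_matrix(-0.1, 1.0, 5)

    @pytest.mark.parametrize("lam,t", [(0.1, 1.0), (0.5, 1.0), (0.25, 4.0)])
    def test_row_stochastic_within_truncation(self, lam, t):
        """Rows never exceed 1; truncation loss is tiny for counts far
        below the cap and stays bounded up to n_max/2 at lam*t <= 1."""
        n_max = 20
        P = bdp.transition_matrix(lam, t, n_max)
        sums = P[: n_max // 2 + 1].sum(axis=1)
        assert np.all(sums <= 1 + 1e-12)
        assert np.all(sums[: n_max // 5] >= 1 - 1e-3)
        assert np.all(sums >= 1 - 0.05)
        # loss grows monotonically with the parent count
        assert np.all(np.diff(sums) <= 1e-12)

    @pytest.mark.parametrize("s,lam,t", [(1, 0.5, 1.0), (3, 0.3, 1.5)])
    def test_matches_gillespie_forward_simulation(self, s, lam, t):
        """Analytic kernel vs 1e5 draws of the exact jump process, 3 SE."""
        n_draws = 100_000
        support = np.arange(25)
        freq = gillespie_tip_freqs(s, lam, t, n_draws, seed=17 + s, support=support)
        P = bdp.transition_matrix(lam, t, len(support) - 1)
        for c in range(12):
            se = np.sqrt(max(P[s, c] * (1 - P[s, c]), 1e-12) / n_draws)
            assert abs(freq[c] - P[s, c]) <= 3 * se + 1e-9, (c, freq[c], P[s, c])


class TestPruning:
    def test_frozen_process(self, balanced_tree):
        prior = np.zeros(6)
        prior[4] = 1.0
        model = bdp.BDPModel(lam=0.0, n_max=5, root_prior=prior)
        obs = {"A": 4, "B": 4, "C": 4, "D": 4}
        assert bdp.family_loglik(balanced_tree, obs, model) == pytest.approx(0.0)
        obs2 = {"A": 4, "B": 4, "C": 4, "D": 3}
        assert bdp.family_loglik(balanced_tree, obs2, model) == -np.inf

    @pytest.mark.parametrize("newick,obs", [
        ("((A:1,B:1):1,(C:1.5,D:0.5):0.5):0;", {"A": 2, "B": 1, "C": 0, "D": 3}),
        ("(((A:0.5,B:0.5):1,C:2):1,(D:1,E:1):2):0;",
         {"A": 1, "B": 2, "C": 2, "D": 5, "E": 0}),
        ("((A:2,B:0.3):0.7,C:1):0;", {"A": 0, "B": 4, "C": 2}),
    ])
    def test_equals_enumeration(self, newick, obs):
        tree = read_newick(newick)
        model = bdp.BDPModel(lam=0.35, n_max=5)
        ll = bdp.family_loglik(tree, obs, model)
        assert ll == pytest.approx(enumerate_loglik(tree, obs, model), abs=1e-10)

    def test_tip_absent_rejected(self, balanced_tree):
        model = bdp.BDPModel(lam=0.1, n_max=5)
        with pytest.raises(KeyError):
            bdp.family_loglik(balanced_tree, {"A": 1, "B": 1, "C": 1}, model)


class TestAncestralCounts:
    def test_consensus_with_small_rate(self, balanced_tree):
        model = bdp.BDPModel(lam=0.001, n_max=10)
        anc = bdp.ancestral_counts(balanced_tree,
                                   {"A": 4, "B": 4, "C": 4, "D": 4}, model)
        assert (anc == 4).all()

    @pytest.mark.parametrize("obs", [
        {"A": 2, "B": 1, "C": 0, "D": 3},
        {"A": 5, "B": 5, "C": 1, "D": 0},
    ])
    def test_matches_enumeration(self, small_tree, obs):
        model = bdp.BDPModel(lam=0.4, n_max=5)
        _, lp = bdp.ancestral_counts(small_tree, obs, model,
                                     return_logprob=True)
        assert lp == pytest.approx(enumerate_viterbi(small_tree, obs, model),
                                   abs=1e-10)

    def test_recovery_on_forward_simulation(self):
        """Most internal states exactly recovered at the generating rate."""
        tree = synth.simulate_tree(52, 192.0, seed=97)
        model = bdp.BDPModel(lam=0.002, n_max=12)
        rng = np.random.default_rng(98)
        states = bdp.simulate_families(tree, model, 200, rng)
        hit = tot = 0
        internal = tree.internal_indices
        for f in range(200):
            obs = dict(zip(tree.tip_names, states[f, tree.tip_indices]))
            anc = bdp.ancestral_counts(tree, obs, model)
            for i in internal:
                tot += 1
                hit += int(anc.iloc[i] == states[f, i])
        assert hit / tot >= 0.70


class TestLambdaEstimation:
    def test_constant_families_drive_lambda_to_floor(self, yule_tree_20):
        counts = pd.DataFrame(
            {f"f{j}": np.full(20, 3) for j in range(5)},
            index=yule_tree_20.tip_names)
        lam, _ = bdp.estimate_lambda(yule_tree_20, counts)
        assert lam <= 1e-5

    def test_all_zero_matrix_rejected(self, yule_tree_20):
        counts = pd.DataFrame({"f": np.zeros(20, int)},
                              index=yule_tree_20.tip_names)
        with pytest.raises(ValueError, match="zero"):
            bdp.estimate_lambda(yule_tree_20, counts)

    def test_parameter_recovery_and_optimality(self):
        tree = synth.simulate_tree(52, 192.0, seed=11)
        model = bdp.BDPModel(lam=0.002, n_max=16)
        rng = np.random.default_rng(12)
        states = bdp.simulate_families(tree, model, 300, rng)
        counts = pd.DataFrame(states[:, tree.tip_indices].T,
                              index=tree.tip_names,
                              columns=[f"f{j}" for j in range(300)])
        lam, ll = bdp.estimate_lambda(tree, counts)
        assert abs(lam - 0.002) / 0.002 <= 0.25
        for other in (lam * 0.9, lam * 1.1):
            ll_other = sum(
                bdp.loglik_many(tree, block,
                                bdp.BDPModel(lam=other, n_max=nm)).sum()
                for _, block, nm in bdp._grouped_counts(tree, counts))
            assert ll >= ll_other - 1e-6


class TestFamilywidePvalue:
    def test_add_one_bound(self, yule_tree_20):
        model = bdp.BDPModel(lam=0.01, n_max=10)
        obs = dict(zip(yule_tree_20.tip_names, [2] * 20))
        p = bdp.familywide_pvalue(yule_tree_20, obs, model, n_sim=50, seed=3)
        assert 0 < p <= 1

    def test_zero_sims_rejected(self, yule_tree_20):
        model = bdp.BDPModel(lam=0.01, n_max=10)
        with pytest.raises(ValueError):
            bdp.null_loglik_sample(yule_tree_20, model, 0, seed=1)

    def test_null_pvalues_uniform(self):
        """p of null draws ~ U(0,1): KS test across 200 null families."""
        from scipy import stats
        tree = synth.simulate_tree(52, 192.0, seed=21)
        model = bdp.BDPModel(lam=0.002, n_max=20)
        rng = np.random.default_rng(31)
        sims = bdp.simulate_families(tree, model, 200, rng)[:, tree.tip_indices]
        null_ll = bdp.null_loglik_sample(tree, model, 1000, seed=32)
        obs_ll = bdp.loglik_many(tree, sims, model)
        pvals = [(1 + np.sum(null_ll <= o + 1e-12)) / (len(null_ll) + 1)
                 for o in obs_ll]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_extreme_expansion_detected(self):
        """A 1 -> 30 expansion on one short terminal branch is significant."""
        tree = synth.simulate_tree(20, 100.0, seed=41)
        obs = {t: 1 for t in tree.tip_names}
        # shortest terminal branch gets the jump
        term = min((i for i in tree.tip_indices), key=lambda i: tree.blen[i])
        obs[tree.names[term]] = 30
        model = bdp.BDPModel(lam=0.001, n_max=60)
        p = bdp.familywide_pvalue(tree, obs, model, n_sim=1000, seed=42)
        assert p < 0.01


class TestViterbiBranchPvalues:
    def test_modal_transition_p_one(self, balanced_tree):
        model = bdp.BDPModel(lam=1e-5, n_max=8)
        table = bdp.viterbi_branch_pvalues(
            balanced_tree, {"A": 3, "B": 3, "C": 3, "D": 3}, model)
        assert np.allclose(table["viterbi_p"], 1.0)
        assert (table["direction"] == "none").all()

    def test_tail_matches_hand_enumeration(self):
        """s*=1, c*=0, alpha=1/3: sum of probabilities <= P(1->0)=1/3."""
        tree = read_newick("(A:1,B:1):0;")
        model = bdp.BDPModel(lam=0.5, n_max=6)
        table = bdp.viterbi_branch_pvalues(tree, {"A": 0, "B": 1}, model)
        row_a = table[table.child == "A"].iloc[0]
        assert (row_a.parent_count, row_a.child_count) == (1, 0)
        P = bdp.transition_matrix(0.5, 1.0, 6)
        expected = P[1][P[1] <= P[1, 0] + 1e-15].sum()
        assert row_a.viterbi_p == pytest.approx(expected, abs=1e-12)

    def test_pvalues_in_unit_interval(self, small_tree):
        model = bdp.BDPModel(lam=0.3, n_max=8)
        table = bdp.viterbi_branch_pvalues(
            small_tree, {"A": 2, "B": 1, "C": 0, "D": 3}, model)
        assert ((table["viterbi_p"] > 0) & (table["viterbi_p"] <= 1)).all()


class TestFastFamilyClassification:
    def test_thresholding(self):
        p = pd.Series({"a": 0.5, "b": 0.5})
        assert bdp.classify_fast_families(p) == []
        p = pd.Series({"a": 0.005, "b": 0.02})
        assert bdp.classify_fast_families(p, alpha=0.01) == ["a"]

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bdp.classify_fast_families(pd.Series({"a": 1.5}))
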