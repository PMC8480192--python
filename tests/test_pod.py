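"""POD typing rules, marginal ancestral reconstruction, and type-origin
dating, with an enumeration oracle for the pruning posteriors."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lignevo import pod, synth
from lignevo.coreio import Msa, SiteMap, read_newick
from lignevo.substmodels import SubstModel, get_model


def profile(distal=("H", "R"), mn=("E", "E", "D"), trp="F", tyr="F",
            tail=10, prox="H"):
    return pod.PodSiteProfile(
        distal_his=distal[0], distal_arg=distal[1], proximal_his=prox,
        mn_site_1=mn[0], mn_site_2=mn[1], mn_site_3=mn[2],
        trp_lip=trp, tyr_tc=tyr, c_tail_length=tail)


class TestClassifyPod:
    """The eight exemplar assignments plus rule edges."""

    @pytest.mark.parametrize("prof,expected", [
        (profile(mn=("A", "A", "N"), trp="W"), "LiP"),
        (profile(mn=("E", "E", "D"), trp="F", tail=25), "MnP-l"),
        (profile(mn=("E", "E", "D"), trp="F", tail=8), "MnP-s"),
        (profile(mn=("E", "E", "D"), trp="W"), "VP"),
        (profile(mn=("K", "A", "N"), trp="F"), "GP"),
        (profile(mn=("E", "S", "D"), trp="F"), "MnP-ESD"),
        (profile(mn=("D", "G", "D"), trp="F"), "MnP-DGD"),
        (profile(mn=("D", "E", "D"), trp="F"), "MnP-DED"),
        (profile(distal=("H", "H"), mn=("E", "A", "Y"), tyr="Y"), "NPOD"),
    ])
    def test_exemplar_assignments(self, prof, expected):
        assert pod.classify_pod(prof) == expected

    def test_partial_mn_site_with_trp_is_vpa(self):
        assert pod.classify_pod(profile(mn=("E", "S", "D"), trp="W")) == "VP-a"
        assert pod.classify_pod(profile(mn=("D", "G", "D"), trp="W")) == "VP-a"

    def test_unexpected_distal_pair_unclassified(self):
        assert pod.classify_pod(profile(distal=("Q", "R"))) == "unclassified"
        assert pod.classify_pod(profile(distal=("H", "-"))) == "unclassified"

    def test_tail_threshold_boundary(self):
        assert pod.classify_pod(profile(tail=16), tail_threshold=16) == "MnP-l"
        assert pod.classify_pod(profile(tail=15), tail_threshold=16) == "MnP-s"

    def test_total_and_nondecisive_invariance(self):
        """Every profile maps to exactly one type; the proximal His and
        surface-Tyr columns never change a non-NPOD call."""
        residues = ["H", "R", "E", "D", "W", "A", "-"]
        for distal in itertools.product(residues[:4], repeat=2):
            for trp in ("W", "F"):
                p1 = profile(distal=distal, trp=trp, prox="H", tyr="F")
                p2 = profile(distal=distal, trp=trp, prox="A", tyr="Y")
                t1, t2 = pod.classify_pod(p1), pod.classify_pod(p2)
                assert t1 in pod.POD_TYPES
                assert t1 == t2


class TestExtractProfile:
    def test_reads_mapped_columns_and_tail(self):
        #       123456789012345678
        row = "AHXRQEHEDWAYFFKKK-KK"
        sm = SiteMap(distal_his=2, distal_arg=4, proximal_his=7,
                     mn_site_1=6, mn_site_2=8, mn_site_3=9, trp_lip=10,
                     tyr_tc=12, tail_anchor=14)
        msa = Msa(ids=["s1"], rows=[row])
        prof = pod.extract_profile(msa, sm, "s1")
        assert (prof.distal_his, prof.distal_arg) == ("H", "R")
        assert prof.mn_triad == ("E", "E", "D")
        assert prof.trp_lip == "W" and prof.tyr_tc == "Y"
        assert prof.c_tail_length == 5  # six columns after 14, one gap

    def test_gap_at_catalytic_column_not_error(self):
        row = "A-AR-EHEDW" + "A" * 10
        sm = SiteMap(distal_his=2, distal_arg=4, proximal_his=7,
                     mn_site_1=6, mn_site_2=8, mn_site_3=9, trp_lip=10,
                     tyr_tc=12, tail_anchor=14)
        prof = pod.extract_profile(Msa(ids=["s"], rows=[row]), sm, "s")
        assert prof.distal_his == "-"

    def test_missing_sequence_rejected(self):
        sm = synth.default_site_map(90)
        msa = Msa(ids=["a"], rows=["A" * 90])
        with pytest.raises(KeyError):
            pod.extract_profile(msa, sm, "zzz")


def enumeration_posterior(tree, tip_states, model: SubstModel, node):
    """Brute-force marginal posterior at one node over all assignments."""
    n = len(model.pi)
    Ps = {i: model.transition(float(tree.blen[i]))
          for i in range(1, tree.n_nodes)}
    internals = tree.internal_indices
    post = np.zeros(n)
    for assign in itertools.product(range(n), repeat=len(internals)):
        st = dict(zip(internals, assign))
        st.update(tip_states)
        p = model.pi[st[0]]
        for i in range(1, tree.n_nodes):
            p *= Ps[i][st[tree.parent[i]], st[i]]
        post[st[node]] += p
    return post / post.sum()


class TestMarginalAsr:
    def test_consensus_pull_on_cherry(self):
        t = read_newick("(a:0.05,b:0.05)r:0;", unit="subs")
        msa = Msa(ids=["a", "b"], rows=["H", "H"])
        out = pod.marginal_asr(t, msa, [1], model="WAG")
        model = get_model("WAG")
        h = model.alphabet.index("H")
        assert out[1].loc["r"].idxmax() == "H"
        assert out[1].loc["r", "H"] > model.pi[h]
        assert out[1].loc["r"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_saturation_limit_returns_stationary(self):
        t = read_newick("(a:80.0,b:80.0)r:0;", unit="subs")
        msa = Msa(ids=["a", "b"], rows=["H", "W"])
        out = pod.marginal_asr(t, msa, [1], model="WAG")
        model = get_model("WAG")
        assert np.allclose(out[1].loc["r"].to_numpy(), model.pi, atol=1e-4)

    def test_matches_enumeration_on_restricted_alphabet(self):
        """3-tip tree, 4-state model: posteriors equal exhaustive
        enumeration at every internal node to 1e-10."""
        t = read_newick("((a:0.3,b:0.6)u:0.4,c:0.9)r:0;", unit="subs")
        S = np.array([[0, 1.0, 2.0, 0.5], [1.0, 0, 0.7, 1.2],
                      [2.0, 0.7, 0, 0.9], [0.5, 1.2, 0.9, 0]])
        model = SubstModel(S, np.array([0.4, 0.3, 0.2, 0.1]), name="toy4")
        msa = Msa(ids=["a", "b", "c"],
                  rows=[model.alphabet[0], model.alphabet[2],
                        model.alphabet[1]])
        out = pod.marginal_asr(t, msa, [1], model=model)
        tip_states = {t.index_of("a"): 0, t.index_of("b"): 2,
                      t.index_of("c"): 1}
        for node_name in ("r", "u"):
            i = t.index_of(node_name)
            expected = enumeration_posterior(t, tip_states, model, i)
            assert np.allclose(out[1].loc[node_name].to_numpy(), expected,
                               atol=1e-10)

    def test_gap_treated_as_missing(self):
        t = read_newick("((a:0.1,b:0.1)u:0.1,c:0.1)r:0;", unit="subs")
        msa = Msa(ids=["a", "b", "c"], rows=["H", "H", "-"])
        out = pod.marginal_asr(t, msa, [1], model="WAG")
        assert out[1].loc["r"].idxmax() == "H"

    def test_tip_order_invariance(self):
        t1 = read_newick("((a:0.2,b:0.3)u:0.1,c:0.4)r:0;", unit="subs")
        t2 = read_newick("(c:0.4,(b:0.3,a:0.2)u:0.1)r:0;", unit="subs")
        msa = Msa(ids=["a", "b", "c"], rows=["H", "R", "H"])
        p1 = pod.marginal_asr(t1, msa, [1])[1].loc["r"]
        p2 = pod.marginal_asr(t2, msa, [1])[1].loc["r"]
        assert np.allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-12)


class TestClassifyAncestors:
    def _vp_cherry(self):
        t = read_newick("(a:0.05,b:0.05)r:0;", unit="subs")
        types = {"a": "VP", "b": "VP"}
        msa, sm = synth.simulate_pod_alignment(t, types, seed=3)
        return t, msa, sm

    def test_cherry_ancestor_recovers_tip_type(self):
        t, msa, sm = self._vp_cherry()
        cols = [c for k, c in sm.columns().items() if k != "tail_anchor"]
        asr = pod.marginal_asr(t, msa, cols)
        tails = pd.Series({s: pod.extract_profile(msa, sm, s).c_tail_length
                           for s in msa.ids})
        anc = pod.classify_ancestors(asr, sm, tree=t, tip_tail_lengths=tails)
        assert anc.loc["r", "pod_type"] == "VP"

    def test_fixed_tail_policy(self):
        t, msa, sm = self._vp_cherry()
        cols = [c for k, c in sm.columns().items() if k != "tail_anchor"]
        asr = pod.marginal_asr(t, msa, cols)
        anc = pod.classify_ancestors(asr, sm, tail_policy=30)
        assert (anc["tail_length"] == 30).all()

    def test_ambiguous_column_reports_runner_up(self):
        """Long branches leave a decisive column uncertain; the runner-up
        type must be reported."""
        t = read_newick("(a:3.0,b:3.0)r:0;", unit="subs")
        msa, sm = synth.simulate_pod_alignment(
            t, {"a": "VP", "b": "MnP-s"}, seed=4)
        cols = [c for k, c in sm.columns().items() if k != "tail_anchor"]
        asr = pod.marginal_asr(t, msa, cols)
        anc = pod.classify_ancestors(asr, sm, tail_policy=8)
        assert anc.loc["r", "min_decisive_prob"] < 0.7
        assert anc.loc["r", "runner_up"] != ""


class TestMapTypeOrigins:
    def test_single_type_origin_is_root(self, balanced_tree):
        types = pd.Series("MnP-s", index=balanced_tree.names)
        out = pod.map_type_origins(balanced_tree, types)
        assert len(out) == 1
        assert out.iloc[0].origin_node == "N0"
        assert out.iloc[0].parent_type == "none"
        assert out.iloc[0].age_My == pytest.approx(2.0)

    def test_single_transition_dated_at_child(self, balanced_tree):
        types = pd.Series("MnP-s", index=balanced_tree.names)
        # the A/B cherry ancestor (first internal after root) becomes VP
        cherry = balanced_tree.names[1]
        for n in ("A", "B", cherry):
            types[n] = "VP"
        out = pod.map_type_origins(balanced_tree, types)
        vp = out[out.pod_type == "VP"]
        assert len(vp) == 1
        assert vp.iloc[0].origin_node == cherry
        assert vp.iloc[0].age_My == pytest.approx(1.0)
        assert vp.iloc[0].parent_type == "MnP-s"

    def test_convergent_origins_all_reported(self):
        t = read_newick("((A:1,B:1)u:1,(C:1,D:1)v:1)r:0;")
        types = pd.Series("MnP-s", index=t.names)
        for n in ("A", "C"):
            types[n] = "MnP-ESD"
        out = pod.map_type_origins(t, types)
        esd = out[out.pod_type == "MnP-ESD"]
        assert sorted(esd.origin_node) == ["A", "C"]


class TestEndToEndSynthetic:
    def test_tip_classification_recovers_planted_types(self):
        """Every ungapped planted profile is recovered exactly."""
        rng = np.random.default_rng(6)
        tree = synth.simulate_tree(20, 1.0, seed=5, unit="subs")
        planted = {tip: rng.choice(list(synth.POD_TEMPLATES))
                   for tip in tree.tip_names}
        msa, sm = synth.simulate_pod_alignment(tree, planted, seed=7)
        for tip, expected in planted.items():
            prof = pod.extract_profile(msa, sm, tip)
            got = pod.classify_pod(prof)
            if expected == "MnP-l":
                assert got == "MnP-l" and prof.c_tail_length >= 16
            else:
                assert got == expected

    def test_uniform_tips_give_uniform_ancestors(self):
        tree = synth.simulate_tree(10, 0.5, seed=8, unit="subs")
        msa, sm = synth.simulate_pod_alignment(
            tree, {t: "MnP-s" for t in tree.tip_names}, seed=9)
        cols = [c for k, c in sm.columns().items() if k != "tail_anchor"]
        asr = pod.marginal_asr(tree, msa, cols)
        tails = pd.Series({s: pod.extract_profile(msa, sm, s).c_tail_length
                           for s in msa.ids})
        anc = pod.classify_ancestors(asr, sm, tree=tree,
                                     tip_tail_lengths=tails)
        assert (anc["pod_type"] == "MnP-s").all()
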