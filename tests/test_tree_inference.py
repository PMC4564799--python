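"""Neighbour joining, Fitch parsimony, heuristic search, bootstrap,
consensus and rooting."""

import itertools

import numpy as np
import pandas as pd
import pytest

import plastochron as pc
from plastochron.infer import SearchOptions
from conftest import random_alignment, random_metric_tree, tree_path_distances


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = pd.DataFrame([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]],
                          index=list("abc"), columns=list("abc"))
        tree = pc.neighbor_joining(dm)
        lengths = {n.label: n.length for n in tree.leaves()}
        assert lengths == pytest.approx(
            {"a": 0.05, "b": 0.15, "c": 0.25})

    @pytest.mark.parametrize("seed", range(6))
    def test_additive_matrix_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        true = random_metric_tree(rng, int(rng.integers(4, 11)))
        D = tree_path_distances(true)
        nj = pc.neighbor_joining(D)
        assert nj.same_topology(true)
        D2 = tree_path_distances(nj)
        assert np.allclose(D.to_numpy(),
                           D2.loc[D.index, D.columns].to_numpy(), atol=1e-9)

    def test_star_distances_give_zero_internal_edges(self):
        taxa = list("abcde")
        D = pd.DataFrame(1.0, index=taxa, columns=taxa)
        np.fill_diagonal(D.values, 0.0)
        tree = pc.neighbor_joining(D)
        for node in tree.postorder():
            if not node.is_leaf and node is not tree.root:
                assert node.length == pytest.approx(0.0, abs=1e-12)

    def test_too_few_taxa(self):
        D = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"],
                         columns=["a", "b"])
        with pytest.raises(ValueError):
            pc.neighbor_joining(D)

    def test_deterministic_under_ties(self):
        taxa = list("abcd")
        D = pd.DataFrame(2.0, index=taxa, columns=taxa)
        np.fill_diagonal(D.values, 0.0)
        t1 = pc.neighbor_joining(D)
        t2 = pc.neighbor_joining(D.copy())
        assert t1.to_newick() == t2.to_newick()


class TestFitch:
    def test_constant_alignment_zero(self):
        a = pc.Alignment(list("abcd"), ["AC"] * 4)
        t = pc.read_newick("((a,b),(c,d));")
        assert pc.fitch_length(t, a) == 0

    def test_hand_column(self):
        a = pc.Alignment(list("abcd"), ["A", "A", "G", "G"])
        assert pc.fitch_length(pc.read_newick("((a,b),(c,d));"), a) == 1
        assert pc.fitch_length(pc.read_newick("((a,c),(b,d));"), a) == 2

    def test_missing_contributes_full_state_set(self):
        a = pc.Alignment(list("abcd"), ["A", "-", "G", "G"])
        assert pc.fitch_length(pc.read_newick("((a,b),(c,d));"), a) == 1

    def test_rooting_and_taxon_order_invariance(self, rng):
        a = random_alignment(rng, 6, 30)
        tree = random_metric_tree(rng, 6)
        for n in tree.postorder():
            n.label = n.label and n.label.replace("x", "s")
        score = pc.fitch_length(tree, a)
        rerooted = tree.reroot_on_edge(tree.find_tip("s3"), 0.5)
        assert pc.fitch_length(rerooted, a) == score
        shuffled = a.subset_taxa(list(reversed(a.taxa)))
        assert pc.fitch_length(tree, shuffled) == score

    def test_brute_force_six_taxa(self, rng):
        """Search-free check: tree score equals enumeration minimum."""
        a = random_alignment(rng, 6, 15)
        scores = [pc.fitch_length(t, a)
                  for t in pc.enumerate_unrooted_topologies(a.taxa)]
        assert len(scores) == 105
        trees, best = pc.parsimony_search(
            a, SearchOptions(n_addition_replicates=5, seed=0))
        assert best == min(scores)


class TestParsimonySearch:
    def test_search_beats_or_equals_stepwise(self, tiny_alignment):
        none_opt = SearchOptions(n_addition_replicates=3, swap="none", seed=2)
        tbr_opt = SearchOptions(n_addition_replicates=3, swap="TBR", seed=2)
        _, s_none = pc.parsimony_search(tiny_alignment, none_opt)
        _, s_tbr = pc.parsimony_search(tiny_alignment, tbr_opt)
        assert s_tbr <= s_none

    def test_recovers_true_topology_high_signal(self, tiny_bundle):
        trees, _ = pc.parsimony_search(
            tiny_bundle.result.alignment,
            SearchOptions(n_addition_replicates=5, seed=3))
        assert any(t.same_topology(tiny_bundle.result.tree) for t in trees)

    def test_deterministic_given_seed(self, tiny_alignment):
        opt = SearchOptions(n_addition_replicates=3, seed=9)
        t1, s1 = pc.parsimony_search(tiny_alignment, opt)
        t2, s2 = pc.parsimony_search(tiny_alignment, opt)
        assert s1 == s2
        assert [t.topology_key() for t in t1] == [t.topology_key() for t in t2]


class TestNniMlSearch:
    def test_lnl_never_below_start(self, tiny_bundle):
        aln = tiny_bundle.result.alignment
        model = pc.SubstitutionModel.from_spec("HKY")
        start = pc.nj_tree(aln, pc.SubstitutionModel.from_spec("JC"))
        _, start_lnl = pc.optimize_branch_lengths(start, aln, model)
        tree, lnl = pc.nni_ml_search(aln, model, start)
        # within the coordinate optimizer's convergence tolerance
        assert lnl >= start_lnl - 1e-3

    def test_true_tree_is_local_optimum(self, tiny_bundle):
        aln = tiny_bundle.result.alignment
        model = pc.SubstitutionModel.from_spec("HKY")
        tree, _ = pc.nni_ml_search(aln, model, tiny_bundle.result.tree)
        assert tree.same_topology(tiny_bundle.result.tree)


class TestBootstrap:
    def test_supports_in_range_and_deterministic(self, tiny_alignment):
        t1, s1 = pc.bootstrap(tiny_alignment, "parsimony", n_replicates=20,
                              seed=4)
        t2, s2 = pc.bootstrap(tiny_alignment, "parsimony", n_replicates=20,
                              seed=4)
        assert s1["support"].between(0, 100).all()
        assert s1.equals(s2)
        t3, s3 = pc.bootstrap(tiny_alignment, "parsimony", n_replicates=20,
                              seed=5)
        assert not s1.equals(s3) or len(s1) == 0

    def test_zero_homoplasy_full_support(self):
        # perfectly clean signal: every split marked by many private columns
        rows = {
            "a": "AAAA" + "CCCC" + "AAAA" + "AAAA",
            "b": "AAAA" + "CCCC" + "CCCC" + "AAAA",
            "c": "CCCC" + "AAAA" + "AAAA" + "GGGG",
            "d": "CCCC" + "AAAA" + "AAAA" + "AAAA",
        }
        a = pc.Alignment(list(rows), list(rows.values()))
        tree, supports = pc.bootstrap(a, "parsimony", n_replicates=30, seed=0)
        assert (supports["support"] == 100.0).all()


class TestBootstrapTrend:
    def test_supports_grow_with_alignment_length(self):
        """True-clade bootstrap support rises (weakly) from 1 kb to 50 kb."""
        chron = pc.simulate_yule_chronogram(6, 1.0, seed=31)
        jc = pc.SubstitutionModel.from_spec("JC")
        clock = pc.ClockModel("strict", rate=0.003)
        mins = []
        for length in (1000, 10000, 50000):
            sim = pc.evolve_sequences(chron, clock, jc, length, seed=32)
            _, supports = pc.bootstrap(
                sim.alignment, "nj", n_replicates=30, seed=33, model=jc,
                point_tree=sim.tree.unroot())
            mins.append(supports["support"].min())
        assert mins[0] <= mins[1] <= mins[2]
        assert mins[2] == 100.0


class TestConsensusAndRooting:
    def test_identical_trees_consensus(self):
        trees = [pc.read_newick("((a,b),(c,d),e);") for _ in range(3)]
        cons = pc.majority_consensus(trees)
        assert cons.same_topology(trees[0])
        supports = [n.support for n in cons.postorder()
                    if not n.is_leaf and n is not cons.root]
        assert all(s == 100.0 for s in supports)

    def test_two_thirds_bipartition_kept(self):
        trees = [pc.read_newick("((a,b),(c,d),e);"),
                 pc.read_newick("((a,b),(c,e),d);"),
                 pc.read_newick("((a,e),(c,d),b);")]
        cons = pc.majority_consensus(trees, threshold=0.5)
        splits = cons.bipartitions()
        # ab appears 2/3, cd appears 2/3; ae and ce appear 1/3
        assert frozenset({"a", "b"}) not in splits  # normalized away from 'a'
        names = {tuple(sorted(s)) for s in splits}
        assert ("c", "d", "e") in names or ("c", "d") in names

    def test_rooting_round_trip(self, tiny_bundle):
        unrooted = tiny_bundle.result.tree.unroot()
        rooted = pc.root_with_outgroup(unrooted, "t1")
        assert len(rooted.root.children) == 2
        assert rooted.unroot().same_topology(unrooted)

    def test_missing_outgroup_errors(self, tiny_bundle):
        with pytest.raises(KeyError):
            pc.root_with_outgroup(tiny_bundle.result.tree, "nope")

    def test_outgroup_pendant_edge_split_in_half(self):
        tree = pc.read_newick("((a:1,b:1):0.5,c:2,(d:1,e:1):0.5);")
        rooted = pc.root_with_outgroup(tree, "c")
        c_child = [ch for ch in rooted.root.children if ch.label == "c"]
        assert len(c_child) == 1
        assert c_child[0].length == pytest.approx(1.0)


class TestCongruence:
    def test_nj_mp_ml_agree_on_clean_data(self, tiny_bundle):
        aln = tiny_bundle.result.alignment
        nj = pc.nj_tree(aln)
        mp, _ = pc.parsimony_search(
            aln, SearchOptions(n_addition_replicates=3, seed=1))
        ml, _ = pc.nni_ml_search(
            aln, pc.SubstitutionModel.from_spec("HKY"), nj)
        assert nj.same_topology(mp[0])
        assert nj.same_topology(ml)
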