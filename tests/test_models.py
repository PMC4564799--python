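"""Substitution models, distances, pruning likelihood, optimization, AIC."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats

import plastochron as pc
from plastochron.models import SaturationError, empirical_base_freqs
from conftest import random_alignment

HKY = pc.SubstitutionModel(name="HKY", kappa=3.0,
                           base_freqs=np.array([0.3, 0.2, 0.2, 0.3]))


def brute_force_lnl(tree, alignment, model):
    """Direct summation over all internal-state assignments (tiny trees)."""
    pi = model.base_freqs
    rates = model.category_rates()
    pinv = model.p_invariant or 0.0
    codes = alignment.codes
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    row = {t: i for i, t in enumerate(alignment.taxa)}
    total = 0.0
    for col in range(alignment.column_count):
        site = 0.0
        for rc in rates:
            P = {id(n): pc.transition_probabilities(model, (n.length or 0) * rc)
                 for n in nodes}
            s = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                st = dict(zip((id(n) for n in internals), assign))
                p = pi[st[id(tree.root)]]
                for n in nodes:
                    if n is tree.root:
                        continue
                    if n.is_leaf:
                        x = codes[row[n.label], col]
                        if x < 4:
                            p *= P[id(n)][st[id(n.parent)], x]
                    else:
                        p *= P[id(n)][st[id(n.parent)], st[id(n)]]
                s += p
            site += s / len(rates)
        if pinv:
            obs = codes[:, col]
            inv = sum(pi[x] for x in range(4)
                      if all(o >= 4 or o == x for o in obs))
            site = pinv * inv + (1 - pinv) * site
        total += math.log(site)
    return total


class TestTransitionProbabilities:
    @pytest.mark.parametrize("spec", ["JC", "K80", "HKY", "GTR"])
    def test_identity_at_zero_and_row_stochastic(self, spec, rng):
        m = pc.SubstitutionModel.from_spec(spec)
        assert np.allclose(pc.transition_probabilities(m, 0.0), np.eye(4))
        for t in rng.uniform(0, 3, size=5):
            P = pc.transition_probabilities(m, float(t))
            assert np.allclose(P.sum(axis=1), 1.0)
            assert np.all(P >= 0)

    def test_jc_closed_form_diagonal(self):
        m = pc.SubstitutionModel.from_spec("JC")
        P = pc.transition_probabilities(m, 0.1)
        expect = 0.25 + 0.75 * math.exp(-4 * 0.1 / 3)
        assert np.allclose(np.diag(P), expect, atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            pc.transition_probabilities(HKY, -0.1)

    def test_detailed_balance(self, rng):
        m = pc.SubstitutionModel(
            name="GTR", base_freqs=rng.dirichlet(np.ones(4) * 5),
            exchangeabilities=rng.uniform(0.2, 3, 6))
        Q = m.rate_matrix()
        pi = m.base_freqs
        assert np.allclose(pi[:, None] * Q, (pi[:, None] * Q).T, atol=1e-12)

    def test_chapman_kolmogorov(self, rng):
        m = pc.SubstitutionModel(
            name="GTR", base_freqs=np.array([0.35, 0.15, 0.2, 0.3]),
            exchangeabilities=np.array([1.2, 4.0, 0.8, 1.1, 3.5, 1.0]))
        for _ in range(5):
            t, s = rng.uniform(0.01, 2, 2)
            lhs = pc.transition_probabilities(m, t + s)
            rhs = pc.transition_probabilities(m, t) \
                @ pc.transition_probabilities(m, s)
            assert np.abs(lhs - rhs).max() < 1e-10


class TestDiscretizeGamma:
    def test_single_category(self):
        assert pc.discretize_gamma(0.7, 1).tolist() == [1.0]

    @pytest.mark.parametrize("alpha,n", [(0.2, 4), (0.5, 4), (1.0, 8),
                                         (5.0, 4)])
    def test_mean_is_one(self, alpha, n):
        assert pc.discretize_gamma(alpha, n).mean() == pytest.approx(1.0)

    def test_matches_quadrature(self):
        alpha, n = 0.5, 4
        rates = pc.discretize_gamma(alpha, n)
        dist = stats.gamma(a=alpha, scale=1 / alpha)
        edges = dist.ppf(np.linspace(0, 1, n + 1))
        edges[-1] = dist.ppf(1 - 1e-14)
        for k in range(n):
            mean_k, _ = integrate.quad(
                lambda x: x * dist.pdf(x), edges[k], edges[k + 1])
            assert rates[k] == pytest.approx(n * mean_k, abs=1e-6)


class TestPairwiseDistance:
    def test_identical_is_zero(self):
        m = pc.SubstitutionModel.from_spec("JC")
        assert pc.pairwise_distance("ACGT" * 10, "ACGT" * 10, m) == 0.0

    def test_jc_closed_form(self):
        m = pc.SubstitutionModel.from_spec("JC")
        a = "A" * 100
        b = "A" * 90 + "C" * 10
        d = pc.pairwise_distance(a, b, m)
        assert d == pytest.approx(-0.75 * math.log(1 - 4 * 0.1 / 3),
                                  abs=1e-6)
        assert d == pytest.approx(0.10733, abs=1e-5)

    def test_jc_saturation_error(self):
        m = pc.SubstitutionModel.from_spec("JC")
        with pytest.raises(SaturationError):
            pc.pairwise_distance("ACGT" * 25, "CATG" * 25, m)

    def test_gtr_gamma_collapses_to_jc(self):
        # equal frequencies/exchangeabilities and a huge shape: GTR+G ~ JC
        rng = np.random.default_rng(5)
        chron = pc.simulate_yule_chronogram(2, 1.0, seed=6)
        sim = pc.evolve_sequences(chron, pc.ClockModel("strict", rate=0.05),
                                  pc.SubstitutionModel.from_spec("JC"),
                                  20000, seed=7)
        a, b = sim.alignment.codes
        jc = pc.pairwise_distance(a, b, pc.SubstitutionModel.from_spec("JC"))
        gtr = pc.SubstitutionModel(name="GTR", gamma_shape=500.0)
        d = pc.pairwise_distance(a, b, gtr)
        assert d == pytest.approx(jc, abs=1e-3)


class TestLogLikelihood:
    def test_two_taxa_zero_length_identical(self):
        a = pc.Alignment(["a", "b"], ["ACGT", "ACGT"])
        t = pc.read_newick("(a:0,b:0);")
        expect = sum(math.log(f) for f in HKY.base_freqs)
        assert pc.log_likelihood(t, a, HKY) == pytest.approx(expect)

    @pytest.mark.parametrize("spec", ["HKY", "HKY+G4", "HKY+G4+I"])
    def test_three_taxon_brute_force(self, spec, rng):
        a = random_alignment(rng, 3, 25, gap_prob=0.1)
        a.taxa = ["a", "b", "c"]
        t = pc.read_newick("((a:0.1,b:0.25):0.05,c:0.4);")
        m = pc.SubstitutionModel.from_spec(spec)
        m.kappa = 3.0
        if m.gamma_shape is not None:
            m.gamma_shape = 0.4
        if m.p_invariant is not None:
            m.p_invariant = 0.25
        assert pc.log_likelihood(t, a, m) == pytest.approx(
            brute_force_lnl(t, a, m), abs=1e-8)

    def test_rerooting_invariance(self, rng):
        a = random_alignment(rng, 5, 60)
        labels = a.taxa
        tree = pc.simulate_yule_chronogram(5, 1.0, rng, labels=labels)
        for n in tree.postorder():
            if n is not tree.root:
                n.length = float(rng.uniform(0.01, 0.5))
        base = pc.log_likelihood(tree, a, HKY)
        for lab in labels[:3]:
            re = tree.reroot_on_edge(tree.find_tip(lab), 0.3)
            assert pc.log_likelihood(re, a, HKY) == pytest.approx(
                base, abs=1e-8)

    def test_pattern_compression_matches_columnwise(self, rng):
        a = random_alignment(rng, 4, 40, gap_prob=0.1)
        t = pc.read_newick(
            f"(({a.taxa[0]}:0.1,{a.taxa[1]}:0.2):0.1,"
            f"({a.taxa[2]}:0.15,{a.taxa[3]}:0.05):0.1);")
        whole = pc.log_likelihood(t, a, HKY)
        by_column = sum(
            pc.log_likelihood(t, a.take_columns(np.array([c])), HKY)
            for c in range(a.column_count))
        assert whole == pytest.approx(by_column, abs=1e-9)

    def test_partitioned_sums_per_partition(self, rng):
        a = random_alignment(rng, 4, 40)
        part = pc.PartitionSet({"left": [(0, 25)], "right": [(25, 40)]})
        a.partition = part
        t = pc.read_newick(
            f"(({a.taxa[0]}:0.1,{a.taxa[1]}:0.2):0.1,"
            f"({a.taxa[2]}:0.15,{a.taxa[3]}:0.05):0.1);")
        m2 = pc.SubstitutionModel(name="HKY", kappa=6.0)
        combined = pc.log_likelihood(t, a, {"left": HKY, "right": m2})
        left = pc.log_likelihood(t, a.take_columns(np.arange(25)), HKY)
        right = pc.log_likelihood(t, a.take_columns(np.arange(25, 40)), m2)
        assert combined == pytest.approx(left + right, abs=1e-9)

    def test_taxon_mismatch_reported(self):
        a = pc.Alignment(["a", "b"], ["AC", "GT"])
        t = pc.read_newick("(a:1,x:1);")
        with pytest.raises(ValueError, match="x"):
            pc.log_likelihood(t, a, HKY)


class TestOptimization:
    def test_optimizer_never_decreases_lnl(self, tiny_alignment):
        start = pc.nj_tree(tiny_alignment,
                           pc.SubstitutionModel.from_spec("JC"))
        before = pc.log_likelihood(start, tiny_alignment, HKY)
        _, after = pc.optimize_branch_lengths(start, tiny_alignment, HKY)
        assert after >= before - 1e-9

    def test_kappa_recovery(self):
        chron = pc.simulate_yule_chronogram(6, 1.0, seed=2)
        truth = pc.SubstitutionModel(
            name="HKY", kappa=4.0, base_freqs=np.array([0.3, 0.2, 0.2, 0.3]))
        sim = pc.evolve_sequences(chron, pc.ClockModel("strict", rate=0.05),
                                  truth, 50000, seed=3)
        fitted, _, _ = pc.fit_model(sim.tree.copy(), sim.alignment, "HKY")
        assert fitted.kappa == pytest.approx(4.0, abs=0.5)


class TestModelSelection:
    def test_aic_arithmetic(self):
        # AIC = 2k - 2 lnL
        m = pc.SubstitutionModel.from_spec("GTR")          # k = 8
        assert m.n_free_parameters() == 8
        assert pc.SubstitutionModel.from_spec("JC").n_free_parameters() == 0
        assert pc.SubstitutionModel.from_spec("HKY+G4+I").n_free_parameters() \
            == 6
        assert 2 * 5 - 2 * (-1000.0) == 2010.0

    def test_jc_data_prefers_jc(self):
        chron = pc.simulate_yule_chronogram(5, 1.0, seed=4)
        sim = pc.evolve_sequences(chron, pc.ClockModel("strict", rate=0.03),
                                  pc.SubstitutionModel.from_spec("JC"),
                                  20000, seed=5)
        table = pc.select_model(sim.alignment, sim.tree.copy(),
                                candidates=("JC", "GTR+G4+I"))
        assert table.iloc[0]["model"] == "JC"

    def test_gtr_gamma_data_beats_jc(self):
        chron = pc.simulate_yule_chronogram(5, 1.0, seed=6)
        truth = pc.SubstitutionModel(
            name="GTR", base_freqs=np.array([0.4, 0.1, 0.15, 0.35]),
            exchangeabilities=np.array([0.5, 6.0, 0.4, 0.9, 8.0, 1.0]),
            gamma_shape=0.25)
        sim = pc.evolve_sequences(chron, pc.ClockModel("strict", rate=0.04),
                                  truth, 50000, seed=7)
        table = pc.select_model(sim.alignment, sim.tree.copy(),
                                candidates=("JC", "GTR+G4"))
        assert table.iloc[0]["model"] == "GTR+G4"

    def test_empirical_frequencies(self):
        a = pc.Alignment(["a", "b"], ["AAAC", "AAAG"])
        f = empirical_base_freqs(a)
        assert f.sum() == pytest.approx(1.0)
        assert f[0] == pytest.approx(6 / 8)
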