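"""Calibrated-Yule prior, clock likelihood, MCMC and posterior summaries."""

import math

import numpy as np
import pytest

import plastochron as pc
from plastochron.dating import ages_to_lengths, check_ultrametric


def chronogram_from_ages(newick, ages):
    """Attach ages (postorder internal order) to a parsed topology."""
    tree = pc.read_newick(newick)
    it = iter(ages)
    for node in tree.postorder():
        node.age = 0.0 if node.is_leaf else float(next(it))
    ages_to_lengths(tree)
    return tree


class TestYulePrior:
    def test_closed_form_three_taxa(self):
        # two internal nodes at ages 2 and 1; iid Exp(lambda) node ages:
        # log p = 2 log(lambda) - lambda * (2 + 1)
        chron = chronogram_from_ages("((a,b),c);", [1.0, 2.0])
        assert pc.yule_log_prior(chron, 1.0) == pytest.approx(-3.0)
        lam = 0.7
        assert pc.yule_log_prior(chron, lam) == pytest.approx(
            2 * math.log(lam) - lam * 3.0)

    def test_birth_rate_mle_scales_inversely_with_ages(self):
        chron = pc.simulate_yule_chronogram(6, 1.0, seed=0)
        from scipy.optimize import minimize_scalar

        def mle(tree):
            res = minimize_scalar(
                lambda lam: -pc.yule_log_prior(tree, lam),
                bounds=(1e-3, 100), method="bounded")
            return res.x

        base = mle(chron)
        scaled = chron.copy()
        for n in scaled.postorder():
            n.age *= 0.5
        ages_to_lengths(scaled)
        assert mle(scaled) == pytest.approx(2 * base, rel=1e-3)

    def test_non_ultrametric_rejected(self):
        tree = pc.read_newick("((a:1,b:2):1,c:2);")
        for node in tree.postorder():
            node.age = None
        with pytest.raises(ValueError):
            pc.yule_log_prior(tree, 1.0)


class TestChronogramLikelihood:
    @pytest.fixture()
    def setup(self):
        chron = pc.simulate_yule_chronogram(5, 1.0, seed=1)
        model = pc.SubstitutionModel(name="HKY", kappa=3.0)
        sim = pc.evolve_sequences(chron, pc.ClockModel("strict", rate=0.02),
                                  model, 1500, seed=2)
        return chron, model, sim.alignment

    def test_strict_clock_is_scaled_branch_lengths(self, setup):
        chron, model, aln = setup
        r = 0.02
        clock = pc.ClockModel("strict", rate=r)
        via_clock = pc.chronogram_log_likelihood(chron, clock, aln, model)
        scaled = chron.copy()
        for n in scaled.postorder():
            if n.parent is not None:
                n.length = (n.parent.age - n.age) * r
        assert via_clock == pytest.approx(
            pc.log_likelihood(scaled, aln, model), abs=1e-10)

    def test_rate_time_nonidentifiability(self, setup):
        chron, model, aln = setup
        l1 = pc.chronogram_log_likelihood(
            chron, pc.ClockModel("strict", rate=0.02), aln, model)
        halved = chron.copy()
        for n in halved.postorder():
            n.age *= 0.5
        ages_to_lengths(halved)
        l2 = pc.chronogram_log_likelihood(
            halved, pc.ClockModel("strict", rate=0.04), aln, model)
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_zero_sd_relaxed_equals_strict(self, setup):
        chron, model, aln = setup
        strict = pc.chronogram_log_likelihood(
            chron, pc.ClockModel("strict", rate=0.02), aln, model)
        relaxed = pc.ClockModel("relaxed_lognormal", rate=0.02,
                                log_mean=math.log(0.02), log_sd=0.0)
        n_branch = sum(1 for n in chron.postorder() if n.parent is not None)
        collapsed = pc.chronogram_log_likelihood(
            chron, relaxed, aln, model,
            branch_rates=np.full(n_branch, 0.02))
        assert strict == pytest.approx(collapsed, abs=1e-12)


class TestHpdAndEss:
    def test_constant_samples_zero_width(self):
        lo, hi = pc.hpd_interval([3.0] * 50)
        assert lo == hi == 3.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_minimum_window(self, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.gamma(2.0, 1.0, size=97))
        lo, hi = pc.hpd_interval(x, 0.95)
        m = math.ceil(0.95 * len(x))
        widths = [(x[i + m - 1] - x[i], x[i], x[i + m - 1])
                  for i in range(len(x) - m + 1)]
        best = min(widths)
        assert (lo, hi) == (best[1], best[2])

    def test_hpd_contains_mass(self, rng):
        x = rng.normal(size=500)
        lo, hi = pc.hpd_interval(x, 0.9)
        assert ((x >= lo) & (x <= hi)).mean() >= 0.9

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pc.hpd_interval([], 0.95)

    def test_ess_iid_near_n(self, rng):
        x = rng.normal(size=4000)
        assert pc.effective_sample_size(x) == pytest.approx(4000, rel=0.2)

    def test_ess_autocorrelated_below_n(self, rng):
        x = np.cumsum(rng.normal(size=2000)) * 0.1
        x = x - np.linspace(0, x[-1], 2000)
        assert pc.effective_sample_size(x) < 500

    def test_ess_agrees_with_arviz(self, rng):
        import arviz

        phi = 0.7
        e = rng.normal(size=3000)
        x = np.empty(3000)
        x[0] = e[0]
        for i in range(1, 3000):
            x[i] = phi * x[i - 1] + e[i]
        ours = pc.effective_sample_size(x)
        ref = float(arviz.ess(x))
        assert ours == pytest.approx(ref, rel=0.25)


class TestMcmc:
    def test_prior_only_recovers_calibration_density(self):
        """Sampling with the likelihood off reproduces the calibration."""
        chron = pc.simulate_yule_chronogram(5, 1.0, seed=1)
        cal = pc.CalibrationPrior(frozenset(chron.tip_labels()),
                                  "normal", (50.0, 2.5))
        cfg = pc.MCMCConfig(chain_length=30000, sample_every=20,
                            burn_in=4000, seed=5)
        trace = pc.run_dating_mcmc(None, chron, "strict", [cal], cfg,
                                   likelihood_on=False)
        ages = pc.clade_age_samples(trace, chron.tip_labels())
        ess = pc.effective_sample_size(ages)
        mc_se = ages.std() / math.sqrt(ess)
        assert ages.mean() == pytest.approx(50.0, abs=2 * mc_se + 0.05)

    def test_nonmonophyletic_calibration_rejected(self):
        chron = pc.simulate_yule_chronogram(5, 1.0, seed=1)
        tips = chron.tip_labels()
        # pick a pair that is NOT a cherry under this seed
        cherries = set()
        for n in chron.postorder():
            if not n.is_leaf and all(c.is_leaf for c in n.children):
                cherries.add(frozenset(c.label for c in n.children))
        import itertools
        bad = next(frozenset(p) for p in itertools.combinations(tips, 2)
                   if frozenset(p) not in cherries)
        cal = pc.CalibrationPrior(bad, "normal", (10.0, 1.0))
        with pytest.raises(ValueError, match="monophyletic"):
            pc.run_dating_mcmc(None, chron, "strict", [cal],
                               pc.MCMCConfig(2000, 10, 100, 0),
                               likelihood_on=False)

    def test_seed_reproducibility(self):
        chron = pc.simulate_yule_chronogram(4, 1.0, seed=3)
        cal = pc.CalibrationPrior(frozenset(chron.tip_labels()),
                                  "normal", (10.0, 1.0))
        cfg = pc.MCMCConfig(chain_length=3000, sample_every=10,
                            burn_in=500, seed=8)
        t1 = pc.run_dating_mcmc(None, chron, "strict", [cal], cfg,
                                likelihood_on=False)
        t2 = pc.run_dating_mcmc(None, chron, "strict", [cal], cfg,
                                likelihood_on=False)
        assert t1.samples.equals(t2.samples)

    def test_relaxed_width_exceeds_strict_under_rate_variation(self):
        """With strongly varying branch rates the relaxed clock admits
        wider node-age posteriors than the misspecified strict clock."""
        chron = pc.simulate_yule_chronogram(5, 1.0, seed=21)
        clock = pc.ClockModel("relaxed_lognormal", rate=0.02,
                              log_mean=math.log(0.02), log_sd=0.8)
        model = pc.SubstitutionModel(name="HKY", kappa=3.0)
        sim = pc.evolve_sequences(chron, clock, model, 4000, seed=22)
        cal = pc.CalibrationPrior(frozenset(chron.tip_labels()), "normal",
                                  (chron.root.age, 0.15 * chron.root.age))
        cfg = pc.MCMCConfig(chain_length=12000, sample_every=20,
                            burn_in=3000, seed=23)
        widths = {}
        for kind in ("strict", "relaxed_lognormal"):
            trace = pc.run_dating_mcmc(sim.alignment, chron, kind, [cal], cfg)
            total = 0.0
            for col in trace.clades:
                lo, hi = pc.hpd_interval(trace.samples[col])
                total += hi - lo
            widths[kind] = total
        assert widths["relaxed_lognormal"] > widths["strict"]

    def test_summarize_shape_and_bounds(self):
        chron = pc.simulate_yule_chronogram(4, 1.0, seed=3)
        cal = pc.CalibrationPrior(frozenset(chron.tip_labels()),
                                  "normal", (10.0, 1.0))
        cfg = pc.MCMCConfig(chain_length=4000, sample_every=10,
                            burn_in=500, seed=8)
        trace = pc.run_dating_mcmc(None, chron, "strict", [cal], cfg,
                                   likelihood_on=False)
        summ = pc.summarize(trace)
        assert (summ["hpd_lo"] <= summ["hpd_hi"]).all()
        assert (summ["ess"] > 0).all()
        for col in trace.clades:
            x = trace.samples[col].to_numpy()
            lo, hi = summ.loc[col, "hpd_lo"], summ.loc[col, "hpd_hi"]
            assert ((x >= lo) & (x <= hi)).mean() >= 0.95 - 1e-9
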