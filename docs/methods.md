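# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `plastochron`, in the order the pipeline applies
them.

## Alignment statistics

Columns are classified with gaps, `N` and IUPAC ambiguity codes treated
as missing data. With missing-data gap handling, a column is *constant*
when at most one distinct non-missing state is present (an all-missing
column is therefore constant), *variable* with two or more, and
*parsimony-informative* when at least two states each occur in at least
two taxa; variable non-informative columns are singletons. The
alternative gap mode deletes every column containing a gap before
classifying and reports the deleted count separately; it is the
mechanical reading of "deleting the indels", and the two modes satisfy
the identity `classify(delete) = classify(missing) ∘ strip_gap_columns`
plus the excluded count, which the tests assert. Pairwise differences
count columns where both taxa carry differing non-missing states; this
quantity is symmetric and zero on the diagonal but is deliberately not
treated as a metric (missingness patterns differ between pairs).

## Substitution models

The nested JC/K80/HKY/GTR family is parameterized by base frequencies
π, transition/transversion ratio κ (K80/HKY) or six exchangeabilities
with the GT rate fixed at 1 (GTR), an optional discrete-gamma shape α
with four categories by default, and an optional invariant-site
proportion p_inv. Rate matrices are scaled so one unit of branch length
is one expected substitution per site: category rates average one, and
with +I the variable-site matrix is sped up by 1/(1 − p_inv).
Transition probabilities come from the symmetric eigendecomposition of
the reversible generator (D^{1/2} Q D^{-1/2}); detailed balance and the
Chapman–Kolmogorov identity are asserted to 1e-10 in the tests.

Gamma categories use the mean-of-quantile-interval discretization (the
convention of mainstream likelihood software), computed from the
shape-(α+1) incomplete-gamma identity and renormalized to mean one
exactly.

Pairwise distances use the Jukes–Cantor closed form when the model is
plain JC (raising a saturation error at p ≥ 3/4) and otherwise maximize
the two-sequence likelihood over divergence numerically (bounded Brent
on t ∈ [1e-9, 15], frequencies empirical from the pair); hitting the
upper bound is reported as saturation rather than returned as a number.

## Likelihood and optimization

The pruning likelihood compresses the alignment to unique site patterns
(`numpy.unique` over columns) and propagates per-category partial
vectors bottom-up; missing tip states contribute a vector of ones. With
+I the invariant class contributes Σ_x π_x over states compatible with
every non-missing tip. A partitioned alignment sums independent
per-partition likelihoods on the shared topology. Reversibility makes
the result invariant to the rooting used for the traversal (asserted to
1e-8).

Branch lengths and free model parameters are optimized coordinate-wise
with bounded derivative-free 1-D searches (Brent, xatol 1e-8 for branch
lengths), cycling until a sweep gains less than the tolerance; iterates
are monotone by construction. At the ≤ 13-taxon problem sizes this
package targets, coordinate search is robust and reproducible; no
analytic gradients are used. Model selection fixes a NJ guide topology,
fits each candidate, and ranks by AIC = 2k − 2 lnL, counting empirical
frequencies as 3 parameters, exchangeabilities 5, and κ, α, p_inv one
each (branch lengths are shared by all candidates and excluded from k);
ties go to the smaller k. The candidate set is the four families ± Γ ±
I rather than a 56-model grid; the families nest, so AIC differences
against the richest model are still interpretable.

## Tree inference

Neighbour joining is the canonical Saitou–Nei agglomeration on the Q
criterion; ties are broken by the lexicographically smallest cluster
pair and negative length estimates are clamped to zero, so results are
bit-reproducible. On additive matrices NJ provably returns the
generating tree; the tests exercise this exactly (topology and lengths
to 1e-9) on random trees up to 10 taxa.

Parsimony uses the Fitch two-set pass vectorized over compressed
patterns (state bitmasks, missing = full set). The heuristic search
does random-addition-order stepwise insertion followed by hill-climbing
branch swapping: TBR candidates are generated by bisecting at every
edge and reconnecting every edge pair of the two fragments, accepting
only strict improvements (best-improvement per sweep), which guarantees
termination and determinism given the seed. All equally optimal
topologies found across replicates are retained (the MulTrees
behaviour). No ratchet or tabu search is used: at ten-ish taxa the
landscape does not require them, and the search is validated against
exhaustive enumeration of all 105 six-taxon topologies.

ML topology search runs NNI sweeps from a start tree (NJ by default),
screening each neighbour with a coarse one-sweep branch-length
re-optimization and fully re-optimizing accepted trees; full
TBR-in-likelihood is intentionally out of scope for runtime reasons.

Bootstrap resamples columns with replacement; parsimony pseudo-
replicates use a single addition replicate each (standard practice);
supports are the percentage of replicate trees containing each
bipartition of the point-estimate tree, which is also the tree the
supports are attached to. Majority-rule consensus keeps bipartitions
above the threshold (mutually compatible for thresholds ≥ 0.5) and
nests them directly. Out-group rooting bisects the out-group's pendant
edge at its midpoint.

## Divergence dating

Dating fixes the rooted binary topology (from the tree-inference stage)
rather than co-sampling it. The congruence of NJ/MP/ML on this class of
data makes the topology effectively known, and fixing it keeps the
sampler simple, fast and exactly testable; co-estimation of topology
and ages is a known limitation.

The state is the set of internal node ages (tips at zero), the Yule
birth rate λ, the clock parameters, and per-partition κ and α of an
HKY+Γ model. The Yule prior uses the conditioned reconstructed-process
form: given n tips, internal node ages behave as order statistics of
n − 1 iid Exponential(λ) draws, so log p = (n−1) log λ − λ Σ ages. This
form matches the forward simulator (below), gives root age ~ Exp(λ)
for two taxa, and makes the λ-MLE scale inversely with ages — all
asserted in tests.

**Calibrations.** A calibration is a proper density (normal, lognormal
or uniform) on the age of a clade's MRCA; the clade must be
monophyletic in the fixed topology. The calibration density *replaces*
the Yule factor for the calibrated node's age rather than multiplying
it. The purely multiplicative construction tilts the calibrated node's
prior marginal by roughly −σ²λ (the Yule exponential acting on the
calibration), which measurably biases prior-only sampling; replacement
makes a prior-only run reproduce the calibration density exactly, which
is the validation contract the test suite enforces. Neither variant is
the exactly conditioned calibrated-Yule density, which is substantially
harder and not attempted. The default cereal calibration used in the
fixtures is normal(50, 2.5) Myr; σ is a configuration knob since only
the point value is conventionally quoted.

**Clocks.** Strict: one global rate (subs/site/Myr). Relaxed: branch
rates iid LogNormal(M, S) with S = 0 collapsing to strict (asserted
exactly). Branch length in substitutions/site is duration × rate, so
doubling rates while halving ages leaves the likelihood unchanged —
the rate–time ridge that the calibration resolves.

**Moves and priors.** Uniform node-age slides within the
parent/children bracket (symmetric), multiplicative scales on the root
age, rates, λ, κ and α (Hastings log f), random-walks on relaxed M and
branch-rate deviations, and a likelihood-invariant "ridge" move that
multiplies all internal ages by f and divides the clock rate by f
(log-Jacobian (n_internal − 1) log f), which decorrelates rate and ages
cheaply and was the single biggest mixing improvement. Parameter
priors: 1/x on wide bounds for λ and the strict rate, LogNormal(1,
1.25) for κ, Exponential(1) for α and the relaxed log-sd — weakly
informative and overridable. Acceptance rates per move class are
logged on the trace object.

**Summaries.** HPD intervals are the narrowest contiguous window
containing ⌈0.95 n⌉ sorted samples (checked against exhaustive window
search); ESS uses the initial-positive-sequence autocorrelation
estimator (cross-checked against arviz on an AR(1) series). Because the
topology is fixed, per-clade age summaries are exact and no
maximum-clade-credibility search is needed; the posterior-mean
chronogram annotates the fixed tree.

Default chain settings (1.1M steps, thinning 200, burn-in 100k) follow
the only chain settings printed for this analysis class; the test suite
and acceptance script use shorter, seeded chains (20–40k steps at 6
taxa × 20 kb) chosen so that effective sample sizes of node ages stay
near or above ~100, which the coverage experiment shows is sufficient
for calibrated 95% HPDs to cover true ages at the nominal rate.

## Synthetic data

The generator is the forward model of everything the analysis assumes.
Yule chronograms are simulated in the conditioned form (ages = order
statistics of iid exponentials; topology by uniform random joins),
matching the dating prior exactly. Sequences evolve root-to-tips with
per-branch rates from the clock; per-site gamma categories (and
invariant flags) are drawn once at the root and inherited.

Substitution outcomes are a pure function of (site identity, branch,
seed): every site carries a persistent 64-bit tag, every branch a key,
and the child state inverts the transition CDF at a splitmix64-derived
uniform. Indel events (per-site Poisson along each branch, geometric
lengths with mean 3 bp, insertion:deletion 1:1) draw from a separate
stream, so enabling indels changes which sites exist but never the
substitution history of surviving sites — an invariant the tests check
column-by-column via recorded site keys. The true alignment is emitted
directly from the site-key bookkeeping, not re-estimated.

The quadripartite profile evolves LSC, SSC and a single IR and emits
each genome as LSC + IRa + SSC + revcomp(IRa), i.e. perfect IR
homogenization applied after substitution sampling, mirroring the
near-identity of real plastome repeats. Region sizes default to
80,786 / 12,347 / 20,787 bp (total 134,707), placing simulated genomes
inside the 134,563–134,911 bp band observed for the target system.

The `aa_like` fixture emulates the target system's geometry: ten
ingroup taxa on
a Yule tree scaled to a 0.95 Myr crown, an out-group diverging at 4.37
Myr, a calibration pair splitting at 50 Myr, root at 60 Myr, strict
rate 0.0015 subs/site/Myr, HKY κ=3.5 with Γ(α=0.5) and plastome-like
base frequencies (0.31/0.19/0.19/0.31). These values reproduce the
target scale — a few hundred pairwise differences among ingroup
genomes — and are fixed, not tuned per run. What the simulator does
*not* emulate: alignment error (the true alignment is known), IR
boundary shifts, structural rearrangements, heterotachy, and base
compositional heterogeneity across lineages; passing tests therefore
validate the inference machinery, not robustness to real-data
misalignment.

Profiles: `tiny` (5 taxa × 2 kb, rate 0.02, no indels) for fast
end-to-end checks; `aa_like` as above with indel rate 0.002 events/
site/substitution; `stress` (6 taxa, ~3 expected substitutions per
site) for saturation behaviour.

## Pipeline and reproducibility

The `run` command executes stats → AIC model choice → NJ/MP/ML with
bootstrap → out-group rooting → dating, writing TSV/Newick artifacts, a
manifest of SHA-256 content hashes, and a log of seeds and stage wall
times. All randomness flows from the single run seed, and re-running a
configuration reproduces byte-identical artifacts (asserted in the
tests). Configuration files are flat INI `key = value` sections — no
schema engine.

## Known limitations

- Topology is fixed during dating; topological uncertainty is not
  propagated into age HPDs.
- The calibrated-Yule prior is the replacement approximation, not the
  exactly conditioned density.
- ML search explores NNI space only; parsimony TBR is the thorough
  search. At ≤ 13 taxa with clean signal all three criteria agree, but
  larger or noisier problems would need a stronger ML search.
- Ambiguity codes are treated as missing rather than as partial
  likelihood constraints.
- AICc/BIC are intentionally absent (AIC only); codon and amino-acid
  models are out of scope.
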