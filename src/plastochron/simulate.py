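"""Synthetic plastome datasets with known ground truth.

Generates Yule chronograms, evolves sequences along them under the
package's substitution models with strict or lognormal-relaxed clocks,
optionally inserts indels (per-site Poisson events, geometric lengths)
while recording the true alignment, and mirrors an inverted repeat to
produce quadripartite LSC/IRa/SSC/IRb plastome-like genomes.

The Yule generator uses the conditioned reconstructed process: node
ages are order statistics of n-1 iid Exponential(birth_rate) draws and
the labelled topology is built by uniform random joins, which matches
the prior density used by :mod:`plastochron.dating`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .alignment import Alignment
from .dating import ClockModel, ages_to_lengths, check_ultrametric
from .io import PartitionSet, SequenceRecord, write_fasta, write_partition_file
from .models import SubstitutionModel, transition_probabilities
from .trees import Node, Tree

_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}
_CODE2CHAR = np.frombuffer(b"ACGT-N", dtype=np.uint8)


@dataclass
class PlastomeStructure:
    """Quadripartite layout: LSC + IRa + SSC + IRb (IRb = revcomp IRa)."""

    lsc_length: int = 80786
    ssc_length: int = 12347
    ir_length: int = 20787

    def __post_init__(self):
        if min(self.lsc_length, self.ssc_length, self.ir_length) <= 0:
            raise ValueError("all region lengths must be > 0")

    @property
    def total(self) -> int:
        return self.lsc_length + self.ssc_length + 2 * self.ir_length


@dataclass
class IndelConfig:
    """Poisson indel events per site per substitution, geometric lengths."""

    rate: float = 0.0
    mean_length: float = 3.0
    insertion_fraction: float = 0.5

    def __post_init__(self):
        if self.rate < 0 or self.mean_length < 1:
            raise ValueError("invalid indel configuration")


@dataclass
class SimulationResult:
    alignment: Alignment                  # true alignment (with gaps)
    genomes: list[SequenceRecord]         # ungapped sequences per tip
    tree: Tree                            # chronogram w/ branch subs/site
    partition: Optional[PartitionSet]
    branch_rates: dict                    # clade-key -> subs/site/Myr
    column_keys: list = field(default_factory=list)  # (region, site key)


# ----------------------------------------------------------------------
# Yule chronograms
# ----------------------------------------------------------------------

def simulate_yule_chronogram(n_taxa: int, birth_rate: float, seed=0,
                             labels: Optional[Sequence[str]] = None) -> Tree:
    """Random ultrametric Yule tree; tips at age 0, ages in 1/birth_rate units."""
    if n_taxa < 2:
        raise ValueError("need >= 2 taxa")
    if birth_rate <= 0:
        raise ValueError("birth rate must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    labels = list(labels) if labels is not None else \
        [f"t{i + 1}" for i in range(n_taxa)]
    if len(labels) != n_taxa:
        raise ValueError("one label per taxon required")
    ages = np.sort(rng.exponential(1.0 / birth_rate, size=n_taxa - 1))
    lineages = [Node(lab, age=0.0) for lab in labels]
    for age in ages:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        parent = Node(age=float(age))
        parent.add_child(lineages[i])
        parent.add_child(lineages[j])
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
        lineages.append(parent)
    tree = Tree(lineages[0])
    ages_to_lengths(tree)
    return tree


def scale_chronogram(tree: Tree, root_age: float) -> Tree:
    """Rescale all node ages so the root sits at ``root_age``."""
    out = tree.copy()
    factor = root_age / out.root.age
    for node in out.postorder():
        node.age = (node.age or 0.0) * factor
    ages_to_lengths(out)
    return out


# ----------------------------------------------------------------------
# sequence evolution
# ----------------------------------------------------------------------

def _branch_rate(clock: ClockModel, rng: np.random.Generator) -> float:
    if clock.kind == "strict" or clock.log_sd == 0:
        return clock.rate if clock.kind == "strict" else math.exp(clock.log_mean)
    return float(rng.lognormal(clock.log_mean, clock.log_sd))


class _Region:
    """One evolving region: column keys, states, categories and site tags."""

    __slots__ = ("keys", "states", "cats", "tags")

    def __init__(self, keys, states, cats, tags):
        self.keys = keys          # list of tuples, globally ordered
        self.states = states      # np.uint8 array, 0..3
        self.cats = cats          # per-site rate-category index; -1 invariant
        self.tags = tags          # per-site uint64 identity for state draws


def _splitmix64(z: np.ndarray) -> np.ndarray:
    z = z + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def _site_uniform(tags: np.ndarray, branch_key: np.uint64) -> np.ndarray:
    """Deterministic uniform in [0,1) per site for a given branch."""
    return (_splitmix64(tags ^ branch_key) >> np.uint64(11)) * 2.0 ** -53


def _evolve_region(chronogram: Tree, model: SubstitutionModel, length: int,
                   indel: IndelConfig, rng: np.random.Generator,
                   branch_rate_of) -> tuple[list, dict]:
    """Evolve one region; returns (all column keys sorted, tip sequences).

    Substitution outcomes are a pure function of (site identity, branch,
    seed): each site carries a persistent random tag and each branch a
    key, and the child state comes from inverting the transition CDF at
    a hash-derived uniform.  Indel events draw from a separate stream,
    so switching indels on changes only which sites exist, never the
    substitution history of surviving sites.
    """
    pi = model.base_freqs
    rates = model.category_rates()
    pinv = model.p_invariant or 0.0
    ncat = len(rates)
    seeds = rng.integers(2**31, size=3)
    root_rng = np.random.default_rng(seeds[0])
    indel_rng = np.random.default_rng(seeds[1])
    branch_rng = np.random.default_rng(seeds[2])
    counter = [0]

    def draw_sites(n, source):
        states = source.choice(4, size=n, p=pi).astype(np.uint8)
        cats = source.integers(0, ncat, size=n)
        if pinv:
            cats[source.random(n) < pinv] = -1
        tags = source.integers(0, 2**63, size=n, dtype=np.uint64)
        return states, cats, tags

    root = _Region([(i,) for i in range(length)],
                   *draw_sites(length, root_rng))
    tips: dict[str, _Region] = {}

    def evolve_branch(region: _Region, t_subs: float,
                      branch_key: np.uint64) -> _Region:
        states = region.states.copy()
        cats = region.cats.copy()
        tags = region.tags.copy()
        keys = list(region.keys)
        if t_subs > 0:
            P = transition_probabilities(model, t_subs * rates)
            cdf = np.cumsum(P, axis=2)                    # (ncat, 4, 4)
            u = _site_uniform(tags, branch_key)
            variable = cats >= 0
            row = cdf[cats[variable], states[variable]]   # (n_var, 4)
            states[variable] = (row < u[variable, None]).sum(axis=1) \
                .astype(np.uint8).clip(0, 3)
            if indel.rate > 0:
                n_events = indel_rng.poisson(indel.rate * len(keys) * t_subs)
                p_geom = 1.0 / indel.mean_length
                for _ in range(n_events):
                    ln = int(indel_rng.geometric(p_geom))
                    if indel_rng.random() < indel.insertion_fraction:
                        pos = int(indel_rng.integers(0, len(keys) + 1))
                        anchor = keys[pos - 1] if pos > 0 else (-1,)
                        counter[0] += 1
                        new_keys = [anchor + (counter[0], j) for j in range(ln)]
                        ns, nc, nt = draw_sites(ln, indel_rng)
                        keys[pos:pos] = new_keys
                        states = np.concatenate([states[:pos], ns, states[pos:]])
                        cats = np.concatenate([cats[:pos], nc, cats[pos:]])
                        tags = np.concatenate([tags[:pos], nt, tags[pos:]])
                    elif len(keys) > ln:
                        pos = int(indel_rng.integers(0, len(keys) - ln + 1))
                        del keys[pos:pos + ln]
                        states = np.delete(states, slice(pos, pos + ln))
                        cats = np.delete(cats, slice(pos, pos + ln))
                        tags = np.delete(tags, slice(pos, pos + ln))
        return _Region(keys, states, cats, tags)

    def recurse(node: Node, region: _Region) -> None:
        if node.is_leaf:
            tips[node.label] = region
            return
        for child in node.children:
            branch_key = np.uint64(branch_rng.integers(0, 2**63))
            duration = node.age - child.age
            t_subs = duration * branch_rate_of(child)
            recurse(child, evolve_branch(region, t_subs, branch_key))

    recurse(chronogram.root, root)
    all_keys = sorted(set().union(*(set(r.keys) for r in tips.values())))
    return all_keys, tips


def evolve_sequences(chronogram: Tree,
                     clock: ClockModel,
                     model: Union[SubstitutionModel, dict],
                     length_or_structure: Union[int, PlastomeStructure],
                     indel_config: Optional[IndelConfig] = None,
                     seed=0) -> SimulationResult:
    """Simulate sequences along a chronogram; emit the true alignment.

    With a :class:`PlastomeStructure` the LSC, IR and SSC regions are
    evolved separately (the IR once) and each genome is assembled as
    LSC + IRa + SSC + revcomp(IRa), mirroring the homogenised inverted
    repeats of real plastomes; the alignment carries the matching
    partition.  With an integer length a single region is evolved.
    """
    check_ultrametric(chronogram)
    rng = np.random.default_rng(seed)
    indel = indel_config or IndelConfig()

    # one rate per branch, drawn up front so clades map to rates
    rate_of: dict[int, float] = {}
    clade_rates: dict[str, float] = {}
    below: dict[int, frozenset] = {}
    for node in chronogram.postorder():
        below[id(node)] = frozenset([node.label]) if node.is_leaf else \
            frozenset().union(*(below[id(c)] for c in node.children))
        if node.parent is not None or True:
            r = _branch_rate(clock, rng)
            rate_of[id(node)] = r
            clade_rates["|".join(sorted(below[id(node)]))] = r

    def branch_rate_of(node: Node) -> float:
        return rate_of[id(node)]

    if isinstance(length_or_structure, PlastomeStructure):
        st = length_or_structure
        regions = [("lsc", st.lsc_length), ("ir", st.ir_length),
                   ("ssc", st.ssc_length)]
    else:
        regions = [("all", int(length_or_structure))]

    if isinstance(model, dict):
        models = model
    else:
        models = {name: model for name, _ in regions}

    taxa = chronogram.tip_labels()
    aligned: dict[str, list[np.ndarray]] = {t: [] for t in taxa}
    genome: dict[str, list[np.ndarray]] = {t: [] for t in taxa}
    bounds: list[tuple[str, int]] = []
    column_keys: list[tuple[str, tuple]] = []
    ir_block: Optional[dict[str, np.ndarray]] = None
    ir_keys: list = []

    for name, length in regions:
        all_keys, tips = _evolve_region(
            chronogram, models[name], length, indel, rng, branch_rate_of)
        pos = {k: i for i, k in enumerate(all_keys)}
        width = len(all_keys)
        block: dict[str, np.ndarray] = {}
        for t in taxa:
            row = np.full(width, 4, dtype=np.uint8)       # 4 = gap
            reg = tips[t]
            row[[pos[k] for k in reg.keys]] = reg.states
            block[t] = row
        for t in taxa:
            aligned[t].append(block[t])
            genome[t].append(block[t][block[t] < 4])
        bounds.append((name, width))
        column_keys.extend((name, k) for k in all_keys)
        if name == "ir":
            ir_block = block
            ir_keys = all_keys

    if ir_block is not None:
        # IRb: reverse-complement mirror of the IRa alignment block
        comp = np.array([3, 2, 1, 0, 4, 5], dtype=np.uint8)
        for t in taxa:
            mirrored = comp[ir_block[t]][::-1]
            aligned[t].append(mirrored)
            genome[t].append(mirrored[mirrored < 4])
        bounds.append(("irb", ir_block[taxa[0]].shape[0]))
        column_keys.extend(("irb", k) for k in reversed(ir_keys))

    rows = ["".join(_CODE2CHAR[np.concatenate(aligned[t])].tobytes()
                    .decode("ascii")) for t in taxa]
    partition = None
    if len(bounds) > 1:
        ivals: dict[str, list[tuple[int, int]]] = {}
        offset = 0
        rename = {"lsc": "lsc", "ir": "ira", "ssc": "ssc", "irb": "irb"}
        for name, width in bounds:
            ivals[rename.get(name, name)] = [(offset, offset + width)]
            offset += width
        partition = PartitionSet(ivals)
    alignment = Alignment(taxa, rows, partition)
    genomes = [SequenceRecord(
        t, _CODE2CHAR[np.concatenate(genome[t])].tobytes().decode("ascii"))
        for t in taxa]

    # true tree: the chronogram with realized substitution branch lengths
    true_tree = chronogram.copy()
    below2: dict[int, frozenset] = {}
    for node in true_tree.postorder():
        below2[id(node)] = frozenset([node.label]) if node.is_leaf else \
            frozenset().union(*(below2[id(c)] for c in node.children))
        if node.parent is not None:
            r = clade_rates["|".join(sorted(below2[id(node)]))]
            node.length = (node.parent.age - node.age) * r

    return SimulationResult(alignment, genomes, true_tree, partition,
                            clade_rates, column_keys)


# ----------------------------------------------------------------------
# fixtures
# ----------------------------------------------------------------------

@dataclass
class FixtureBundle:
    profile: str
    seed: int
    result: SimulationResult
    chronogram: Tree
    clock: ClockModel
    model: Union[SubstitutionModel, dict]
    calibration_clade: tuple
    calibration_age: float
    outgroup: Optional[str]
    manifest: dict = field(default_factory=dict)


def _aa_like_chronogram(rng: np.random.Generator) -> Tree:
    """Ten shallow ingroup taxa, an out-group stem and a deep calibration pair.

    Geometry emulates the target system: ingroup crown ~0.95 Myr,
    out-group divergence 4.37 Myr, calibration pair split 50 Myr, root
    60 Myr.
    """
    ingroup = simulate_yule_chronogram(
        10, 2.0, rng, labels=[f"aa_{i:02d}" for i in range(1, 11)])
    ingroup = scale_chronogram(ingroup, 0.95)
    stem = Node(age=4.37)
    stem.add_child(ingroup.root)
    stem.add_child(Node("outgroup", age=0.0))
    cal = Node(age=50.0)
    cal.add_child(Node("cal_left", age=0.0))
    cal.add_child(Node("cal_right", age=0.0))
    root = Node(age=60.0)
    root.add_child(stem)
    root.add_child(cal)
    tree = Tree(root)
    ages_to_lengths(tree)
    return tree


def make_fixture(profile_name: str, seed: int = 0,
                 out_dir: Optional[Union[str, Path]] = None) -> FixtureBundle:
    """Build a named synthetic dataset: ``tiny``, ``aa_like`` or ``stress``.

    ``tiny``: 5 taxa x 2 kb, strict clock, fast end-to-end testing.
    ``aa_like``: 13 taxa (10 shallow ingroup, out-group, calibration
    pair) on a quadripartite ~134.7 kb plastome with occasional indels,
    emulating the target system's divergence scale.
    ``stress``: 6 taxa near saturation.
    """
    rng = np.random.default_rng(seed)
    if profile_name == "tiny":
        chron = simulate_yule_chronogram(5, 1.0, rng)
        clock = ClockModel("strict", rate=0.02)
        model = SubstitutionModel.from_spec(
            "HKY", base_freqs=np.array([0.31, 0.19, 0.19, 0.31]))
        model.kappa = 3.0
        result = evolve_sequences(chron, clock, model, 2000,
                                  IndelConfig(rate=0.0),
                                  seed=int(rng.integers(2**31)))
        cal_clade = tuple(chron.tip_labels())
        cal_age = chron.root.age
        outgroup = None
    elif profile_name == "aa_like":
        chron = _aa_like_chronogram(rng)
        clock = ClockModel("strict", rate=0.0015)
        model = SubstitutionModel.from_spec(
            "HKY+G4", base_freqs=np.array([0.31, 0.19, 0.19, 0.31]))
        model.kappa = 3.5
        model.gamma_shape = 0.5
        result = evolve_sequences(chron, clock, model, PlastomeStructure(),
                                  IndelConfig(rate=0.002, mean_length=3.0),
                                  seed=int(rng.integers(2**31)))
        cal_clade = ("cal_left", "cal_right")
        cal_age = 50.0
        outgroup = "outgroup"
    elif profile_name == "stress":
        chron = simulate_yule_chronogram(6, 1.0, rng)
        chron = scale_chronogram(chron, 30.0)
        clock = ClockModel("strict", rate=0.05)
        model = SubstitutionModel.from_spec("JC")
        result = evolve_sequences(chron, clock, model, 5000,
                                  IndelConfig(rate=0.0),
                                  seed=int(rng.integers(2**31)))
        cal_clade = tuple(chron.tip_labels())
        cal_age = chron.root.age
        outgroup = None
    else:
        raise ValueError(f"unknown profile {profile_name!r}")

    manifest = {
        "profile": profile_name,
        "seed": seed,
        "n_taxa": result.alignment.n_taxa,
        "alignment_columns": result.alignment.column_count,
        "clock_kind": clock.kind,
        "clock_rate": clock.rate,
        "model": model.spec if isinstance(model, SubstitutionModel)
        else ",".join(m.spec for m in model.values()),
        "calibration_clade": ",".join(cal_clade),
        "calibration_age_myr": cal_age,
        "root_age_myr": chron.root.age,
        "outgroup": outgroup or "",
    }
    bundle = FixtureBundle(profile_name, seed, result, chron, clock, model,
                           cal_clade, cal_age, outgroup, manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(result.alignment.to_records(), out / "alignment.fasta")
        write_fasta(result.genomes, out / "genomes.fasta")
        (out / "true_tree.nwk").write_text(result.tree.to_newick() + "\n")
        chron_copy = chron.copy()
        ages_to_lengths(chron_copy)
        (out / "true_chronogram.nwk").write_text(
            chron_copy.to_newick() + "\n")
        if result.partition is not None:
            write_partition_file(result.partition, out / "partitions.txt")
        with open(out / "manifest.txt", "w") as fh:
            for k, v in manifest.items():
                fh.write(f"{k}={v}\n")
    return bundle
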