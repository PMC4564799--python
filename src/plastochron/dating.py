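"""Bayesian divergence dating on a fixed rooted topology.

The model follows the standard molecular-clock construction: node ages
(Myr, tips at zero) on a fixed binary rooted tree, a calibrated-Yule
prior on ages, a strict or lognormal-relaxed clock mapping ages to
branch lengths in substitutions/site, and an HKY(+G) pruning likelihood
optionally partitioned (coding / non-coding / intergenic).  Sampling is
plain Metropolis-Hastings; summaries report posterior means, 95% HPD
intervals and autocorrelation-corrected effective sample sizes.

The Yule prior uses the conditioned reconstructed-process form: given
``n`` tips the internal node ages behave as order statistics of
``n - 1`` iid Exponential(lambda) draws, so
``log p = (n-1) log(lambda) - lambda * sum(ages)``.  In the calibrated
variant the calibration density replaces the Yule factor on the
calibrated MRCA's age, so prior-only sampling reproduces the
calibration exactly (the exactly conditioned calibrated-Yule density
is not attempted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .alignment import Alignment
from .models import SubstitutionModel, _compress, _pattern_lnl
from .trees import Node, Tree

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

__all__ = [
    "ClockModel", "CalibrationPrior", "MCMCConfig", "Trace",
    "yule_log_prior", "chronogram_log_likelihood", "run_dating_mcmc",
    "hpd_interval", "effective_sample_size", "summarize",
    "clade_age_samples", "posterior_mean_chronogram",
]


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------

@dataclass
class ClockModel:
    """Strict (one global rate) or lognormal-relaxed branch-rate model.

    Rates are in substitutions/site/Myr.  For the relaxed clock the
    branch rates are iid LogNormal(log_mean, log_sd); log_sd = 0
    collapses to the strict clock.
    """

    kind: str = "strict"              # strict | relaxed_lognormal
    rate: float = 1e-3
    log_mean: float = math.log(1e-3)
    log_sd: float = 0.3

    def __post_init__(self):
        if self.kind not in ("strict", "relaxed_lognormal"):
            raise ValueError(f"unknown clock kind {self.kind!r}")
        if self.rate <= 0:
            raise ValueError("clock rate must be > 0")
        if self.log_sd < 0:
            raise ValueError("log_sd must be >= 0")


@dataclass
class CalibrationPrior:
    """A proper density on the age (Myr) of a clade's MRCA."""

    clade: frozenset
    density: str = "normal"           # normal | lognormal | uniform
    params: tuple = (50.0, 2.5)

    def __post_init__(self):
        self.clade = frozenset(self.clade)
        if len(self.clade) < 2:
            raise ValueError("calibration clade needs >= 2 taxa")
        if self.density not in ("normal", "lognormal", "uniform"):
            raise ValueError(f"unknown calibration density {self.density!r}")

    def logpdf(self, age: float) -> float:
        if self.density == "normal":
            mu, sd = self.params
            return -0.5 * ((age - mu) / sd) ** 2 - math.log(sd) - _LOG_SQRT_2PI
        if self.density == "lognormal":
            mu, sd = self.params       # parameters of log-age
            if age <= 0:
                return -np.inf
            z = (math.log(age) - mu) / sd
            return -0.5 * z * z - math.log(age * sd) - _LOG_SQRT_2PI
        lo, hi = self.params
        return -math.log(hi - lo) if lo <= age <= hi else -np.inf

    @property
    def mean(self) -> float:
        if self.density == "normal":
            return self.params[0]
        if self.density == "lognormal":
            mu, sd = self.params
            return math.exp(mu + 0.5 * sd * sd)
        lo, hi = self.params
        return 0.5 * (lo + hi)


@dataclass
class MCMCConfig:
    chain_length: int = 1_100_000
    sample_every: int = 200
    burn_in: int = 100_000
    seed: int = 0
    # relative weights of the move classes
    move_weights: dict = field(default_factory=lambda: {
        "node_age": 5.0, "root_scale": 1.0, "clock": 2.0,
        "birth_rate": 1.0, "substitution": 2.0, "ridge": 2.0,
    })

    def __post_init__(self):
        if not 0 <= self.burn_in < self.chain_length:
            raise ValueError("burn_in must be < chain_length")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")


@dataclass
class Trace:
    """Thinned post-burn-in MCMC samples plus bookkeeping."""

    samples: pd.DataFrame
    clades: dict                       # column name -> sorted tip labels
    acceptance: dict                   # move class -> acceptance rate
    config: MCMCConfig


# ----------------------------------------------------------------------
# chronogram helpers
# ----------------------------------------------------------------------

def check_ultrametric(tree: Tree, rtol: float = 1e-6) -> None:
    for node in tree.postorder():
        if node.age is None:
            raise ValueError("every node needs an age")
        if node.is_leaf and abs(node.age) > rtol:
            raise ValueError(f"tip {node.label!r} not at age 0")
        for child in node.children:
            if node.age <= child.age - rtol:
                raise ValueError("parent age must exceed child age")


def ages_to_lengths(tree: Tree) -> None:
    """Set branch lengths (Myr durations) from node ages, in place."""
    for node in tree.postorder():
        if node.parent is not None:
            node.length = node.parent.age - node.age


def lengths_to_ages(tree: Tree) -> None:
    """Set node ages from branch lengths, assuming the tree is ultrametric."""
    depth: dict[int, float] = {id(tree.root): 0.0}
    height = 0.0
    for node in tree.preorder():
        if node.parent is not None:
            depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
            height = max(height, depth[id(node)])
    for node in tree.postorder():
        node.age = height - depth[id(node)]
        if node.is_leaf:
            node.age = 0.0


def yule_log_prior(chronogram: Tree, birth_rate: float) -> float:
    """Log density of the internal node ages under the Yule prior."""
    if birth_rate <= 0:
        raise ValueError("birth rate must be > 0")
    check_ultrametric(chronogram)
    ages = [n.age for n in chronogram.internal_nodes()]
    return len(ages) * math.log(birth_rate) - birth_rate * float(sum(ages))


def chronogram_log_likelihood(
        chronogram: Tree,
        clock: ClockModel,
        alignment: Alignment,
        model: Union[SubstitutionModel, dict],
        branch_rates: Optional[Sequence[float]] = None) -> float:
    """Alignment log-likelihood of a dated tree under a clock.

    Branch length in substitutions/site = branch duration (Myr) x
    branch rate.  ``branch_rates``, when given, supplies per-branch
    rates in postorder (root excluded); otherwise the strict rate is
    used (a relaxed clock with log_sd = 0 collapses to strict).
    """
    check_ultrametric(chronogram)
    work = chronogram.copy()
    nonroot = [n for n in work.postorder() if n is not work.root]
    if branch_rates is None:
        rates = np.full(len(nonroot), clock.rate)
    else:
        rates = np.asarray(branch_rates, dtype=float)
        if len(rates) != len(nonroot):
            raise ValueError("one rate per non-root branch required")
    for node, r in zip(nonroot, rates):
        node.length = (node.parent.age - node.age) * r
    from .models import log_likelihood
    return log_likelihood(work, alignment, model)


# ----------------------------------------------------------------------
# posterior summaries
# ----------------------------------------------------------------------

def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``mass`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    m = int(math.ceil(mass * n))
    if m < 1 or m > n:
        raise ValueError(f"cannot take {mass} mass of {n} samples")
    if m == n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[:n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def effective_sample_size(samples) -> float:
    """ESS via the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need >= 2 samples")
    v = x.var()
    if v == 0:
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1:] / n
    rho = acov / acov[0]
    # Geyer initial positive sequence on pair sums
    tau = 1.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        k += 2
    return float(n / max(tau, 1.0 / n))


def summarize(trace: Trace, mass: float = 0.95) -> pd.DataFrame:
    """Posterior mean, HPD bounds and ESS for every sampled quantity."""
    rows = []
    for col in trace.samples.columns:
        x = trace.samples[col].to_numpy()
        lo, hi = hpd_interval(x, mass)
        rows.append({
            "parameter": col,
            "mean": float(x.mean()),
            "hpd_lo": lo,
            "hpd_hi": hi,
            "ess": effective_sample_size(x),
            "clade": "|".join(trace.clades.get(col, [])),
        })
    return pd.DataFrame(rows).set_index("parameter")


# ----------------------------------------------------------------------
# the sampler
# ----------------------------------------------------------------------

class _TreeIndex:
    """Array view of a fixed rooted binary topology for fast age moves."""

    def __init__(self, topology: Tree):
        self.tree = topology.copy()
        self.nodes = list(self.tree.postorder())
        for node in self.nodes:
            if not node.is_leaf and len(node.children) != 2:
                raise ValueError("dating requires a binary rooted topology")
        self.nonroot = [n for n in self.nodes if n is not self.tree.root]
        self.internal = [n for n in self.nodes if not n.is_leaf]
        self.root = self.tree.root
        self.clade = {}
        below: dict[int, frozenset] = {}
        for node in self.nodes:
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children))
            self.clade[id(node)] = below[id(node)]

    def mrca(self, clade: frozenset) -> Node:
        node = self.tree.clade_node(clade)
        if self.clade[id(node)] != clade:
            raise ValueError(
                f"calibration clade {sorted(clade)} is not monophyletic "
                "in the fixed topology")
        return node

    def init_ages(self, root_age: float) -> None:
        # proportional-to-depth initial ages below the root
        def depth(node: Node) -> int:
            return 0 if node.is_leaf else 1 + max(depth(c) for c in node.children)

        root_levels = depth(self.root)

        def assign(node: Node, upper: float) -> None:
            if node.is_leaf:
                node.age = 0.0
                return
            node.age = upper * depth(node) / max(root_levels, 1) \
                if node is not self.root else upper
            for c in node.children:
                assign(c, node.age)

        assign(self.root, root_age)


def _default_partition_models(alignment: Alignment) -> dict:
    from .models import empirical_base_freqs

    freqs = empirical_base_freqs(alignment)
    names = alignment.partition.with_default(alignment.column_count).names() \
        if alignment.partition is not None else ["all"]
    return {name: SubstitutionModel.from_spec("HKY+G4", base_freqs=freqs)
            for name in names}


def run_dating_mcmc(alignment: Optional[Alignment],
                    topology: Tree,
                    clock: str = "strict",
                    calibrations: Sequence[CalibrationPrior] = (),
                    config: Optional[MCMCConfig] = None,
                    partition_models: Optional[dict] = None,
                    likelihood_on: bool = True) -> Trace:
    """Metropolis-Hastings sampler for node ages, clock and model parameters.

    The topology is fixed; the state is the set of internal node ages,
    the Yule birth rate, the clock parameters (global rate, or
    lognormal mean/sd plus per-branch rates) and per-partition HKY+G
    parameters (kappa, alpha).  ``likelihood_on=False`` samples from
    the prior alone (the standard validation mode).

    Parameter priors: birth rate and strict rate 1/x on wide bounds,
    kappa LogNormal(1, 1.25), alpha Exponential(1), relaxed log-sd
    Exponential(1), with every calibration density multiplied in.
    """
    if not calibrations:
        raise ValueError("at least one calibration is required")
    config = config or MCMCConfig()
    rng = np.random.default_rng(config.seed)
    index = _TreeIndex(topology)

    cal_nodes = [(index.mrca(c.clade), c) for c in calibrations]
    root_cals = [c for node, c in cal_nodes if node is index.root]
    root_age0 = root_cals[0].mean if root_cals \
        else max(c.mean for _, c in cal_nodes) * 1.25
    index.init_ages(root_age0)
    for node, cal in cal_nodes:       # nudge calibrated nodes toward their mean
        if node is index.root:
            continue
        hi = node.parent.age
        lo = max(c.age for c in node.children)
        node.age = min(max(cal.mean, lo + 0.05 * (hi - lo)),
                       lo + 0.95 * (hi - lo))

    relaxed = clock == "relaxed_lognormal" or clock == "relaxed"
    n_branch = len(index.nonroot)

    # data structures for the likelihood
    part_data = []
    if likelihood_on:
        if alignment is None:
            raise ValueError("likelihood_on requires an alignment")
        if set(topology.tip_labels()) != set(alignment.taxa):
            raise ValueError("topology and alignment taxa differ")
        models = partition_models or _default_partition_models(alignment)
        if alignment.partition is not None:
            full = alignment.partition.with_default(alignment.column_count)
            for name in full.names():
                if name not in models:
                    raise ValueError(f"no model for partition {name!r}")
                cols = full.columns(name)
                if len(cols) == 0:
                    continue
                sub = alignment.take_columns(cols)
                patterns, weights = _compress(sub.codes)
                part_data.append([name, patterns, weights, sub.taxa,
                                  models[name]])
        else:
            patterns, weights = _compress(alignment.codes)
            key = next(iter(models)) if "all" not in models else "all"
            part_data.append(["all", patterns, weights, alignment.taxa,
                              models[key]])

    # state ------------------------------------------------------------
    if likelihood_on:
        from .models import SubstitutionModel as _SM, pairwise_distance
        try:
            d0 = pairwise_distance(alignment.codes[0], alignment.codes[-1],
                                   _SM.from_spec("JC"))
        except Exception:
            d0 = 0.01
        rate = max(d0 / (2.0 * root_age0), 1e-8)
    else:
        rate = 1e-3
    state = {
        "birth_rate": 1.0 / root_age0,
        "rate": rate,
        "log_mean": math.log(rate),
        "log_sd": 0.2,
        "branch_log_rates": np.zeros(n_branch),   # deviations from log_mean
    }
    sub_params = {i: {"kappa": 2.0, "alpha": 0.5}
                  for i in range(len(part_data))}

    def branch_rates() -> np.ndarray:
        if relaxed:
            return np.exp(state["log_mean"] + state["branch_log_rates"])
        return np.full(n_branch, state["rate"])

    def set_lengths() -> None:
        for node, r in zip(index.nonroot, branch_rates()):
            node.length = (node.parent.age - node.age) * r

    def log_likelihood_now() -> float:
        if not likelihood_on:
            return 0.0
        set_lengths()
        total = 0.0
        for i, (name, patterns, weights, taxa, model) in enumerate(part_data):
            m = _dc_replace(model, kappa=sub_params[i]["kappa"],
                            gamma_shape=sub_params[i]["alpha"])
            total += _pattern_lnl(index.tree, patterns, weights, taxa, m)
        return total

    # calibrated nodes: the calibration density replaces the Yule factor
    # on that node's age (rather than multiplying it), so prior-only
    # sampling reproduces the calibration density exactly
    calibrated_ids = {id(node) for node, _ in cal_nodes}

    def log_prior() -> float:
        lam = state["birth_rate"]
        if not (1e-8 < lam < 1e6):
            return -np.inf
        free_ages = [n.age for n in index.internal
                     if id(n) not in calibrated_ids]
        lp = len(free_ages) * math.log(lam) - lam * sum(free_ages) \
            - math.log(lam)
        for node, cal in cal_nodes:
            lp += cal.logpdf(node.age)
        if relaxed:
            s = state["log_sd"]
            if not 0 < s < 10:
                return -np.inf
            dev = state["branch_log_rates"]
            lp += float(-0.5 * np.sum((dev / s) ** 2)
                        - len(dev) * (math.log(s) + _LOG_SQRT_2PI))
            lp += -s                                  # Exp(1) prior on log_sd
            r = math.exp(state["log_mean"])
            if not (1e-12 < r < 1e3):
                return -np.inf
            lp += -state["log_mean"]                  # 1/r prior
        else:
            r = state["rate"]
            if not (1e-12 < r < 1e3):
                return -np.inf
            lp += -math.log(r)
        for i in sub_params:
            k, a = sub_params[i]["kappa"], sub_params[i]["alpha"]
            if k <= 0 or a <= 0:
                return -np.inf
            zk = (math.log(k) - 1.0) / 1.25           # LogNormal(1, 1.25)
            lp += -0.5 * zk * zk - math.log(k * 1.25) - _LOG_SQRT_2PI
            lp += -a                                  # Exp(1) prior on alpha
        return lp

    current_lnl = log_likelihood_now()
    current_prior = log_prior()
    current = current_lnl + current_prior
    if not np.isfinite(current):
        raise ValueError("non-finite initial posterior; check calibrations")

    moves = list(config.move_weights)
    if not likelihood_on:
        moves = [m for m in moves if m != "substitution"] or moves
    weights_arr = np.array([config.move_weights[m] for m in moves], dtype=float)
    weights_arr /= weights_arr.sum()
    non_root_internal = [n for n in index.internal if n is not index.root]
    tried = {m: 0 for m in moves}
    accepted = {m: 0 for m in moves}

    records = []
    col_names = None
    for it in range(config.chain_length):
        move = moves[int(rng.choice(len(moves), p=weights_arr))]
        tried[move] += 1
        log_hastings = 0.0
        undo = None
        proposed = True

        if move == "node_age" and non_root_internal:
            node = non_root_internal[int(rng.integers(len(non_root_internal)))]
            lo = max(c.age for c in node.children)
            hi = node.parent.age
            old = node.age
            node.age = float(rng.uniform(lo, hi))
            undo = ("age", node, old)
        elif move in ("node_age", "root_scale"):
            node = index.root
            old = node.age
            factor = math.exp(0.2 * (rng.random() - 0.5))
            new = old * factor
            if new <= max(c.age for c in node.children):
                proposed = False
            else:
                node.age = new
                log_hastings = math.log(factor)
                undo = ("age", node, old)
        elif move == "clock":
            if relaxed:
                which = rng.random()
                if which < 0.4:
                    old = state["log_mean"]
                    state["log_mean"] = old + 0.2 * (rng.random() - 0.5)
                    undo = ("scalar", "log_mean", old)
                elif which < 0.7:
                    old = state["log_sd"]
                    factor = math.exp(0.3 * (rng.random() - 0.5))
                    state["log_sd"] = old * factor
                    log_hastings = math.log(factor)
                    undo = ("scalar", "log_sd", old)
                else:
                    b = int(rng.integers(n_branch))
                    old = state["branch_log_rates"][b]
                    state["branch_log_rates"][b] = old + 0.4 * (rng.random() - 0.5)
                    undo = ("branch", b, old)
            else:
                old = state["rate"]
                factor = math.exp(0.3 * (rng.random() - 0.5))
                state["rate"] = old * factor
                log_hastings = math.log(factor)
                undo = ("scalar", "rate", old)
        elif move == "birth_rate":
            old = state["birth_rate"]
            factor = math.exp(0.5 * (rng.random() - 0.5))
            state["birth_rate"] = old * factor
            log_hastings = math.log(factor)
            undo = ("scalar", "birth_rate", old)
        elif move == "ridge":
            # scale every internal age by f and the clock rate by 1/f;
            # branch lengths (duration x rate) are invariant, so this
            # travels along the rate-time ridge without touching the
            # likelihood.  log-Jacobian: (n_internal - 1) log f.
            factor = math.exp(0.3 * (rng.random() - 0.5))
            old_ages = [n.age for n in index.internal]
            old_rate = state["rate"]
            old_logmean = state["log_mean"]
            for n in index.internal:
                n.age *= factor
            if relaxed:
                state["log_mean"] -= math.log(factor)
            else:
                state["rate"] /= factor
            log_hastings = (len(index.internal) - 1) * math.log(factor)
            undo = ("ridge", (old_ages, old_rate, old_logmean), None)
        elif move == "substitution" and part_data:
            i = int(rng.integers(len(part_data)))
            key = "kappa" if rng.random() < 0.5 else "alpha"
            old = sub_params[i][key]
            factor = math.exp(0.3 * (rng.random() - 0.5))
            sub_params[i][key] = old * factor
            log_hastings = math.log(factor)
            undo = ("sub", (i, key), old)
        else:
            proposed = False

        if proposed and undo is not None:
            new_prior = log_prior()
            if np.isfinite(new_prior):
                need_lnl = likelihood_on and move not in ("birth_rate", "ridge")
                new_lnl = log_likelihood_now() if need_lnl else current_lnl
                new = new_lnl + new_prior
                if math.log(rng.random() + 1e-300) < new - current + log_hastings:
                    current, current_lnl, current_prior = new, new_lnl, new_prior
                    accepted[move] += 1
                    undo = None
        if undo is not None:
            kind, where, old = undo
            if kind == "age":
                where.age = old
            elif kind == "scalar":
                state[where] = old
            elif kind == "branch":
                state["branch_log_rates"][where] = old
            elif kind == "sub":
                i, key = where
                sub_params[i][key] = old
            elif kind == "ridge":
                old_ages, old_rate, old_logmean = where
                for n, a in zip(index.internal, old_ages):
                    n.age = a
                state["rate"] = old_rate
                state["log_mean"] = old_logmean

        if it >= config.burn_in and (it - config.burn_in) % config.sample_every == 0:
            row = [current_lnl, current_prior, state["birth_rate"]]
            names = ["lnL", "log_prior", "birth_rate"]
            if relaxed:
                row += [math.exp(state["log_mean"]), state["log_sd"]]
                names += ["clock_rate", "clock_log_sd"]
            else:
                row += [state["rate"]]
                names += ["clock_rate"]
            for i in sub_params:
                row += [sub_params[i]["kappa"], sub_params[i]["alpha"]]
                names += [f"kappa_{part_data[i][0] if part_data else i}",
                          f"alpha_{part_data[i][0] if part_data else i}"]
            for j, node in enumerate(index.internal):
                row.append(node.age)
                names.append(f"age_node{j}")
            records.append(row)
            col_names = names

    if not records:
        raise ValueError("chain produced no post-burn-in samples")
    samples = pd.DataFrame(records, columns=col_names)
    clades = {f"age_node{j}": sorted(index.clade[id(node)])
              for j, node in enumerate(index.internal)}
    acc = {m: (accepted[m] / tried[m] if tried[m] else float("nan"))
           for m in moves}
    return Trace(samples=samples, clades=clades, acceptance=acc, config=config)


def posterior_mean_chronogram(trace: Trace, topology: Tree) -> Tree:
    """Fixed topology annotated with posterior-mean node ages."""
    index = _TreeIndex(topology)
    for j, node in enumerate(index.internal):
        node.age = float(trace.samples[f"age_node{j}"].mean())
    for node in index.nodes:
        if node.is_leaf:
            node.age = 0.0
    ages_to_lengths(index.tree)
    return index.tree


def clade_age_samples(trace: Trace, clade: Sequence[str]) -> np.ndarray:
    """Posterior age samples for the MRCA of ``clade``."""
    want = sorted(clade)
    for col, tips in trace.clades.items():
        if tips == want:
            return trace.samples[col].to_numpy()
    raise KeyError(f"no sampled node with clade {want}")
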