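"""Time-reversible nucleotide substitution models and the likelihood engine.

Implements the nested JC / K80 / HKY / GTR family with optional
discrete-gamma rate heterogeneity (+G) and a proportion of invariant
sites (+I), pairwise ML distances, Felsenstein-pruning log-likelihoods
with site-pattern compression, coordinate-wise branch-length and
parameter optimization, and AIC model ranking.

Rate matrices are scaled so one unit of branch length equals one
expected substitution per site, accounting for +G (category rates have
mean one) and +I (variable sites are sped up by 1/(1-p_inv)).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from .alignment import _CHAR2CODE, Alignment
from .trees import Tree

BASES = "ACGT"
# exchangeability order: AC, AG, AT, CG, CT, GT
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
_MODEL_NAMES = ("JC", "K80", "HKY", "GTR")


class SaturationError(ValueError):
    """Raised when a pairwise distance cannot be estimated (saturation)."""


# ----------------------------------------------------------------------
# model definition
# ----------------------------------------------------------------------

@dataclass
class SubstitutionModel:
    """A reversible DNA substitution model, optionally +G and/or +I."""

    name: str = "HKY"
    base_freqs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    kappa: float = 2.0
    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6))
    gamma_shape: Optional[float] = None
    n_gamma_categories: int = 4
    p_invariant: Optional[float] = None

    def __post_init__(self) -> None:
        if self.name not in _MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}")
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        if self.name in ("JC", "K80"):
            self.base_freqs = np.full(4, 0.25)
        if not np.all(self.base_freqs > 0):
            raise ValueError("base frequencies must be positive")
        self.base_freqs = self.base_freqs / self.base_freqs.sum()
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be > 0")
        if self.p_invariant is not None and not 0 <= self.p_invariant < 1:
            raise ValueError("p_invariant must lie in [0, 1)")

    # -- spec strings: "GTR+G4+I", "HKY+G", "JC" --------------------------
    @classmethod
    def from_spec(cls, spec: str, base_freqs=None) -> "SubstitutionModel":
        parts = spec.upper().split("+")
        name = parts[0]
        if name not in _MODEL_NAMES:
            raise ValueError(f"unknown model spec {spec!r}")
        gamma, ncat, pinv = None, 4, None
        for token in parts[1:]:
            if token == "I":
                pinv = 0.0
            elif token.startswith("G"):
                gamma = 1.0
                if token[1:]:
                    ncat = int(token[1:])
            else:
                raise ValueError(f"unknown model component {token!r} in {spec!r}")
        kw = {}
        if base_freqs is not None:
            kw["base_freqs"] = base_freqs
        return cls(name=name, gamma_shape=gamma, n_gamma_categories=ncat,
                   p_invariant=pinv, **kw)

    @property
    def spec(self) -> str:
        s = self.name
        if self.gamma_shape is not None:
            s += f"+G{self.n_gamma_categories}"
        if self.p_invariant is not None:
            s += "+I"
        return s

    def n_free_parameters(self) -> int:
        """Modeltest-style parameter count (branch lengths excluded)."""
        k = 0
        if self.name in ("HKY", "GTR"):
            k += 3                      # frequencies
        if self.name in ("K80", "HKY"):
            k += 1                      # kappa
        elif self.name == "GTR":
            k += 5                      # exchangeabilities (one fixed)
        if self.gamma_shape is not None:
            k += 1
        if self.p_invariant is not None:
            k += 1
        return k

    # -- rate matrix ------------------------------------------------------
    def _raw_exchangeabilities(self) -> np.ndarray:
        if self.name == "JC":
            return np.ones(6)
        if self.name in ("K80", "HKY"):
            s = np.ones(6)
            s[1] = s[4] = self.kappa    # AG and CT are transitions
            return s
        return self.exchangeabilities

    def rate_matrix(self) -> np.ndarray:
        """Scaled generator Q with unit expected substitution rate."""
        pi = self.base_freqs
        s = self._raw_exchangeabilities()
        Q = np.zeros((4, 4))
        for (i, j), sij in zip(_PAIRS, s):
            Q[i, j] = sij * pi[j]
            Q[j, i] = sij * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q))
        Q /= mu
        if self.p_invariant:
            Q /= (1.0 - self.p_invariant)
        return Q

    def _eigen(self):
        # symmetric decomposition of the reversible generator
        pi = self.base_freqs
        Q = self.rate_matrix()
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)          # symmetric up to rounding for reversible Q
        lam, U = np.linalg.eigh(B)
        A = U / sq[:, None]
        Ainv = U.T * sq[None, :]
        return lam, A, Ainv

    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return discretize_gamma(self.gamma_shape, self.n_gamma_categories)


def discretize_gamma(alpha: float, n_categories: int) -> np.ndarray:
    """Equal-probability gamma categories, mean-of-quantile-interval rates.

    The gamma has shape ``alpha`` and mean one; the returned rates are
    renormalized so their average is exactly one.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if n_categories < 1:
        raise ValueError("need >= 1 category")
    return _discretize_gamma_cached(float(alpha), int(n_categories)).copy()


@lru_cache(maxsize=256)
def _discretize_gamma_cached(alpha: float, n_categories: int) -> np.ndarray:
    if n_categories == 1:
        return np.ones(1)
    scale = 1.0 / alpha
    edges = gamma_dist.ppf(np.linspace(0, 1, n_categories + 1), a=alpha,
                           scale=scale)
    # mean over [q_k, q_{k+1}] of the gamma(alpha) density equals the
    # gamma(alpha+1) probability of the interval, times n
    cdf_hi = gamma_dist.cdf(edges[1:], a=alpha + 1, scale=scale)
    cdf_lo = gamma_dist.cdf(edges[:-1], a=alpha + 1, scale=scale)
    rates = n_categories * (cdf_hi - cdf_lo)
    return rates / rates.mean()


def transition_probabilities(model: SubstitutionModel, t) -> np.ndarray:
    """P(t) = exp(Qt); accepts a scalar or an array of branch lengths."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("branch length must be >= 0")
    lam, A, Ainv = model._eigen()
    expo = np.exp(np.multiply.outer(t_arr, lam))       # (..., 4)
    P = np.einsum("ij,...j,jk->...ik", A, expo, Ainv)
    return np.clip(P, 0.0, None)


# ----------------------------------------------------------------------
# pairwise distances
# ----------------------------------------------------------------------

def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8)
    if hasattr(seq, "seq"):
        seq = seq.seq
    return _CHAR2CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def pairwise_distance(seq_a, seq_b, model: SubstitutionModel,
                      t_max: float = 15.0) -> float:
    """ML evolutionary distance between two sequences under ``model``.

    Plain JC uses the closed form; every other model maximizes the
    two-sequence likelihood over the divergence time numerically, with
    base frequencies taken from the pair.  Saturated pairs raise
    :class:`SaturationError`.
    """
    a, b = _as_codes(seq_a), _as_codes(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    ok = (a < 4) & (b < 4)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no jointly non-missing columns")
    counts = np.bincount((a[ok] * 4 + b[ok]).astype(int), minlength=16
                         ).reshape(4, 4).astype(float)
    n_diff = n - np.trace(counts)
    if n_diff == 0:
        return 0.0

    if model.name == "JC" and model.gamma_shape is None and not model.p_invariant:
        p = n_diff / n
        if p >= 0.75:
            raise SaturationError(f"JC distance undefined at p={p:.4f} >= 3/4")
        return float(-0.75 * np.log1p(-4.0 * p / 3.0))

    freqs = (counts.sum(axis=1) + counts.sum(axis=0)) / (2.0 * n)
    freqs = np.clip(freqs, 1e-6, None)
    m = replace(model, base_freqs=freqs) if model.name in ("HKY", "GTR") \
        else replace(model)
    rates = m.category_rates()
    pinv = m.p_invariant or 0.0
    pi = m.base_freqs

    def neg_lnl(t: float) -> float:
        P = transition_probabilities(m, t * rates)        # (ncat, 4, 4)
        joint = pi[None, :, None] * P                     # (ncat, 4, 4)
        lik = joint.mean(axis=0)
        if pinv:
            lik = pinv * np.diag(pi) + (1 - pinv) * lik
        with np.errstate(divide="ignore"):
            ll = counts * np.log(np.where(lik > 0, lik, 1.0))
            ll[(counts > 0) & (lik <= 0)] = -np.inf
        return -ll.sum()

    res = minimize_scalar(neg_lnl, bounds=(1e-9, t_max), method="bounded",
                          options={"xatol": 1e-10})
    t_hat = float(res.x)
    if not res.success or t_hat > 0.98 * t_max:
        raise SaturationError(
            f"pairwise distance did not converge below {t_max} "
            f"(observed difference proportion {n_diff / n:.4f})")
    return t_hat


def distance_matrix(alignment: Alignment, model: SubstitutionModel) -> pd.DataFrame:
    """Symmetric matrix of pairwise ML distances (substitutions/site)."""
    n = alignment.n_taxa
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pairwise_distance(alignment.codes[i], alignment.codes[j], model)
        D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=alignment.taxa, columns=alignment.taxa)


def empirical_base_freqs(alignment: Alignment) -> np.ndarray:
    counts = alignment.state_counts().sum(axis=1).astype(float)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


# ----------------------------------------------------------------------
# pruning likelihood
# ----------------------------------------------------------------------

def _compress(codes: np.ndarray):
    patterns, counts = np.unique(codes, axis=1, return_counts=True)
    return patterns, counts.astype(float)


def _pattern_lnl(tree: Tree, patterns: np.ndarray, weights: np.ndarray,
                 taxa: Sequence[str], model: SubstitutionModel) -> float:
    row_of = {t: i for i, t in enumerate(taxa)}
    rates = model.category_rates()
    ncat = len(rates)
    pi = model.base_freqs
    pinv = model.p_invariant or 0.0
    n_pat = patterns.shape[1]

    nodes = list(tree.postorder())
    lengths = np.array([n.length or 0.0 for n in nodes])
    ts = np.multiply.outer(lengths, rates)                # (n_nodes, ncat)
    P = transition_probabilities(model, ts)               # (n_nodes, ncat, 4, 4)

    Pt = P.transpose(0, 1, 3, 2)                          # for right-matmul
    partial: dict[int, np.ndarray] = {}
    for k, node in enumerate(nodes):
        if node.is_leaf:
            codes = patterns[row_of[node.label]]
            part = np.zeros((n_pat, 4))                   # broadcasts over cats
            obs = codes < 4
            part[np.arange(n_pat)[obs], codes[obs]] = 1.0
            part[~obs] = 1.0
        else:
            part = None
            for child in node.children:
                ck, cpart = partial.pop(id(child))
                term = cpart @ Pt[ck]                     # (ncat, n_pat, 4)
                part = term if part is None else part * term
        partial[id(node)] = (k, part)

    _, root_part = partial[id(tree.root)]
    site_lik = (root_part @ pi).mean(axis=0)              # (n_pat,)
    if pinv:
        compat = np.ones((n_pat, 4), dtype=bool)
        for t in taxa:
            codes = patterns[row_of[t]]
            obs = codes < 4
            row = np.ones((n_pat, 4), dtype=bool)
            row[obs] = False
            row[np.arange(n_pat)[obs], codes[obs]] = True
            compat &= row
        inv_lik = (compat * pi).sum(axis=1)
        site_lik = pinv * inv_lik + (1 - pinv) * site_lik
    if np.any(site_lik <= 0):
        return -np.inf
    return float(weights @ np.log(site_lik))


def log_likelihood(tree: Tree,
                   alignment: Alignment,
                   model: Union[SubstitutionModel, dict]) -> float:
    """Felsenstein-pruning log-likelihood of ``alignment`` on ``tree``.

    ``model`` is a single :class:`SubstitutionModel`, or a mapping
    partition-name -> model when the alignment carries a partition; the
    per-partition likelihoods share the topology and are summed.  Gaps,
    Ns and ambiguity codes are missing data.
    """
    tips = set(tree.tip_labels())
    taxa = set(alignment.taxa)
    if tips != taxa:
        raise ValueError(
            f"tree/alignment taxa mismatch: only-in-tree={sorted(tips - taxa)}, "
            f"only-in-alignment={sorted(taxa - tips)}")
    if isinstance(model, dict):
        if alignment.partition is None:
            raise ValueError("per-partition models require a partitioned alignment")
        full = alignment.partition.with_default(alignment.column_count)
        total = 0.0
        for name in full.names():
            if name not in model:
                raise ValueError(f"no model supplied for partition {name!r}")
            cols = full.columns(name)
            if len(cols) == 0:
                continue
            sub = alignment.take_columns(cols)
            patterns, weights = _compress(sub.codes)
            total += _pattern_lnl(tree, patterns, weights, sub.taxa, model[name])
        return total
    patterns, weights = _compress(alignment.codes)
    return _pattern_lnl(tree, patterns, weights, alignment.taxa, model)


# ----------------------------------------------------------------------
# optimization
# ----------------------------------------------------------------------

def optimize_branch_lengths(tree: Tree, alignment: Alignment,
                            model: SubstitutionModel,
                            tol: float = 1e-6, max_sweeps: int = 20,
                            b_max: float = 10.0) -> tuple[Tree, float]:
    """Coordinate-wise ML branch lengths on a fixed topology.

    Cycles bounded 1-D optimizations over every branch until a full
    sweep improves the log-likelihood by less than ``tol``.  Returns the
    optimized copy of the tree and its log-likelihood (monotone in the
    iterates).
    """
    tree = tree.copy()
    patterns, weights = _compress(alignment.codes)
    taxa = alignment.taxa
    branches = [n for n in tree.postorder() if n is not tree.root]
    for n in branches:
        if n.length is None:
            n.length = 0.1

    def lnl() -> float:
        return _pattern_lnl(tree, patterns, weights, taxa, model)

    current = lnl()
    if not np.isfinite(current):
        raise ValueError("non-finite starting log-likelihood")
    for _ in range(max_sweeps):
        before = current
        for node in branches:
            prev = node.length
            def neg(x: float, node=node) -> float:
                node.length = x
                return -lnl()
            res = minimize_scalar(neg, bounds=(0.0, b_max), method="bounded",
                                  options={"xatol": 1e-8})
            if -res.fun >= current:
                node.length = float(res.x)
                current = -res.fun
            else:               # bounded search noise: keep previous value
                node.length = prev
        if current - before < tol:
            break
    return tree, current


_PARAM_BOUNDS = {
    "kappa": (0.05, 100.0),
    "alpha": (0.02, 100.0),
    "p_invariant": (0.0, 0.999),
    "exch": (1e-3, 100.0),
}


def fit_model(tree: Tree, alignment: Alignment, model_family: str,
              n_cycles: int = 3, tol: float = 1e-4,
              empirical_freqs: bool = True) -> tuple[SubstitutionModel, Tree, float]:
    """Fit free parameters of ``model_family`` (e.g. ``"GTR+G4+I"``).

    Alternates branch-length optimization with bounded 1-D searches over
    each free model parameter.  Base frequencies are empirical (the
    Modeltest convention).  Returns (model, tree with ML branch
    lengths, log-likelihood).
    """
    freqs = empirical_base_freqs(alignment) if empirical_freqs else None
    model = SubstitutionModel.from_spec(model_family, base_freqs=freqs)
    patterns, weights = _compress(alignment.codes)
    taxa = alignment.taxa

    def score(m: SubstitutionModel, t: Tree) -> float:
        return _pattern_lnl(t, patterns, weights, taxa, m)

    tree, current = optimize_branch_lengths(tree, alignment, model)

    def opt_scalar(setter, lo, hi, m, t):
        def neg(x):
            return -score(setter(m, x), t)
        res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        return setter(m, float(res.x)), -res.fun

    for _ in range(n_cycles):
        before = current
        if model.name in ("K80", "HKY"):
            model, current = opt_scalar(
                lambda m, x: replace(m, kappa=x), *_PARAM_BOUNDS["kappa"],
                model, tree)
        elif model.name == "GTR":
            for idx in range(5):        # GT exchangeability fixed at 1
                def set_exch(m, x, idx=idx):
                    ex = m.exchangeabilities.copy()
                    ex[idx] = x
                    return replace(m, exchangeabilities=ex)
                model, current = opt_scalar(
                    set_exch, *_PARAM_BOUNDS["exch"], model, tree)
        if model.gamma_shape is not None:
            model, current = opt_scalar(
                lambda m, x: replace(m, gamma_shape=x),
                *_PARAM_BOUNDS["alpha"], model, tree)
        if model.p_invariant is not None:
            model, current = opt_scalar(
                lambda m, x: replace(m, p_invariant=x),
                *_PARAM_BOUNDS["p_invariant"], model, tree)
        tree, current = optimize_branch_lengths(tree, alignment, model)
        if current - before < tol:
            break
    return model, tree, current


DEFAULT_CANDIDATES = ("JC", "K80", "HKY", "GTR",
                      "JC+G4", "K80+G4", "HKY+G4", "GTR+G4",
                      "HKY+G4+I", "GTR+G4+I")


def select_model(alignment: Alignment, tree: Tree,
                 candidates: Sequence[str] = DEFAULT_CANDIDATES) -> pd.DataFrame:
    """AIC ranking of candidate substitution models on a fixed topology.

    AIC = 2k - 2 lnL with k the number of free model parameters
    (empirical frequencies count 3, exchangeabilities 5, kappa, alpha
    and p_inv one each).  Rows are sorted by ascending AIC; ties go to
    the model with fewer parameters.
    """
    rows = []
    for spec in candidates:
        model, _, lnl = fit_model(tree, alignment, spec)
        k = model.n_free_parameters()
        rows.append({"model": model.spec, "k": k, "lnL": lnl,
                     "AIC": 2.0 * k - 2.0 * lnl})
    table = pd.DataFrame(rows).sort_values(
        ["AIC", "k"], kind="stable").reset_index(drop=True)
    return table
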