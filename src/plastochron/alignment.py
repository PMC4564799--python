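"""Alignment container, site-pattern classification and difference counts.

The classification mirrors the MEGA conventions: with gaps treated as
missing data a column is *constant* when at most one distinct
non-missing state is present, *variable* when two or more are present,
and *parsimony-informative* when at least two states each occur in at
least two taxa.  Ambiguity codes (R, Y, ..., N) and gaps are missing in
every count.  The alternative gap mode deletes every column containing
a gap before classifying, reporting the deleted columns separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import PartitionSet, SequenceRecord

# state codes: 0..3 = ACGT, 4 = gap, 5 = other missing (N / ambiguity)
A, C, G, T, GAP, MISSING = range(6)
_CHAR2CODE = np.full(256, MISSING, dtype=np.uint8)
for i, base in enumerate(b"ACGT"):
    _CHAR2CODE[base] = i
    _CHAR2CODE[base + 32] = i
_CHAR2CODE[ord("-")] = GAP

GapMode = str  # "missing" | "delete_columns"
_GAP_MODES = ("missing", "delete_columns")


def _check_gap_mode(gap_mode: str) -> None:
    if gap_mode not in _GAP_MODES:
        raise ValueError(f"gap_mode must be one of {_GAP_MODES}, got {gap_mode!r}")


@dataclass
class SiteClassification:
    n_constant: int
    n_variable: int
    n_parsimony_informative: int
    n_singleton: int
    n_excluded: int
    column_count: int

    def __post_init__(self) -> None:
        assert self.n_constant + self.n_variable + self.n_excluded == self.column_count
        assert self.n_parsimony_informative + self.n_singleton == self.n_variable


class Alignment:
    """Taxa-by-columns character matrix over the IUPAC DNA alphabet."""

    def __init__(self, taxa: Sequence[str], rows: Sequence[str],
                 partition: Optional[PartitionSet] = None):
        taxa = list(taxa)
        if len(taxa) < 2:
            raise ValueError("alignment needs >= 2 taxa")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        if len(rows) != len(taxa):
            raise ValueError("one row per taxon required")
        self.taxa = taxa
        self.chars = np.frombuffer(
            "".join(r.upper() for r in rows).encode("ascii"), dtype=np.uint8
        ).reshape(len(taxa), -1).copy()
        self.codes = _CHAR2CODE[self.chars]
        if partition is not None:
            partition.check_bounds(self.column_count)
        self.partition = partition

    # ------------------------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord],
                     partition: Optional[PartitionSet] = None) -> "Alignment":
        records = list(records)
        return cls([r.id for r in records], [r.seq for r in records], partition)

    def to_records(self) -> list[SequenceRecord]:
        return [SequenceRecord(t, self.row(t)) for t in self.taxa]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def column_count(self) -> int:
        return self.chars.shape[1]

    def index(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"taxon not in alignment: {taxon!r}") from None

    def row(self, taxon: str) -> str:
        return self.chars[self.index(taxon)].tobytes().decode("ascii")

    def subset_taxa(self, keep: Sequence[str]) -> "Alignment":
        rows = [self.row(t) for t in keep]
        return Alignment(list(keep), rows, self.partition)

    def drop_taxa(self, drop: Sequence[str]) -> "Alignment":
        for t in drop:
            self.index(t)  # raise on unknown
        keep = [t for t in self.taxa if t not in set(drop)]
        if len(keep) < 2:
            raise ValueError("taxon exclusion leaves fewer than 2 taxa")
        return self.subset_taxa(keep)

    def take_columns(self, cols: np.ndarray) -> "Alignment":
        sub = self.chars[:, cols]
        rows = [sub[i].tobytes().decode("ascii") for i in range(self.n_taxa)]
        return Alignment(self.taxa, rows)

    # ------------------------------------------------------------------
    def state_counts(self, codes: Optional[np.ndarray] = None) -> np.ndarray:
        """Per-column counts of A, C, G, T among non-missing states.

        Returns an array of shape (4, n_columns).
        """
        codes = self.codes if codes is None else codes
        return np.stack([(codes == s).sum(axis=0) for s in range(4)])


def classify_sites(alignment: Alignment, gap_mode: GapMode = "missing",
                   exclude_taxa: Sequence[str] = ()) -> SiteClassification:
    """Count constant / variable / parsimony-informative / singleton columns."""
    _check_gap_mode(gap_mode)
    aln = alignment.drop_taxa(exclude_taxa) if exclude_taxa else alignment
    total = aln.column_count
    n_excluded = 0
    if gap_mode == "delete_columns":
        has_gap = (aln.codes == GAP).any(axis=0)
        n_excluded = int(has_gap.sum())
        if n_excluded == total:
            return SiteClassification(0, 0, 0, 0, n_excluded, total)
        counts = aln.state_counts(aln.codes[:, ~has_gap])
    else:
        counts = aln.state_counts()
    n_states = (counts > 0).sum(axis=0)
    n_states_ge2 = (counts >= 2).sum(axis=0)
    variable = n_states >= 2
    informative = variable & (n_states_ge2 >= 2)
    n_variable = int(variable.sum())
    n_pi = int(informative.sum())
    n_constant = counts.shape[1] - n_variable
    return SiteClassification(
        n_constant=n_constant,
        n_variable=n_variable,
        n_parsimony_informative=n_pi,
        n_singleton=n_variable - n_pi,
        n_excluded=n_excluded,
        column_count=total,
    )


def pairwise_differences(alignment: Alignment, taxon_a: str, taxon_b: str,
                         gap_mode: GapMode = "missing") -> int:
    """Number of columns where both taxa carry differing non-missing states."""
    _check_gap_mode(gap_mode)
    aln = alignment
    if gap_mode == "delete_columns":
        aln = strip_gap_columns(alignment)
    a = aln.codes[aln.index(taxon_a)]
    b = aln.codes[aln.index(taxon_b)]
    ok = (a < 4) & (b < 4)
    return int(((a != b) & ok).sum())


def pairwise_difference_matrix(alignment: Alignment,
                               gap_mode: GapMode = "missing") -> np.ndarray:
    n = alignment.n_taxa
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_differences(alignment, alignment.taxa[i],
                                     alignment.taxa[j], gap_mode)
            out[i, j] = out[j, i] = d
    return out


def strip_gap_columns(alignment: Alignment) -> Alignment:
    """Drop every column containing a gap in any taxon."""
    keep = ~(alignment.codes == GAP).any(axis=0)
    if not keep.any():
        raise ValueError("deleting gapped columns leaves an empty alignment")
    out = alignment.take_columns(np.flatnonzero(keep))
    out.partition = None  # column coordinates no longer apply
    return out
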