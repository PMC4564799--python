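"""Readers and writers for FASTA, GenBank, Newick and NEXUS charsets.

All coordinates exposed to the rest of the package are 0-based
half-open; GenBank's 1-based inclusive convention is converted exactly
once, here.  Parsing of the standard flat formats is delegated to
Biopython and DendroPy; only the conversion into the package's own
types lives in this module.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import dendropy
from Bio import SeqIO

from .trees import Node, Tree

IUPAC_DNA = set("ACGTRYSWKMBDHVN-")


@dataclass
class SequenceRecord:
    """A single labelled DNA sequence (taxon or accession)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq.upper()) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-IUPAC characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Feature:
    """A typed GenBank feature with 0-based half-open parts."""

    kind: str                       # gene / CDS / tRNA / rRNA / ...
    parts: list[tuple[int, int]]    # half-open intervals, ascending
    strand: int                     # +1 / -1
    qualifiers: dict = field(default_factory=dict)

    @property
    def start(self) -> int:
        return self.parts[0][0]

    @property
    def end(self) -> int:
        return self.parts[-1][1]


@dataclass
class PartitionSet:
    """Named, pairwise-disjoint half-open column intervals of an alignment.

    Columns not covered by any named partition implicitly form a default
    partition when one is requested via :meth:`with_default`.
    """

    partitions: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        covered: list[tuple[int, int]] = []
        for name, ivals in self.partitions.items():
            for lo, hi in ivals:
                if not (0 <= lo < hi):
                    raise ValueError(f"bad interval [{lo},{hi}) in {name!r}")
                covered.append((lo, hi))
        covered.sort()
        for (a0, a1), (b0, b1) in zip(covered, covered[1:]):
            if b0 < a1:
                raise ValueError(
                    f"overlapping partition intervals [{a0},{a1}) and [{b0},{b1})")

    def names(self) -> list[str]:
        return list(self.partitions)

    def columns(self, name: str):
        import numpy as np

        ivals = self.partitions[name]
        return np.concatenate([np.arange(lo, hi) for lo, hi in ivals]) \
            if ivals else np.empty(0, dtype=int)

    def check_bounds(self, n_columns: int) -> None:
        for name, ivals in self.partitions.items():
            for lo, hi in ivals:
                if hi > n_columns:
                    raise ValueError(
                        f"partition {name!r} interval [{lo},{hi}) exceeds "
                        f"alignment width {n_columns}")

    def with_default(self, n_columns: int, name: str = "unassigned") -> "PartitionSet":
        """Return a copy whose partitions cover every column."""
        self.check_bounds(n_columns)
        import numpy as np

        mask = np.zeros(n_columns, dtype=bool)
        for ivals in self.partitions.values():
            for lo, hi in ivals:
                mask[lo:hi] = True
        gaps: list[tuple[int, int]] = []
        i = 0
        while i < n_columns:
            if not mask[i]:
                j = i
                while j < n_columns and not mask[j]:
                    j += 1
                gaps.append((i, j))
                i = j
            else:
                i += 1
        parts = {k: list(v) for k, v in self.partitions.items()}
        if gaps:
            parts[name] = gaps
        return PartitionSet(parts)


# ----------------------------------------------------------------------
# FASTA
# ----------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file; sequences are upper-cased.

    Duplicate ids and empty files raise ``ValueError``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path],
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ----------------------------------------------------------------------
# GenBank
# ----------------------------------------------------------------------

def align_with_mafft(records: Iterable[SequenceRecord],
                     mafft_args: Sequence[str] = ("--auto",)
                     ) -> list[SequenceRecord]:
    """Convenience hook: align unaligned sequences by shelling out to MAFFT.

    Requires ``mafft`` on PATH; the analysis core always consumes
    pre-aligned input, so this helper is not exercised by the tests.
    """
    import subprocess
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        src = Path(tmp) / "in.fasta"
        dst = Path(tmp) / "out.fasta"
        write_fasta(records, src)
        with open(dst, "w") as fh:
            subprocess.run(["mafft", *mafft_args, str(src)], stdout=fh,
                           stderr=subprocess.DEVNULL, check=True)
        return read_fasta(dst)


def read_genbank(path: Union[str, Path]) -> tuple[SequenceRecord, list[Feature]]:
    """Read one GenBank flat-file record: sequence plus typed features.

    Feature locations are converted to 0-based half-open intervals on
    the forward strand; compound (join) locations keep one part per
    exon.  Trans-spliced or zero-length features are dropped.
    """
    try:
        rec = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise ValueError(f"no GenBank record found in {path}") from None
    if len(rec.seq) == 0:
        raise ValueError(f"GenBank record {rec.id!r} has no sequence")
    features: list[Feature] = []
    for feat in rec.features:
        if feat.type == "source":
            continue
        try:
            parts = sorted(
                (int(p.start), int(p.end)) for p in feat.location.parts)
        except Exception:
            continue
        if any(hi <= lo for lo, hi in parts):
            continue
        strand = feat.location.strand or 1
        quals = {k: v[0] if isinstance(v, list) and v else v
                 for k, v in feat.qualifiers.items()}
        features.append(Feature(feat.type, parts, int(strand), quals))
    return SequenceRecord(rec.id, str(rec.seq).upper()), features


def partitions_from_features(features: list[Feature], seq_length: int
                             ) -> PartitionSet:
    """Derive a coding / intergenic partition from CDS features.

    ``coding`` is the union of all CDS parts; ``intergenic`` is its
    complement.  The result is the partition scheme used when dating a
    dataset whose only structural annotation is GenBank CDS features.
    """
    import numpy as np

    mask = np.zeros(seq_length, dtype=bool)
    for feat in features:
        if feat.kind != "CDS":
            continue
        for lo, hi in feat.parts:
            mask[lo:min(hi, seq_length)] = True
    coding: list[tuple[int, int]] = []
    i = 0
    while i < seq_length:
        if mask[i]:
            j = i
            while j < seq_length and mask[j]:
                j += 1
            coding.append((i, j))
            i = j
        else:
            i += 1
    ps = PartitionSet({"coding": coding})
    return ps.with_default(seq_length, "intergenic")


# ----------------------------------------------------------------------
# Newick / NEXUS
# ----------------------------------------------------------------------

def _from_dendropy(dnode: dendropy.Node) -> Node:
    label = dnode.taxon.label if dnode.taxon is not None else dnode.label
    node = Node(label=label, length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def read_newick(source: Union[str, Path]) -> Tree:
    """Parse a Newick (or NEXUS trees-block) source into a :class:`Tree`."""
    text = source if isinstance(source, str) and ";" in source \
        else Path(source).read_text()
    schema = "nexus" if text.lstrip().lower().startswith("#nexus") \
        else "newick"
    try:
        dtree = dendropy.Tree.get(
            data=text, schema=schema,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"invalid {schema} tree: {exc}") from exc
    tree = Tree(_from_dendropy(dtree.seed_node))
    labels = tree.tip_labels()
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels in Newick input")
    return tree


def write_newick(tree: Tree, path: Optional[Union[str, Path]] = None,
                 supports: bool = False) -> str:
    text = tree.to_newick(supports=supports)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


_CHARSET_RE = re.compile(
    r"charset\s+(\S+?)\s*=\s*([^;]+);", re.IGNORECASE)


def read_nexus_charsets(path: Union[str, Path]) -> PartitionSet:
    """Read ``charset name = 1-100 200-300;`` blocks from a NEXUS file.

    NEXUS positions are 1-based inclusive and are converted to the
    package convention here.  Step sizes (``\\3`` codon notation) are
    not supported.
    """
    text = Path(path).read_text()
    parts: dict[str, list[tuple[int, int]]] = {}
    for m in _CHARSET_RE.finditer(text):
        name, body = m.group(1), m.group(2)
        ivals: list[tuple[int, int]] = []
        for token in body.split():
            if "\\" in token:
                raise ValueError(f"charset step notation unsupported: {token}")
            if "-" in token:
                lo, hi = token.split("-")
                ivals.append((int(lo) - 1, int(hi)))
            else:
                pos = int(token)
                ivals.append((pos - 1, pos))
        parts[name] = ivals
    if not parts:
        raise ValueError(f"no charset blocks found in {path}")
    return PartitionSet(parts)


def read_partition_file(path: Union[str, Path]) -> PartitionSet:
    """Read a flat ``name = start-end[, start-end...]`` partition file.

    Coordinates are 1-based inclusive (the convention of RAxML-style
    partition files); converted on input.
    """
    parts: dict[str, list[tuple[int, int]]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, body = line.partition("=")
        name = name.strip()
        ivals = []
        for chunk in body.replace(",", " ").split():
            lo, _, hi = chunk.partition("-")
            hi = hi or lo
            ivals.append((int(lo) - 1, int(hi)))
        parts[name] = ivals
    if not parts:
        raise ValueError(f"no partitions found in {path}")
    return PartitionSet(parts)


def write_partition_file(ps: PartitionSet, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for name, ivals in ps.partitions.items():
            body = ", ".join(f"{lo + 1}-{hi}" for lo, hi in ivals)
            fh.write(f"{name} = {body}\n")
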