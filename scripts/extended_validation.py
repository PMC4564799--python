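#!/usr/bin/env python
"""Prepare the real *Oryza* plastome data for the extended-validation tests.

Downloads the deposited *Oryza* chloroplast genomes from GenBank, aligns them
with MAFFT, and writes the inputs that
``tests/test_acceptance.py::TestReal*`` consume:

    data/real/aa_alignment.fasta       ten AA accessions + out-group
    data/real/dating_alignment.fasta   + Zea mays / Triticum aestivum
    data/real/dating_topology.nwk      rooted topology for the dating run

Requires network access and ``mafft`` on PATH; run time is dominated by
the download and the whole-plastome alignment.  The deposited
accessions are KM881634-KM881643 plus the japonica reference GU592207;
the *O. meridionalis*, *O. nivara*, *O. rufipogon* and *indica*
plastomes and the two calibration plastomes come from GenBank and can
be overridden with --accessions (accession=label pairs), since the
original supplementary table is the authoritative list.

    python scripts/extended_validation.py --out data/real
"""

from __future__ import annotations

import argparse
import subprocess
import sys
import tempfile
import urllib.request
from pathlib import Path

EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nucleotide&id={acc}&rettype=fasta&retmode=text")

# deposited genomes (study) and the japonica reference
DEFAULT_ACCESSIONS = {
    "KM881634": "O_barthii_1",
    "KM881635": "O_barthii_2",
    "KM881636": "O_barthii_3",
    "KM881637": "O_barthii_4",
    "KM881638": "O_glaberrima_1",
    "KM881639": "O_glaberrima_2",
    "KM881640": "O_glumaepatula",
    "KM881641": "O_longistaminata_1",
    "KM881642": "O_longistaminata_2",
    "KM881643": "O_officinalis",
    "GU592207": "GU592207",            # japonica reference
    # GenBank plastomes for the remaining taxa; the original supplementary
    # table is authoritative -- override with --accessions if needed
    "JN005833": "O_nivara",
    "JN005834": "indica_1",
    "KF428978": "indica_2",
    "JN005832": "O_rufipogon",
    "KJ830774": "O_meridionalis",
    # calibration plastomes
    "X86563": "zea_mays",
    "AB042240": "triticum_aestivum",
}


def fetch(acc: str, label: str, out_dir: Path) -> Path:
    path = out_dir / f"{label}.fasta"
    if path.exists():
        return path
    with urllib.request.urlopen(EFETCH.format(acc=acc), timeout=120) as r:
        text = r.read().decode()
    lines = text.splitlines()
    lines[0] = f">{label}"
    path.write_text("\n".join(lines) + "\n")
    return path


def mafft(in_fasta: Path, out_fasta: Path) -> None:
    with open(out_fasta, "w") as fh:
        subprocess.run(["mafft", "--auto", str(in_fasta)], stdout=fh,
                       check=True)


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("data/real"))
    ap.add_argument("--accessions", nargs="*", default=[],
                    help="extra/override accession=label pairs")
    args = ap.parse_args()
    accessions = {k: v for k, v in DEFAULT_ACCESSIONS.items() if v}
    for pair in args.accessions:
        acc, _, label = pair.partition("=")
        accessions[acc] = label or acc
    args.out.mkdir(parents=True, exist_ok=True)
    raw = args.out / "raw"
    raw.mkdir(exist_ok=True)
    paths = {}
    for acc, label in accessions.items():
        print(f"fetching {acc} ({label})", file=sys.stderr)
        paths[label] = fetch(acc, label, raw)

    cal_labels = {"zea_mays", "triticum_aestivum"}
    aa_labels = [l for l in paths if l not in cal_labels]

    def align(labels, out_name):
        with tempfile.NamedTemporaryFile("w", suffix=".fa",
                                         delete=False) as fh:
            for label in labels:
                fh.write(paths[label].read_text())
            tmp = Path(fh.name)
        print(f"aligning {len(labels)} genomes -> {out_name}",
              file=sys.stderr)
        mafft(tmp, args.out / out_name)
        tmp.unlink()

    align(aa_labels, "aa_alignment.fasta")
    align(list(paths), "dating_alignment.fasta")

    # rooted dating topology: infer with the package, root between the
    # calibration pair and the Oryza clade
    sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))
    import plastochron as pc

    aln = pc.Alignment.from_records(
        pc.read_fasta(args.out / "dating_alignment.fasta"))
    nj = pc.nj_tree(aln)
    # root on the edge separating the calibration pair from Oryza, so
    # the Zea-Triticum MRCA is a proper (calibratable) clade; rooting at
    # an Oryza tip first guarantees the pair forms a below-set
    tmp_rooted = pc.root_with_outgroup(nj, "O_officinalis")
    cereal = tmp_rooted.clade_node(cal_labels)
    if {l.label for l in pc.Tree(cereal).leaves()} != cal_labels:
        raise SystemExit("Zea/Triticum do not form a clade in the NJ tree")
    rooted = tmp_rooted.reroot_on_edge(cereal, 0.5)
    (args.out / "dating_topology.nwk").write_text(rooted.to_newick() + "\n")
    print(f"wrote {args.out}/dating_topology.nwk", file=sys.stderr)
    return 0


if __name__ == "__main__":
    sys.exit(main())
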