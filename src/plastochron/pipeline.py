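"""End-to-end analysis: stats -> model selection -> NJ/MP/ML -> rooting
-> Bayesian dating, as one reproducible run.

Every stage writes a plain-text artifact into the output directory and
is seeded from the single run seed, so identical configurations yield
byte-identical trees and tables.  A manifest records a content hash for
each output.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .alignment import Alignment, classify_sites, pairwise_difference_matrix
from .dating import (CalibrationPrior, MCMCConfig, posterior_mean_chronogram,
                     run_dating_mcmc, summarize)
from .infer import bootstrap, nj_tree, root_with_outgroup
from .io import read_fasta, read_partition_file
from .models import SubstitutionModel, select_model
from .trees import Tree


@dataclass
class RunConfig:
    """Settings for a full analysis run.

    Defaults follow the conventional settings for this analysis class:
    1000 bootstrap replicates, gaps treated as missing, AIC model
    choice, GTR+G+I for ML and HKY+G4 for dating.
    """

    alignment_path: str = ""
    partition_path: Optional[str] = None
    out_dir: str = "plastochron_run"
    outgroup: Optional[str] = None
    gap_mode: str = "missing"
    bootstrap_replicates: int = 1000
    mp_addition_replicates: int = 10
    model: str = "auto"                       # "auto" = AIC choice
    model_candidates: Sequence[str] = ("JC", "K80", "HKY", "GTR",
                                       "HKY+G4", "GTR+G4", "GTR+G4+I")
    ml_model: str = "GTR+G4+I"
    dating_model: str = "HKY+G4"
    clock: str = "strict"
    # each calibration: (clade taxa tuple, density, params tuple)
    calibrations: Sequence[tuple] = ()
    chain_length: int = 1_100_000
    sample_every: int = 200
    burn_in: int = 100_000
    seed: int = 0
    run_dating: bool = True

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a flat INI-style ``key = value`` configuration file."""
        cp = configparser.ConfigParser()
        cp.read(str(path))
        g = cp["run"] if cp.has_section("run") else cp["DEFAULT"]
        kw: dict = {}
        for key in ("alignment_path", "partition_path", "out_dir", "outgroup",
                    "gap_mode", "model", "ml_model", "dating_model", "clock"):
            if g.get(key):
                kw[key] = g.get(key)
        for key in ("bootstrap_replicates", "mp_addition_replicates",
                    "chain_length", "sample_every", "burn_in", "seed"):
            if g.get(key):
                kw[key] = g.getint(key)
        if g.get("run_dating"):
            kw["run_dating"] = g.getboolean("run_dating")
        cals = []
        if cp.has_section("calibrations"):
            for _, spec in cp["calibrations"].items():
                cals.append(parse_calibration(spec))
        kw["calibrations"] = tuple(cals)
        return cls(**kw)


def parse_calibration(spec: str) -> tuple:
    """Parse ``taxon1,taxon2:normal:50:2.5`` into a calibration tuple."""
    clade, density, *params = spec.split(":")
    return (tuple(t.strip() for t in clade.split(",")), density,
            tuple(float(p) for p in params))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (paths -> hashes)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"plastochron {__version__}", f"config: {config}"]
    t_start = time.time()

    def stage(name):
        log_lines.append(f"[{time.time() - t_start:8.1f}s] {name}")

    try:
        records = read_fasta(config.alignment_path)
        partition = read_partition_file(config.partition_path) \
            if config.partition_path else None
        alignment = Alignment.from_records(records, partition)
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    exclude = [config.outgroup] if config.outgroup else []

    # 1. site statistics -------------------------------------------------
    stage("stats")
    try:
        rows = []
        for mode in ("missing", "delete_columns"):
            sc = classify_sites(alignment, mode, exclude_taxa=exclude)
            rows.append({"gap_mode": mode, **sc.__dict__})
        pd.DataFrame(rows).to_csv(out / "site_classification.tsv",
                                  sep="\t", index=False)
        diff = pairwise_difference_matrix(alignment, config.gap_mode)
        pd.DataFrame(diff, index=alignment.taxa, columns=alignment.taxa
                     ).to_csv(out / "pairwise_differences.tsv", sep="\t")
    except Exception as exc:
        raise RuntimeError(f"stage 'stats' failed: {exc}") from exc

    # 2. model selection -------------------------------------------------
    stage("modeltest")
    try:
        guide = nj_tree(alignment, SubstitutionModel.from_spec("JC"))
        aic = select_model(alignment, guide, config.model_candidates)
        aic.to_csv(out / "aic_table.tsv", sep="\t", index=False)
        ml_spec = aic.iloc[0]["model"] if config.model == "auto" \
            else config.model
    except Exception as exc:
        raise RuntimeError(f"stage 'modeltest' failed: {exc}") from exc

    # 3-5. NJ / MP / ML with bootstrap ------------------------------------
    trees: dict[str, Tree] = {}
    for method in ("nj", "parsimony", "ml"):
        stage(method)
        try:
            model = None
            if method == "nj":
                model = SubstitutionModel.from_spec("GTR+G4")
            elif method == "ml":
                model = SubstitutionModel.from_spec(str(ml_spec))
            tree, supports = bootstrap(
                alignment, method=method,
                n_replicates=config.bootstrap_replicates,
                seed=config.seed, model=model)
            trees[method] = tree
            (out / f"{method}_tree.nwk").write_text(
                tree.to_newick(supports=True) + "\n")
            supports.to_csv(out / f"{method}_supports.tsv", sep="\t",
                            index=False)
        except Exception as exc:
            raise RuntimeError(f"stage {method!r} failed: {exc}") from exc

    congruent = (trees["nj"].same_topology(trees["parsimony"])
                 and trees["nj"].same_topology(trees["ml"]))
    log_lines.append(f"topological congruence (NJ=MP=ML): {congruent}")

    # 6. rooting ----------------------------------------------------------
    stage("rooting")
    rooted = None
    if config.outgroup:
        try:
            rooted = root_with_outgroup(trees["ml"], config.outgroup)
            (out / "rooted_tree.nwk").write_text(rooted.to_newick() + "\n")
        except Exception as exc:
            raise RuntimeError(f"stage 'rooting' failed: {exc}") from exc

    # 7. dating -----------------------------------------------------------
    if config.run_dating and config.calibrations:
        stage("dating")
        try:
            topo = rooted if rooted is not None else trees["ml"]
            if len(topo.root.children) != 2:
                raise ValueError("dating requires a rooted binary topology "
                                 "(supply an out-group)")
            cals = [CalibrationPrior(frozenset(c), d, p)
                    for c, d, p in config.calibrations]
            cfg = MCMCConfig(chain_length=config.chain_length,
                             sample_every=config.sample_every,
                             burn_in=config.burn_in, seed=config.seed)
            models = None
            if alignment.partition is not None:
                full = alignment.partition.with_default(alignment.column_count)
                models = {name: SubstitutionModel.from_spec(config.dating_model)
                          for name in full.names()}
            trace = run_dating_mcmc(alignment, topo, config.clock, cals, cfg,
                                    partition_models=models)
            trace.samples.to_csv(out / "dating_trace.tsv", sep="\t",
                                 index=False)
            summ = summarize(trace)
            summ.to_csv(out / "dating_summary.tsv", sep="\t")
            chrono = posterior_mean_chronogram(trace, topo)
            (out / "chronogram.nwk").write_text(chrono.to_newick() + "\n")
            log_lines.append(
                "dating acceptance: "
                + json.dumps({k: round(v, 3) for k, v in
                              trace.acceptance.items()}))
        except Exception as exc:
            raise RuntimeError(f"stage 'dating' failed: {exc}") from exc

    # manifest + log ------------------------------------------------------
    stage("manifest")
    manifest = {}
    for p in sorted(out.iterdir()):
        if p.name in ("manifest.json", "run.log") or p.is_dir():
            continue
        manifest[p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest
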