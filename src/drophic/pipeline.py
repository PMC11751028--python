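"""End-to-end pipeline orchestration over the library modules.

A run config (YAML or dict) selects stages in the fixed order
simulate -> dedup -> cellcall -> qc -> scab -> aggregate -> insulation;
partial pipelines are supported.  Every run writes a machine-readable
JSON report with per-stage record counts, the package version, a config
hash and input checksums.  Stages never mutate their inputs; outputs are
new files in the run directory.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cellcall import adaptive_cell_call
from .contacts import DedupConfig, dedup_contacts, per_cell_stats, sort_contacts
from .genome import cpg_density, make_bins
from .matrix import aggregate, balance, insulation
from .pairs import read_pairs_frame, write_pairs_frame
from .qc import cycle_metrics
from .scab import scab_matrix, zscore_normalize
from .sim import SimConfig, sim_cells, sim_genome

__all__ = ["run_pipeline"]

STAGES = ("simulate", "dedup", "cellcall", "qc", "scab", "aggregate", "insulation")


def _hash_config(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the requested stages; returns the run report dict.

    ``config`` keys: ``stages`` (list, default all), ``seed``,
    ``sim`` (SimConfig field overrides), ``pairs`` (input pairs path
    when not simulating), ``bin_size``, ``window`` (insulation bp),
    ``target_retention``.  Missing inputs raise FileNotFoundError with
    the offending path named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", STAGES))
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; valid: {STAGES}")
    report: dict = {
        "version": __version__,
        "config_hash": _hash_config(config),
        "stages": {},
        "inputs": {},
    }
    seed = int(config.get("seed", 0))
    simcfg = SimConfig(seed=seed, **config.get("sim", {}))

    contacts = None
    chrom_sizes = None
    genome = None
    if "simulate" in stages:
        genome = sim_genome(simcfg)
        sc = sim_cells(simcfg, genome)
        contacts = sc.contacts
        chrom_sizes = simcfg.chrom_sizes
        pairs_path = outdir / "simulated.pairs.tsv"
        write_pairs_frame(pairs_path, contacts, chrom_sizes)
        sc.barcode_truth.to_csv(outdir / "barcode_truth.tsv", sep="\t", index=False)
        genome.write_fasta(outdir / "genome.fa")
        report["stages"]["simulate"] = {
            "n_emitted": int(len(contacts)),
            "n_barcodes": int(sc.barcode_truth.shape[0]),
        }
    elif any(s in stages for s in STAGES[1:]):
        pairs_path = config.get("pairs")
        if not pairs_path or not Path(pairs_path).exists():
            raise FileNotFoundError(f"input pairs file not found: {pairs_path!r}")
        report["inputs"][str(pairs_path)] = _checksum(pairs_path)
        contacts, chrom_sizes = read_pairs_frame(pairs_path)

    chrom_order = {c: i for i, c in enumerate(chrom_sizes)} if chrom_sizes else {}
    unique = contacts
    dup_counts: dict = {}
    if "dedup" in stages:
        dcfg = DedupConfig(**config.get("dedup", {}))
        unique, dup_counts = dedup_contacts(sort_contacts(contacts, chrom_order), dcfg)
        write_pairs_frame(outdir / "unique.pairs.tsv", unique, chrom_sizes)
        report["stages"]["dedup"] = {
            "n_in": int(len(contacts)),
            "n_unique": int(len(unique)),
            "n_duplicates": int(sum(dup_counts.values())),
        }

    called = None
    if "cellcall" in stages:
        stats = per_cell_stats(unique, dup_counts)
        stats.to_csv(outdir / "cellstats.tsv", sep="\t", index=False)
        counts = stats.set_index("barcode")["n_unique"]
        knee = adaptive_cell_call(
            counts, target_retention=float(config.get("target_retention", 0.85))
        )
        called = knee.called_barcodes
        (outdir / "called_barcodes.txt").write_text(
            "\n".join(sorted(called)) + "\n"
        )
        report["stages"]["cellcall"] = {
            "sensitivity": knee.sensitivity,
            "threshold_count": knee.threshold_count,
            "retained_fraction": knee.retained_fraction,
            "n_called": len(called),
            "warning": knee.warning,
        }
        unique = unique[unique["barcode"].isin(called)].reset_index(drop=True)

    if "qc" in stages:
        cyc = cycle_metrics(unique)
        cyc.to_csv(outdir / "cycle_metrics.tsv", sep="\t", index=False)
        report["stages"]["qc"] = {"n_cells": int(len(cyc))}

    bins = make_bins(chrom_sizes, int(config.get("bin_size", simcfg.bin_size)))
    mat = None
    if "scab" in stages:
        if genome is not None:
            cpg = cpg_density(genome.sequences, bins)
        else:
            fasta = config.get("fasta")
            if not fasta or not Path(fasta).exists():
                raise FileNotFoundError(f"FASTA not found: {fasta!r}")
            report["inputs"][str(fasta)] = _checksum(fasta)
            cpg = cpg_density(fasta, bins)
        mat = scab_matrix(unique, cpg, bins)
        z = zscore_normalize(mat)
        z.to_frame().to_csv(outdir / "scab_zscore.tsv", sep="\t")
        report["stages"]["scab"] = {
            "n_cells": len(mat.barcodes),
            "n_bins": bins.n_bins,
            "n_flagged": len(z.flagged_cells),
        }

    pooled = None
    if "aggregate" in stages:
        labels = {bc: "pseudobulk" for bc in unique["barcode"].unique()}
        mats, n_unlabeled = aggregate(unique, labels, bins)
        pooled = mats["pseudobulk"]
        balance(pooled)
        report["stages"]["aggregate"] = {
            "mass": pooled.mass,
            "n_unlabeled": n_unlabeled,
        }

    if "insulation" in stages:
        if pooled is None:
            raise ValueError("insulation stage requires the aggregate stage")
        window = int(config.get("window", 20 * bins.bin_size))
        track = insulation(pooled, window)
        track.normalized.to_frame("insulation").to_csv(
            outdir / "insulation.tsv", sep="\t", index=False
        )
        n_defined = int(np.isfinite(track.normalized.values).sum())
        report["stages"]["insulation"] = {"n_bins_scored": n_defined}

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=str) + "\n")
    return report
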