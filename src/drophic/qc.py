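"""Droplet QC: species-mixing collision analysis, distance-band
cell-cycle metrics, and the multiome joint cell filter.

In a barnyard (two-species mixing) experiment, reads are assigned to a
genome by the chromosome-name prefix of a concatenated reference; a
barcode's mixing rate is min(countA, countB)/(countA+countB), and
barcodes with a mixing rate strictly above 20% are called doublets.

Cell-cycle metrics summarise each cell's contact-distance distribution
into bands (short [25 kb, 2 Mb), mitotic [2 Mb, 12 Mb), far [12 Mb, inf)
by default) plus the trans fraction; phase labels are left to a
user-supplied rule table, since the decision boundaries are a
lab-specific prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "JointQCConfig",
    "DEFAULT_BANDS",
    "barnyard_call",
    "split_by_genome",
    "cycle_metrics",
    "joint_qc_filter",
]

DEFAULT_BANDS = {
    "short": (25_000, 2_000_000),
    "mitotic": (2_000_000, 12_000_000),
    "far": (12_000_000, np.inf),
}


def split_by_genome(contacts: pd.DataFrame, prefix_a: str, prefix_b: str) -> pd.DataFrame:
    """Per-barcode contact counts split by chromosome-name prefix.

    Contacts whose two legs disagree on genome (possible chimeras) are
    excluded from both counts.
    """
    a = contacts["chrom1"].str.startswith(prefix_a) & contacts["chrom2"].str.startswith(prefix_a)
    b = contacts["chrom1"].str.startswith(prefix_b) & contacts["chrom2"].str.startswith(prefix_b)
    df = pd.DataFrame({"barcode": contacts["barcode"], "a": a, "b": b})
    out = df.groupby("barcode", sort=True).agg(
        n_genomeA=("a", "sum"), n_genomeB=("b", "sum")
    ).reset_index()
    return out


def barnyard_call(counts: pd.DataFrame, threshold: float = 0.20):
    """Classify barcodes as singlets or cross-species doublets.

    ``counts`` has columns barcode, n_genomeA, n_genomeB.  A barcode is a
    doublet iff its mixing rate min/(sum) is strictly greater than
    ``threshold``; otherwise it is a singlet of the majority genome.
    Zero-count barcodes are excluded and listed in the summary.  Returns
    ``(table, summary dict)``.
    """
    df = counts.copy()
    total = df["n_genomeA"] + df["n_genomeB"]
    excluded = df.loc[total == 0, "barcode"].tolist()
    df = df[total > 0].copy()
    tot = df["n_genomeA"] + df["n_genomeB"]
    df["mixing_rate"] = np.minimum(df["n_genomeA"], df["n_genomeB"]) / tot
    df["call"] = np.where(
        df["mixing_rate"] > threshold,
        "doublet",
        np.where(df["n_genomeA"] >= df["n_genomeB"], "singlet_A", "singlet_B"),
    )
    n = len(df)
    n_doublet = int((df["call"] == "doublet").sum())
    summary = {
        "n_barcodes": n,
        "n_doublet": n_doublet,
        "doublet_fraction": n_doublet / n if n else float("nan"),
        "excluded_zero_count": excluded,
    }
    return df.reset_index(drop=True), summary


def cycle_metrics(contacts: pd.DataFrame, bands: dict | None = None) -> pd.DataFrame:
    """Per-cell trans fraction and cis distance-band fractions.

    Band fractions are taken over all cis contacts, so mass below the
    first band (< 25 kb by default) makes them sum to less than one.
    Cells without cis contacts get NaN band fractions.
    """
    bands = bands or DEFAULT_BANDS
    is_trans = (contacts["chrom1"] != contacts["chrom2"]).values
    dist = np.abs(contacts["pos2"].values - contacts["pos1"].values)
    df = pd.DataFrame({"barcode": contacts["barcode"].values, "trans": is_trans})
    for name, (lo, hi) in bands.items():
        df[name] = (~is_trans) & (dist >= lo) & (dist < hi)
    g = df.groupby("barcode", sort=True)
    out = g.agg(n_total=("trans", "size"), n_trans=("trans", "sum")).reset_index()
    n_cis = out["n_total"] - out["n_trans"]
    out["frac_trans"] = out["n_trans"] / out["n_total"]
    for name in bands:
        out[name] = g[name].sum().values / n_cis.where(n_cis > 0).values
    return out


@dataclass
class JointQCConfig:
    """Joint multiome thresholds; all inequalities are strict."""

    min_umis: int = 500
    min_genes: int = 400
    min_contacts: int = 1000
    max_mito: float = 0.10
    max_trans_rate: float = 0.45


def joint_qc_filter(cells: pd.DataFrame, cfg: JointQCConfig | None = None) -> pd.DataFrame:
    """Joint RNA + chromatin cell filter.

    ``cells`` needs columns umis, genes, contacts, mito_frac, trans_rate.
    A cell passes iff umis > min_umis, genes > min_genes, contacts >
    min_contacts, mito_frac < max_mito and trans_rate < max_trans_rate
    (all strict).  Rows with a missing metric fail with reason
    "incomplete".  Adds ``pass_qc`` and ``fail_reason`` columns.
    """
    cfg = cfg or JointQCConfig()
    df = cells.copy()
    metrics = ["umis", "genes", "contacts", "mito_frac", "trans_rate"]
    missing = df[metrics].isna().any(axis=1)
    checks = [
        ("umis", df["umis"] > cfg.min_umis),
        ("genes", df["genes"] > cfg.min_genes),
        ("contacts", df["contacts"] > cfg.min_contacts),
        ("mito_frac", df["mito_frac"] < cfg.max_mito),
        ("trans_rate", df["trans_rate"] < cfg.max_trans_rate),
    ]
    ok = ~missing
    reason = pd.Series([""] * len(df), index=df.index)
    reason[missing] = "incomplete"
    for name, passed in checks:
        failed = ok & ~passed.fillna(False)
        reason[failed & (reason == "")] = name
        ok &= passed.fillna(False)
    df["pass_qc"] = ok
    df["fail_reason"] = reason.where(~ok, "")
    return df
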