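"""Contact extraction, barcode-aware deduplication and per-cell QC.

Extraction turns barcode-annotated aligned read pairs into canonical
contacts, dropping pairs with a low-quality leg (mapq < 20 by default)
and short-range cis pairs (<= 1 kb), which are dominated by
self-ligation/religation artefacts; trans pairs are always eligible.

Deduplication collapses PCR/optical duplicates: two contacts are
duplicates iff they share the barcode and chromosome pair and both legs
lie within ``dup_dist`` bp (default 100) of each other.  Input must be
sorted by (barcode, chrom1, chrom2, pos1, pos2); within that order the
first contact seen is kept and later contacts are compared greedily
against retained representatives, so duplicate chains collapse onto
their earliest member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pairs import COLUMNS, Contact, canonicalize_frame

__all__ = [
    "DedupConfig",
    "ExtractSummary",
    "extract_contacts",
    "sort_contacts",
    "dedup_contacts",
    "per_cell_stats",
    "iter_bam_read_pairs",
]


@dataclass
class DedupConfig:
    dup_dist: int = 100
    min_mapq: int = 20
    min_cis_distance: int = 1000

    def __post_init__(self):
        if min(self.dup_dist, self.min_mapq, self.min_cis_distance) < 0:
            raise ValueError("DedupConfig fields must be non-negative")


@dataclass
class ExtractSummary:
    n_input: int = 0
    n_unmapped: int = 0
    n_low_mapq: int = 0
    n_short_cis: int = 0
    n_kept: int = 0


def iter_bam_read_pairs(path, barcode_tag: str | None = None, name_sep: str = ":"):
    """Yield (barcode, chrom1, pos1, mapq1, chrom2, pos2, mapq2, mapped)
    from a name-sorted SAM/BAM of paired reads.

    The cell barcode is read from ``barcode_tag`` (e.g. ``CB``) when
    given, otherwise from the read-name suffix after the last
    ``name_sep``.  Positions are 1-based leftmost mapping positions.
    """
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        pending = {}
        for read in bam:
            if read.is_secondary or read.is_supplementary:
                continue
            key = read.query_name
            mate = pending.pop(key, None)
            if mate is None:
                pending[key] = read
                continue
            r1, r2 = (mate, read) if mate.is_read1 else (read, mate)
            if barcode_tag:
                bc = r1.get_tag(barcode_tag) if r1.has_tag(barcode_tag) else None
            else:
                bc = key.rsplit(name_sep, 1)[-1] if name_sep in key else None
            mapped = not (r1.is_unmapped or r2.is_unmapped)
            yield (
                bc,
                r1.reference_name, (r1.reference_start or 0) + 1, r1.mapping_quality,
                r2.reference_name, (r2.reference_start or 0) + 1, r2.mapping_quality,
                mapped,
            )


def extract_contacts(read_pairs, chrom_order: dict, cfg: DedupConfig | None = None):
    """Filter read pairs into canonical contacts.

    ``read_pairs`` yields tuples ``(barcode, chrom1, pos1, mapq1, chrom2,
    pos2, mapq2[, mapped])``.  Returns ``(contacts DataFrame, summary)``.
    Pairs with an unmapped leg or null barcode are skipped and counted.
    """
    cfg = cfg or DedupConfig()
    summary = ExtractSummary()
    rows = []
    for rp in read_pairs:
        summary.n_input += 1
        mapped = rp[7] if len(rp) > 7 else True
        bc, c1, p1, q1, c2, p2, q2 = rp[:7]
        if not mapped or bc is None or c1 is None or c2 is None:
            summary.n_unmapped += 1
            continue
        if q1 < cfg.min_mapq or q2 < cfg.min_mapq:
            summary.n_low_mapq += 1
            continue
        if c1 == c2 and abs(p2 - p1) <= cfg.min_cis_distance:
            summary.n_short_cis += 1
            continue
        rows.append((bc, c1, p1, c2, p2, q1, q2))
    df = pd.DataFrame(rows, columns=COLUMNS)
    if len(df):
        df = canonicalize_frame(df, chrom_order)
    summary.n_kept = len(df)
    return df, summary


def sort_contacts(df: pd.DataFrame, chrom_order: dict) -> pd.DataFrame:
    """Sort to the dedup order (barcode, chrom1, chrom2, pos1, pos2)."""
    key1 = df["chrom1"].map(chrom_order)
    key2 = df["chrom2"].map(chrom_order)
    order = np.lexsort(
        (df["pos2"].values, df["pos1"].values, key2.values, key1.values,
         df["barcode"].astype(str).values)
    )
    return df.iloc[order].reset_index(drop=True)


def dedup_contacts(df: pd.DataFrame, cfg: DedupConfig | None = None):
    """Barcode-aware duplicate removal within a distance window.

    ``df`` must be sorted by (barcode, chrom1, chrom2, pos1, pos2);
    unsorted input raises.  Returns ``(unique DataFrame, dup_counts)``
    where ``dup_counts`` maps barcode -> number of removed duplicates.
    The output is duplicate-free against the retained set under the
    pairwise rule (|dpos1| <= dup_dist and |dpos2| <= dup_dist, same
    barcode and chromosome pair); dedup is idempotent.
    """
    cfg = cfg or DedupConfig()
    n = len(df)
    keep = np.ones(n, dtype=bool)
    if n == 0:
        return df.copy(), {}
    bc, bc_codes = np.unique(df["barcode"].astype(str).values, return_inverse=True)
    c1u, c1 = np.unique(df["chrom1"].values, return_inverse=True)
    c2u, c2 = np.unique(df["chrom2"].values, return_inverse=True)
    p1 = df["pos1"].values.astype(np.int64)
    p2 = df["pos2"].values.astype(np.int64)
    dd = cfg.dup_dist
    dup_counts: dict = {}
    # sortedness is checked structurally: each (barcode, chrom-pair) group
    # must be contiguous and positions non-decreasing within it — this is
    # what the sliding window relies on, and it holds for any consistent
    # chromosome-order convention
    seen_groups: set = set()
    kept_p1: list = []
    kept_p2: list = []
    win_lo = 0
    for i in range(n):
        new_group = i == 0 or (
            bc_codes[i] != bc_codes[i - 1]
            or c1[i] != c1[i - 1]
            or c2[i] != c2[i - 1]
        )
        if new_group:
            key = (bc_codes[i], c1[i], c2[i])
            if key in seen_groups:
                raise ValueError(
                    "contacts are not sorted by (barcode, chrom1, chrom2, "
                    "pos1, pos2); sort_contacts() first"
                )
            seen_groups.add(key)
            kept_p1 = []
            kept_p2 = []
            win_lo = 0
        elif p1[i] < p1[i - 1] or (p1[i] == p1[i - 1] and p2[i] < p2[i - 1]):
            raise ValueError(
                "contacts are not sorted by (barcode, chrom1, chrom2, "
                "pos1, pos2); sort_contacts() first"
            )
        # slide window over retained representatives by pos1
        x1, x2 = p1[i], p2[i]
        while win_lo < len(kept_p1) and kept_p1[win_lo] < x1 - dd:
            win_lo += 1
        dup = False
        for j in range(win_lo, len(kept_p1)):
            if abs(kept_p2[j] - x2) <= dd:
                dup = True
                break
        if dup:
            keep[i] = False
            b = bc[bc_codes[i]]
            dup_counts[b] = dup_counts.get(b, 0) + 1
        else:
            kept_p1.append(x1)
            kept_p2.append(x2)
    return df.loc[keep].reset_index(drop=True), dup_counts


def per_cell_stats(unique: pd.DataFrame, dup_counts: dict | None = None) -> pd.DataFrame:
    """Per-barcode QC table from deduplicated contacts.

    Columns: n_total, n_unique, n_cis, n_trans, dup_rate
    (1 - unique/total) and trans_rate (trans/unique).
    """
    if len(unique) == 0:
        return pd.DataFrame(
            columns=["barcode", "n_total", "n_unique", "n_cis", "n_trans",
                     "dup_rate", "trans_rate"]
        )
    is_trans = (unique["chrom1"] != unique["chrom2"]).values
    g = pd.DataFrame({"barcode": unique["barcode"].values, "trans": is_trans})
    tab = g.groupby("barcode", sort=True).agg(
        n_unique=("trans", "size"), n_trans=("trans", "sum")
    ).reset_index()
    tab["n_cis"] = tab["n_unique"] - tab["n_trans"]
    dups = pd.Series(dup_counts or {}, dtype="int64")
    tab["n_total"] = tab["n_unique"] + tab["barcode"].map(dups).fillna(0).astype(int)
    tab["dup_rate"] = 1.0 - tab["n_unique"] / tab["n_total"]
    tab["trans_rate"] = tab["n_trans"] / tab["n_unique"]
    return tab[["barcode", "n_total", "n_unique", "n_cis", "n_trans",
                "dup_rate", "trans_rate"]]
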