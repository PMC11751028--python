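"""Single-cell A/B compartment (scA/B) scores.

The scA/B value of bin b in one cell is the mean CpG density of the bins
its contacts reach from b: every contact with exactly one leg in b
contributes its other leg's CpG density (a contact with both legs in b
is excluded).  Because the A compartment is CpG-rich, a bin whose
partners are CpG-rich is A-like; the score is a per-cell, per-bin
compartment coordinate that needs no eigendecomposition and works on
sparse single-cell maps.

Raw scores (bounded by the CpG track's range) feed gene-module
averaging; per-cell z-scored values feed cross-cell comparisons and
bin-level differential tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinTrack, GenomeBins, genes_to_bins

__all__ = ["ScABMatrix", "scab_per_cell", "scab_matrix", "zscore_normalize",
           "gene_scab", "markerset_score"]


@dataclass
class ScABMatrix:
    """cells x bins matrix of scA/B values; NaN marks masked bins."""

    values: np.ndarray
    barcodes: list
    bins: GenomeBins
    normalization: str = "raw"   # "raw" | "zscore"
    flagged_cells: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.barcodes), self.bins.n_bins):
            raise ValueError("matrix shape does not match barcodes x bins")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.barcodes, name="barcode"))


def _leg_bins(contacts: pd.DataFrame, bins: GenomeBins):
    b1 = np.empty(len(contacts), dtype=np.int64)
    b2 = np.empty(len(contacts), dtype=np.int64)
    for chrom in pd.unique(contacts["chrom1"]):
        m = (contacts["chrom1"] == chrom).values
        b1[m] = bins.bin_of(chrom, contacts.loc[m, "pos1"].values)
    for chrom in pd.unique(contacts["chrom2"]):
        m = (contacts["chrom2"] == chrom).values
        b2[m] = bins.bin_of(chrom, contacts.loc[m, "pos2"].values)
    return b1, b2


def scab_per_cell(contacts: pd.DataFrame, cpg: BinTrack, bins: GenomeBins,
                  min_partner_contacts: int = 1, include_trans: bool = True,
                  min_cis_distance: int = 0) -> np.ndarray:
    """scA/B vector of one cell from its deduplicated contacts.

    Bins touched by fewer than ``min_partner_contacts`` contacts are NaN.
    ``include_trans=False`` restricts to cis partners;
    ``min_cis_distance`` additionally drops short-range cis pairs.
    """
    if len(contacts) == 0:
        return np.full(bins.n_bins, np.nan)
    df = contacts
    cis = (df["chrom1"] == df["chrom2"]).values
    keep = np.ones(len(df), dtype=bool)
    if not include_trans:
        keep &= cis
    if min_cis_distance > 0:
        far = np.abs(df["pos2"].values - df["pos1"].values) > min_cis_distance
        keep &= np.where(cis, far, True)
    df = df.loc[keep]
    if len(df) == 0:
        return np.full(bins.n_bins, np.nan)
    b1, b2 = _leg_bins(df, bins)
    off_diag = b1 != b2   # a contact within one bin has no partner bin
    b1, b2 = b1[off_diag], b2[off_diag]
    n = bins.n_bins
    sums = np.bincount(b1, weights=cpg.values[b2], minlength=n)
    sums += np.bincount(b2, weights=cpg.values[b1], minlength=n)
    counts = np.bincount(b1, minlength=n) + np.bincount(b2, minlength=n)
    with np.errstate(invalid="ignore"):
        vals = sums / counts
    vals[counts < max(min_partner_contacts, 1)] = np.nan
    return vals


def scab_matrix(contacts: pd.DataFrame, cpg: BinTrack, bins: GenomeBins,
                barcodes=None, **kwargs) -> ScABMatrix:
    """Raw scA/B matrix over all cells in a contacts frame."""
    if barcodes is None:
        barcodes = sorted(pd.unique(contacts["barcode"]))
    groups = dict(tuple(contacts.groupby("barcode", sort=False)))
    mat = np.full((len(barcodes), bins.n_bins), np.nan)
    empty = pd.DataFrame(columns=contacts.columns)
    for i, bc in enumerate(barcodes):
        mat[i] = scab_per_cell(groups.get(bc, empty), cpg, bins, **kwargs)
    return ScABMatrix(mat, list(barcodes), bins, "raw")


def zscore_normalize(m: ScABMatrix) -> ScABMatrix:
    """Per-cell z-scoring over unmasked bins (population sd).

    Cells with fewer than two unmasked bins or zero spread are left raw
    and flagged.  Masked entries stay masked.
    """
    if m.normalization != "raw":
        raise ValueError("matrix is already normalized")
    vals = m.values.copy()
    flagged = []
    for i in range(vals.shape[0]):
        row = vals[i]
        ok = np.isfinite(row)
        if ok.sum() < 2:
            flagged.append(m.barcodes[i])
            continue
        mu = row[ok].mean()
        sd = row[ok].std()
        if sd == 0:
            flagged.append(m.barcodes[i])
            continue
        vals[i, ok] = (row[ok] - mu) / sd
    return ScABMatrix(vals, list(m.barcodes), m.bins, "zscore", flagged)


def gene_scab(m: ScABMatrix, genes: pd.DataFrame) -> pd.DataFrame:
    """cells x genes matrix: mean unmasked scA/B over each gene's bins.

    Genes map to bins by any overlap of the gene body; genes on
    chromosomes absent from the binning are dropped.
    """
    gene_bins = genes_to_bins(genes, m.bins)
    out = {}
    for gene, idx in gene_bins.items():
        sub = m.values[:, idx]
        counts = np.isfinite(sub).sum(axis=1)
        with np.errstate(invalid="ignore"):
            vals = np.nansum(sub, axis=1) / np.where(counts > 0, counts, 1)
        out[gene] = np.where(counts > 0, vals, np.nan)
    return pd.DataFrame(out, index=pd.Index(m.barcodes, name="barcode"))


def markerset_score(m: ScABMatrix, marker_sets: dict, genes: pd.DataFrame,
                    clusters: pd.Series | None = None):
    """Marker-gene-set mean scA/B per cell, and cluster-level type calls.

    ``marker_sets`` maps cell-type name -> gene list (top markers);
    ``genes`` provides gene-body intervals.  Scores are the mean scA/B
    over the union of each set's gene bins.  With ``clusters`` given
    (barcode -> cluster id), each cluster is labelled by the type with
    the maximal mean score over its cells (ties broken by type order and
    flagged).  Returns ``scores`` or ``(scores, labels)``.
    """
    gene_bins = genes_to_bins(genes, m.bins)
    scores = {}
    for ctype, gene_list in marker_sets.items():
        idx = np.unique(np.concatenate(
            [gene_bins[g] for g in gene_list if g in gene_bins] or [np.array([], int)]
        )).astype(int)
        if idx.size == 0:
            scores[ctype] = np.full(len(m.barcodes), np.nan)
            continue
        with np.errstate(invalid="ignore"):
            scores[ctype] = np.nanmean(m.values[:, idx], axis=1)
    score_df = pd.DataFrame(scores, index=pd.Index(m.barcodes, name="barcode"))
    if clusters is None:
        return score_df
    labels = {}
    for cl, members in clusters.groupby(clusters):
        sub = score_df.loc[members.index]
        means = sub.mean(axis=0, skipna=True)
        best = means.idxmax()
        tie = (means == means.max()).sum() > 1
        labels[cl] = {"cell_type": best, "tie": bool(tie)}
    labels_df = pd.DataFrame(labels).T.rename_axis("cluster")
    return score_df, labels_df
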