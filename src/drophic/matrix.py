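"""Binned contact matrices and chromatin topology statistics.

Contacts are aggregated per group (single cell, metacell or pseudobulk)
into symmetric binned count matrices, balanced by iterative correction,
and summarised as distance-decay P(s) curves, diamond insulation tracks,
TAD boundary calls, per-gene boundary usage, and domain-melting scores
comparing insulation-square distributions between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.signal import find_peaks
from scipy.stats import ks_2samp

from .genome import BinTrack, GenomeBins, genes_to_bins

__all__ = [
    "BinnedMatrix",
    "InsulationTrack",
    "BoundarySet",
    "aggregate",
    "balance",
    "ps_curve",
    "fit_ps_slope",
    "insulation",
    "call_boundaries",
    "boundary_usage",
    "melting_score",
]


@dataclass
class BinnedMatrix:
    """Symmetric sparse contact-count matrix over a genome binning."""

    bins: GenomeBins
    counts: sp.csr_matrix
    group_id: str = ""
    balance_weights: np.ndarray | None = None
    balance_converged: bool | None = None

    @property
    def mass(self) -> float:
        """Number of contacts (upper triangle incl. diagonal)."""
        return float(sp.triu(self.counts).sum())

    def dense_chrom(self, chrom: str, balanced: bool = False) -> np.ndarray:
        sl = self.bins.chrom_slice(chrom)
        block = self.counts[sl, sl].toarray().astype(float)
        if balanced:
            if self.balance_weights is None:
                raise ValueError("matrix has no balance weights; run balance() first")
            w = self.balance_weights[sl]
            block = block * np.outer(w, w)
        return block


def _bin_legs(contacts: pd.DataFrame, bins: GenomeBins):
    b1 = np.empty(len(contacts), dtype=np.int64)
    b2 = np.empty(len(contacts), dtype=np.int64)
    for chrom in pd.unique(contacts["chrom1"]):
        m = (contacts["chrom1"] == chrom).values
        b1[m] = bins.bin_of(chrom, contacts.loc[m, "pos1"].values)
    for chrom in pd.unique(contacts["chrom2"]):
        m = (contacts["chrom2"] == chrom).values
        b2[m] = bins.bin_of(chrom, contacts.loc[m, "pos2"].values)
    return b1, b2


def aggregate(contacts: pd.DataFrame, labels, bins: GenomeBins):
    """Binned contact matrix per group label.

    ``labels`` maps barcode -> group (dict or Series); contacts with an
    unlabeled barcode are dropped and counted.  Off-diagonal counts are
    mirrored into both triangles; ``mass`` (upper triangle) equals the
    number of that group's contacts.  Returns ``(matrices, n_unlabeled)``
    where matrices is ``dict group -> BinnedMatrix``.
    """
    lab = pd.Series(labels)
    groups = contacts["barcode"].map(lab)
    unlabeled = int(groups.isna().sum())
    kept = contacts.loc[groups.notna()]
    groups = groups.dropna()
    out = {}
    n = bins.n_bins
    for g, sub in kept.groupby(groups.values):
        b1, b2 = _bin_legs(sub, bins)
        lo, hi = np.minimum(b1, b2), np.maximum(b1, b2)
        m = sp.coo_matrix((np.ones(len(sub)), (lo, hi)), shape=(n, n)).tocsr()
        upper = sp.triu(m, k=1)
        out[g] = BinnedMatrix(bins, m + upper.T, group_id=str(g))
    return out, unlabeled


def balance(m: BinnedMatrix, max_iter: int = 200, tol: float = 1e-6,
            mad_max: float = 5.0) -> np.ndarray:
    """Iterative-correction balance weights.

    Finds per-bin factors w so that the weighted matrix
    ``w_i w_j C_ij`` has equal marginals over retained bins.  Bins with
    zero coverage, or whose log10 marginal lies more than ``mad_max``
    median-absolute-deviations below the median, are filtered (NaN
    weights).  Sets ``m.balance_weights`` and ``m.balance_converged``
    and returns the weights.
    """
    C = m.counts.astype(float)
    marg = np.asarray(C.sum(axis=1)).ravel()
    mask = marg > 0
    if mad_max is not None and mask.sum() > 1:
        logm = np.log10(marg[mask])
        med = np.median(logm)
        mad = np.median(np.abs(logm - med))
        if mad > 0:
            low = np.full(m.bins.n_bins, False)
            low[mask] = logm < med - mad_max * mad
            mask &= ~low
    w = np.zeros(m.bins.n_bins)
    w[mask] = 1.0
    converged = False
    for _ in range(max_iter):
        s = w * np.asarray(C @ w).ravel()
        sm = s[mask]
        mean = sm.mean()
        if mean == 0:
            break
        var = np.var(sm / mean)
        if var < tol:
            converged = True
            break
        w[mask] /= np.sqrt(sm / mean)
    weights = np.where(mask, w, np.nan)
    m.balance_weights = weights
    m.balance_converged = converged
    return weights


def ps_curve(contacts: pd.DataFrame, chrom_sizes: dict, n_dist_bins: int = 30,
             min_dist: int = 1000) -> pd.DataFrame:
    """Contact frequency vs genomic distance on log-spaced bins.

    Frequency is observed cis contacts divided by the number of bp locus
    pairs at those separations (sum over chromosomes of L - s), so a
    homogeneous polymer with P(s) ~ s^a yields a log-log line of slope a.
    """
    cis = contacts.loc[contacts["chrom1"] == contacts["chrom2"]]
    dist = np.abs(cis["pos2"].values - cis["pos1"].values)
    max_dist = max(chrom_sizes.values())
    edges = np.unique(np.geomspace(min_dist, max_dist, n_dist_bins + 1).astype(np.int64))
    counts, _ = np.histogram(dist, bins=edges)
    # closed-form number of position pairs at separation s in [lo, hi)
    n_pairs = np.zeros(len(edges) - 1, dtype=float)
    for L in chrom_sizes.values():
        lo = edges[:-1].astype(float)
        hi = np.minimum(edges[1:], L).astype(float)
        width = np.maximum(hi - lo, 0)
        n_pairs += width * L - (lo + hi - 1) * width / 2.0
    mid = np.sqrt(edges[:-1] * edges[1:].astype(float))
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(n_pairs > 0, counts / n_pairs, np.nan)
    out = pd.DataFrame({
        "dist_lo": edges[:-1], "dist_hi": edges[1:], "dist_mid": mid,
        "n_contacts": counts, "n_pairs": n_pairs, "freq": freq,
    })
    return out[out["n_contacts"] > 0].reset_index(drop=True)


def fit_ps_slope(ps: pd.DataFrame) -> float:
    """Log-log OLS slope of the P(s) curve."""
    ok = ps["freq"] > 0
    x = np.log10(ps.loc[ok, "dist_mid"])
    y = np.log10(ps.loc[ok, "freq"])
    return float(np.polyfit(x, y, 1)[0])


@dataclass
class InsulationTrack:
    """Diamond insulation: raw window means and log2-normalized scores."""

    bins: GenomeBins
    window: int
    raw_square: BinTrack = field(repr=False)
    normalized: BinTrack = field(repr=False)


def insulation(m: BinnedMatrix, window: int, balanced: bool = True) -> InsulationTrack:
    """Diamond (insulation-square) score per bin.

    ``raw_square(i)`` is the mean (balanced) interaction over the square
    [i-w, i) x [i, i+w) with w = window // bin_size;
    ``normalized(i) = log2(raw_square(i) / chromosome mean)``.  Bins
    within w of a chromosome end are missing; chromosomes shorter than
    2w are all-missing.
    """
    w = window // m.bins.bin_size
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    raw = np.full(m.bins.n_bins, np.nan)
    norm = np.full(m.bins.n_bins, np.nan)
    for chrom in m.bins.chroms:
        n = m.bins.n_bins_of(chrom)
        if n < 2 * w + 1:
            continue
        # raw counts are used when no weights are present (single-cell-like maps)
        block = m.dense_chrom(chrom, balanced=balanced and m.balance_weights is not None)
        sl = m.bins.chrom_slice(chrom)
        vals = np.full(n, np.nan)
        # 2D prefix sums for O(1) window sums
        P = np.zeros((n + 1, n + 1))
        P[1:, 1:] = np.nancumsum(np.nancumsum(block, axis=0), axis=1)
        for i in range(w, n - w):
            r0, r1 = i - w, i
            c0, c1 = i, i + w
            s = P[r1, c1] - P[r0, c1] - P[r1, c0] + P[r0, c0]
            vals[i] = s / (w * w)
        interior = np.isfinite(vals)
        mean = vals[interior].mean() if interior.any() else np.nan
        raw[sl] = vals
        if np.isfinite(mean) and mean > 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                norm_vals = np.where(vals > 0, np.log2(vals / mean), -np.inf)
            norm_vals = np.where(np.isfinite(vals), norm_vals, np.nan)
            norm[sl] = norm_vals
    return InsulationTrack(
        m.bins, window, BinTrack(m.bins, raw), BinTrack(m.bins, norm)
    )


@dataclass
class BoundarySet:
    """TAD boundaries: bin ordinals with prominence strengths."""

    bins: GenomeBins
    boundary_bins: np.ndarray
    strengths: np.ndarray
    resolution: int = field(init=False)

    def __post_init__(self):
        self.resolution = self.bins.bin_size

    def __contains__(self, bin_ordinal) -> bool:
        return bool(np.isin(bin_ordinal, self.boundary_bins))


def call_boundaries(track: InsulationTrack, min_strength: float = 0.1) -> BoundarySet:
    """Boundaries = local minima of the normalized insulation track with
    prominence >= ``min_strength`` (log2 units)."""
    vals = track.normalized.values
    bnds = []
    strengths = []
    for chrom in track.bins.chroms:
        sl = track.bins.chrom_slice(chrom)
        v = vals[sl]
        defined = ~np.isnan(v)   # -inf (empty diamond) is a genuine deep minimum
        if defined.sum() < 3:
            continue
        idx = np.flatnonzero(defined)
        seg = v[idx]
        lo = np.min(seg[np.isfinite(seg)]) if np.isfinite(seg).any() else 0.0
        seg = np.clip(seg, lo - 10.0, None)
        peaks, props = find_peaks(-seg, prominence=min_strength)
        bnds.extend(sl.start + idx[peaks])
        strengths.extend(props["prominences"])
    return BoundarySet(track.bins, np.asarray(bnds, dtype=int),
                       np.asarray(strengths, dtype=float))


def boundary_usage(boundary_sets, genes: pd.DataFrame, bins: GenomeBins) -> pd.Series:
    """Fraction of a cluster's members whose boundary calls hit each
    gene's TSS bin.

    ``boundary_sets`` is the cluster's members' :class:`BoundarySet`
    list (single cells or metacells).  ``genes`` needs columns gene,
    chrom, tss (0-based position).  Genes on absent chromosomes are NaN.
    """
    if len(boundary_sets) == 0:
        raise ValueError("empty cluster")
    usage = {}
    member_bins = [set(bs.boundary_bins.tolist()) for bs in boundary_sets]
    for row in genes.itertuples(index=False):
        if row.chrom not in bins.offsets:
            usage[row.gene] = np.nan
            continue
        b = bins.bin_of(row.chrom, int(row.tss), one_based=False)
        usage[row.gene] = sum(b in mb for mb in member_bins) / len(member_bins)
    return pd.Series(usage, name="boundary_usage")


def melting_score(square_ref: BinTrack, square_target: BinTrack, genes: pd.DataFrame,
                  min_gene_length: int = 300_000, min_bins: int = 4) -> pd.DataFrame:
    """Domain melting per long gene between two conditions.

    For every gene longer than ``min_gene_length``, the per-bin
    insulation-square values over the gene body are compared between the
    reference and target conditions with a two-sample Kolmogorov-Smirnov
    test; score = -log10(p).  The domain is "melted" in the target when
    the mean insulation-square decreased there, "established" when it
    increased.  Genes with fewer than ``min_bins`` finite bins in either
    condition are flagged underpowered (NaN score).
    """
    bins = square_ref.bins
    genes = genes.loc[(genes["end"] - genes["start"]) > min_gene_length]
    gene_bins = genes_to_bins(genes, bins)
    rows = []
    for gene, idx in gene_bins.items():
        a = square_ref.values[idx]
        b = square_target.values[idx]
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < min_bins or len(b) < min_bins:
            rows.append((gene, len(a), len(b), np.nan, np.nan, "underpowered"))
            continue
        res = ks_2samp(a, b)
        score = float(-np.log10(max(res.pvalue, 1e-300)))
        if b.mean() < a.mean():
            direction = "melted"
        elif b.mean() > a.mean():
            direction = "established"
        else:
            direction = "none"
        rows.append((gene, len(a), len(b), float(res.statistic), score, direction))
    return pd.DataFrame(
        rows, columns=["gene", "n_bins_ref", "n_bins_target", "ks_stat",
                       "score", "direction"],
    )
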