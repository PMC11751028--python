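"""Metacell-level differential compartment statistics.

The unit of replication is the metacell — a pool of architecturally
similar cells — not the single cell, which avoids pseudoreplication in
between-condition tests.  Per bin, metacell median scA/B values are
compared between groups with the Wilcoxon rank-sum (Mann-Whitney U)
test; p-values are Benjamini-Hochberg adjusted within one comparison,
and bins pass at adjusted p < 0.01, with an additional |delta| > 0.05
effect filter for summary counts of increased/decreased bins.

Gene-module scores are means of *raw* scA/B over a module's gene bins;
bin-level differential runs on per-cell *z-scored* values, matching the
two scales' intended uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .genome import GenomeBins, genes_to_bins
from .scab import ScABMatrix

__all__ = [
    "MetacellTable",
    "build_metacells",
    "ranksum_test",
    "bh_adjust",
    "diff_compartment",
    "gene_module_score",
    "compare_module_groups",
]


@dataclass
class MetacellTable:
    """Per-metacell bin medians plus membership metadata."""

    values: np.ndarray                # metacells x bins, NaN-masked
    meta: pd.DataFrame                # metacell, cell_type, timepoint, n_members, n_contacts
    bins: GenomeBins
    normalization: str = "raw"
    members: dict = field(default_factory=dict)

    def group_values(self, metacell_ids) -> np.ndarray:
        idx = [self.meta.index.get_loc(m) for m in metacell_ids]
        return self.values[idx]


def build_metacells(assignments: pd.DataFrame, m: ScABMatrix,
                    contacts: pd.DataFrame | None = None,
                    min_member_fraction: float = 0.5) -> MetacellTable:
    """Pool cells into metacells by their sub-cluster id.

    ``assignments`` needs columns barcode, metacell and optionally
    cell_type / timepoint (carried through; must be constant within a
    metacell).  Per bin, the metacell value is the median over members'
    unmasked values, masked when fewer than ``min_member_fraction`` of
    members are unmasked.  Singleton metacells are allowed and flagged
    in the metadata.
    """
    bc_index = {bc: i for i, bc in enumerate(m.barcodes)}
    missing = [b for b in assignments["barcode"] if b not in bc_index]
    if missing:
        raise KeyError(f"barcodes not in scA/B matrix: {missing[:3]}...")
    n_contacts = None
    if contacts is not None:
        n_contacts = contacts.groupby("barcode").size()
    rows = []
    values = []
    members = {}
    for mc, sub in assignments.groupby("metacell", sort=True):
        idx = [bc_index[b] for b in sub["barcode"]]
        block = m.values[idx]
        n_members = len(idx)
        with np.errstate(invalid="ignore"):
            med = np.nanmedian(block, axis=0)
        coverage = np.isfinite(block).sum(axis=0) / n_members
        med[coverage < min_member_fraction] = np.nan
        values.append(med)
        members[mc] = list(sub["barcode"])
        row = {"metacell": mc, "n_members": n_members,
               "singleton": n_members == 1}
        for col in ("cell_type", "timepoint"):
            if col in sub.columns:
                u = sub[col].unique()
                if len(u) > 1:
                    raise ValueError(f"metacell {mc!r} mixes {col} values {u}")
                row[col] = u[0]
        if n_contacts is not None:
            row["n_contacts"] = int(n_contacts.reindex(sub["barcode"]).fillna(0).sum())
        rows.append(row)
    meta = pd.DataFrame(rows).set_index("metacell")
    return MetacellTable(np.vstack(values), meta, m.bins, m.normalization, members)


def ranksum_test(x, y, alternative: str = "two-sided"):
    """Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when the pooled size is <= 12 with no ties,
    otherwise the normal approximation with midrank tie correction and
    continuity correction.  Identical constant samples give p = 1.
    Returns ``(U statistic of x, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative=alternative, method=method,
                       use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving,
    capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def diff_compartment(mt: MetacellTable, group_a, group_b, alpha: float = 0.01,
                     min_delta: float = 0.05,
                     max_masked_fraction: float = 0.5) -> pd.DataFrame:
    """Per-bin differential scA/B between two metacell groups.

    ``group_a``/``group_b`` are metacell id lists (>= 2 each).  Bins
    masked in more than ``max_masked_fraction`` of either group are
    left untested.  delta = median(A) - median(B) of metacell medians.
    ``significant`` is p_adj < alpha; ``direction`` summarises bins that
    additionally pass |delta| > min_delta as increased/decreased.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 metacells per group")
    A = mt.group_values(group_a)
    B = mt.group_values(group_b)
    n_bins = mt.bins.n_bins
    ok_a = np.isfinite(A).mean(axis=0) >= 1 - max_masked_fraction
    ok_b = np.isfinite(B).mean(axis=0) >= 1 - max_masked_fraction
    tested = ok_a & ok_b
    rows = []
    for b in np.flatnonzero(tested):
        xa = A[:, b][np.isfinite(A[:, b])]
        xb = B[:, b][np.isfinite(B[:, b])]
        stat, p = ranksum_test(xa, xb)
        delta = float(np.median(xa) - np.median(xb))
        rows.append((b, len(xa), len(xb), delta, stat, p))
    df = pd.DataFrame(rows, columns=["bin", "nA", "nB", "delta", "stat", "p_raw"])
    if len(df):
        df["p_adj"] = bh_adjust(df["p_raw"].values)
    else:
        df["p_adj"] = np.nan
    df["significant"] = df["p_adj"] < alpha
    df["direction"] = "ns"
    strong = df["significant"] & (df["delta"].abs() > min_delta)
    df.loc[strong & (df["delta"] > 0), "direction"] = "increased"
    df.loc[strong & (df["delta"] < 0), "direction"] = "decreased"
    df.attrs["untested_bins"] = np.flatnonzero(~tested)
    df.attrs["alpha"] = alpha
    df.attrs["min_delta"] = min_delta
    return df


def gene_module_score(mt: MetacellTable, gene_list, genes: pd.DataFrame) -> pd.Series:
    """Mean raw scA/B over a gene module's bins, per metacell.

    Raises if no module gene maps to the binning.  (Module scores are
    meant for *raw* scA/B metacell tables.)
    """
    gene_bins = genes_to_bins(genes.loc[genes["gene"].isin(gene_list)], mt.bins)
    if not gene_bins:
        raise ValueError("no module gene maps to the genome binning")
    idx = np.unique(np.concatenate(list(gene_bins.values())))
    with np.errstate(invalid="ignore"):
        score = np.nanmean(mt.values[:, idx], axis=1)
    return pd.Series(score, index=mt.meta.index, name="module_score")


def compare_module_groups(scores: pd.Series, groups: pd.Series,
                          comparisons, alpha: float = 0.01) -> pd.DataFrame:
    """Rank-sum tests of module scores between metacell groups.

    ``groups`` maps metacell -> group label (e.g. timepoint);
    ``comparisons`` is a list of (target, reference) label pairs.
    P-values are BH-adjusted across the supplied comparisons.
    """
    rows = []
    for target, ref in comparisons:
        x = scores[groups == target].dropna()
        y = scores[groups == ref].dropna()
        stat, p = ranksum_test(x.values, y.values)
        rows.append((target, ref, len(x), len(y),
                     float(np.median(x) - np.median(y)), stat, p))
    df = pd.DataFrame(rows, columns=["target", "reference", "n_target",
                                     "n_reference", "delta", "stat", "p_raw"])
    df["p_adj"] = bh_adjust(df["p_raw"].values)
    df["significant"] = df["p_adj"] < alpha
    return df
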