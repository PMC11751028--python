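"""Genome binning, CpG density and per-bin scalar tracks.

A :class:`GenomeBins` tiles each chromosome with fixed-size, 0-based
half-open bins (the last bin of a chromosome may be short).  Bin ordinals
give a total order: chromosome order (as listed in the chromosome-sizes
input) then start coordinate.  All binned quantities in the package — CpG
density, scA/B compartment scores, insulation — live in a
:class:`BinTrack`, one float per bin with NaN marking missing values.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeBins",
    "BinTrack",
    "make_bins",
    "read_chrom_sizes",
    "cpg_density",
    "genes_to_bins",
]


@dataclass(frozen=True)
class GenomeBins:
    """Fixed-size tiling of a genome.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome -> length in bp.  Iteration order defines
        chromosome order and therefore the bin ordinal.
    bin_size
        Bin width in bp.
    """

    chrom_sizes: dict
    bin_size: int
    chroms: tuple = field(init=False)
    offsets: dict = field(init=False)
    n_bins: int = field(init=False)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        for c, ln in self.chrom_sizes.items():
            if ln <= 0:
                raise ValueError(f"chromosome {c!r} has non-positive length {ln}")
        chroms = tuple(self.chrom_sizes)
        offsets = {}
        total = 0
        for c in chroms:
            offsets[c] = total
            total += self.n_bins_of(c)
        object.__setattr__(self, "chroms", chroms)
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "n_bins", total)

    def n_bins_of(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.bin_size)

    def chrom_order(self, chrom: str) -> int:
        try:
            return self.chroms.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def bin_of(self, chrom, pos, one_based: bool = True):
        """Ordinal of the bin containing ``pos``.

        ``pos`` may be a scalar or array.  Contact coordinates are 1-based
        by convention; pass ``one_based=False`` for 0-based coordinates.
        """
        if chrom not in self.offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")
        p = np.asarray(pos, dtype=np.int64)
        if one_based:
            p = p - 1
        idx = self.offsets[chrom] + p // self.bin_size
        return idx if idx.ndim else int(idx)

    def bin_table(self) -> pd.DataFrame:
        """All bins as a (chrom, start, end) frame in ordinal order."""
        rows = []
        for c in self.chroms:
            ln = self.chrom_sizes[c]
            starts = np.arange(0, ln, self.bin_size, dtype=np.int64)
            ends = np.minimum(starts + self.bin_size, ln)
            rows.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def chrom_slice(self, chrom: str) -> slice:
        """Ordinal slice covering one chromosome."""
        o = self.offsets[chrom]
        return slice(o, o + self.n_bins_of(chrom))


@dataclass
class BinTrack:
    """One scalar per bin; NaN encodes missing."""

    bins: GenomeBins
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.bins.n_bins,):
            raise ValueError(
                f"track length {self.values.shape} != number of bins {self.bins.n_bins}"
            )

    def to_frame(self, name: str = "value") -> pd.DataFrame:
        df = self.bins.bin_table()
        df[name] = self.values
        return df


def make_bins(chrom_sizes: dict, bin_size: int) -> GenomeBins:
    """Tile each chromosome with ``bin_size`` bins (last bin may be short)."""
    return GenomeBins(dict(chrom_sizes), int(bin_size))


def read_chrom_sizes(path) -> dict:
    """Two-column TSV (chrom, length); order of lines is chromosome order."""
    sizes = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, ln = line.split()[:2]
            sizes[chrom] = int(ln)
    return sizes


def cpg_density(fasta, bins: GenomeBins) -> BinTrack:
    """Per-bin CpG density: count of CG dinucleotides whose C falls inside
    the bin, divided by bin length.

    ``fasta`` is a path to a FASTA file or any mapping chromosome ->
    sequence string.  Counting is case-insensitive; ambiguous bases never
    form a CpG.  A dinucleotide belongs to the bin of its first base, so a
    CpG straddling a bin edge is counted exactly once.
    """
    if isinstance(fasta, (str, bytes)) or hasattr(fasta, "__fspath__"):
        from pyfaidx import Fasta

        fa = Fasta(str(fasta), as_raw=True, sequence_always_upper=True)
        get = lambda c: str(fa[c][:])  # noqa: E731
        names = set(fa.keys())
    else:
        get = lambda c: str(fasta[c]).upper()  # noqa: E731
        names = set(fasta)

    values = np.full(bins.n_bins, np.nan)
    for chrom in bins.chroms:
        if chrom not in names:
            raise KeyError(f"chromosome {chrom!r} missing from FASTA")
        seq = get(chrom)
        ln = bins.chrom_sizes[chrom]
        arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
        is_c = arr == b"C"
        is_g = arr == b"G"
        # CpG start positions: C at i, G at i+1
        cpg_start = np.zeros(len(arr), dtype=bool)
        cpg_start[:-1] = is_c[:-1] & is_g[1:]
        sl = bins.chrom_slice(chrom)
        n = bins.n_bins_of(chrom)
        bin_idx = np.arange(len(arr)) // bins.bin_size
        counts = np.bincount(bin_idx[cpg_start], minlength=n)[:n]
        starts = np.arange(n) * bins.bin_size
        widths = np.minimum(starts + bins.bin_size, ln) - starts
        values[sl] = counts / widths
    return BinTrack(bins, values)


def genes_to_bins(genes: pd.DataFrame, bins: GenomeBins, drop_missing: bool = True):
    """Map gene-body intervals to bin ordinals by any overlap.

    ``genes`` needs columns ``chrom``, ``start``, ``end``, ``gene``
    (0-based half-open intervals).  Returns ``dict gene -> ndarray of bin
    ordinals``.  Genes on chromosomes absent from ``bins`` are dropped
    (with a KeyError if ``drop_missing`` is False).
    """
    out = {}
    bs = bins.bin_size
    for row in genes.itertuples(index=False):
        if row.chrom not in bins.offsets:
            if drop_missing:
                continue
            raise KeyError(f"gene {row.gene!r} on unknown chromosome {row.chrom!r}")
        off = bins.offsets[row.chrom]
        n = bins.n_bins_of(row.chrom)
        lo = max(0, row.start // bs)
        hi = min(n, -(-row.end // bs))
        if hi > lo:
            out[row.gene] = off + np.arange(lo, hi)
    return out
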