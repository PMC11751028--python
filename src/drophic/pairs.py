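"""Barcode-annotated chromatin contacts and their on-disk pairs dialect.

A contact is one proximity-ligation event: a cell barcode plus two genomic
legs with mapping qualities.  Legs are stored canonically — chrom1 before
chrom2 in genome order, pos1 <= pos2 for cis contacts — and positions are
1-based, following the 4DN pairs convention.

The text dialect is a TSV with columns
``barcode chrom1 pos1 chrom2 pos2 mapq1 mapq2`` and ``#``-prefixed header
lines carrying chromosome sizes; reading and writing round-trips exactly.
I/O is gzip-transparent.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "Contact",
    "canonicalize",
    "read_pairs",
    "write_pairs",
    "read_pairs_frame",
    "write_pairs_frame",
    "canonicalize_frame",
    "COLUMNS",
]

COLUMNS = ["barcode", "chrom1", "pos1", "chrom2", "pos2", "mapq1", "mapq2"]


@dataclass
class Contact:
    barcode: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    mapq1: int = 60
    mapq2: int = 60

    @property
    def is_trans(self) -> bool:
        return self.chrom1 != self.chrom2

    @property
    def distance(self) -> int | None:
        """Genomic separation for cis contacts, None for trans."""
        return None if self.is_trans else abs(self.pos2 - self.pos1)


def canonicalize(c: Contact, chrom_order: dict) -> Contact:
    """Order legs: chrom1 <= chrom2 in genome order; pos1 <= pos2 when cis."""
    o1, o2 = chrom_order[c.chrom1], chrom_order[c.chrom2]
    if o1 > o2 or (o1 == o2 and c.pos1 > c.pos2):
        return Contact(c.barcode, c.chrom2, c.pos2, c.chrom1, c.pos1, c.mapq2, c.mapq1)
    return c


def _opener(path, mode):
    return gzip.open(path, mode) if str(path).endswith(".gz") else open(path, mode)


def write_pairs(path, contacts, chrom_sizes: dict):
    """Write contacts in the pairs dialect; returns number written."""
    n = 0
    with _opener(path, "wt") as fh:
        fh.write("## pairs-like drophic contacts v1\n")
        for chrom, ln in chrom_sizes.items():
            fh.write(f"#chromsize: {chrom} {ln}\n")
        fh.write("#columns: " + " ".join(COLUMNS) + "\n")
        for c in contacts:
            fh.write(
                f"{c.barcode}\t{c.chrom1}\t{c.pos1}\t{c.chrom2}\t{c.pos2}"
                f"\t{c.mapq1}\t{c.mapq2}\n"
            )
            n += 1
    return n


def read_pairs(path, chrom_sizes: dict | None = None):
    """Stream contacts from a pairs file, canonicalizing leg order.

    Yields :class:`Contact`.  Header ``#chromsize:`` lines define the
    chromosome order used for canonicalization unless ``chrom_sizes`` is
    given.  Malformed lines raise with their line number; legs on
    chromosomes absent from the header raise.
    """
    sizes = dict(chrom_sizes) if chrom_sizes else {}
    order = {c: i for i, c in enumerate(sizes)}
    with _opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#chromsize:") and not chrom_sizes:
                    _, chrom, ln = line.split()
                    sizes[chrom] = int(ln)
                    order[chrom] = len(order)
                continue
            fields = line.split("\t")
            if len(fields) != len(COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(COLUMNS)} columns, got {len(fields)}"
                )
            try:
                c = Contact(
                    fields[0], fields[1], int(fields[2]), fields[3], int(fields[4]),
                    int(fields[5]), int(fields[6]),
                )
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
            if c.chrom1 not in order or c.chrom2 not in order:
                bad = c.chrom1 if c.chrom1 not in order else c.chrom2
                raise ValueError(f"{path}:{lineno}: unknown chromosome {bad!r}")
            yield canonicalize(c, order)


# DataFrame-level counterparts: the analysis modules operate on frames.

def canonicalize_frame(df: pd.DataFrame, chrom_order: dict) -> pd.DataFrame:
    """Vectorized leg canonicalization of a contacts frame."""
    df = df.copy()
    o1 = df["chrom1"].map(chrom_order)
    o2 = df["chrom2"].map(chrom_order)
    if o1.isna().any() or o2.isna().any():
        bad = set(df.loc[o1.isna(), "chrom1"]) | set(df.loc[o2.isna(), "chrom2"])
        raise KeyError(f"unknown chromosomes {sorted(bad)}")
    swap = (o1 > o2) | ((o1 == o2) & (df["pos1"] > df["pos2"]))
    for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("mapq1", "mapq2")):
        if a in df.columns and b in df.columns:
            va, vb = df.loc[swap, a].copy(), df.loc[swap, b].copy()
            df.loc[swap, a] = vb
            df.loc[swap, b] = va
    return df


def read_pairs_frame(path, chrom_sizes: dict | None = None):
    """Whole pairs file as a canonicalized DataFrame; returns (df, sizes)."""
    sizes = dict(chrom_sizes) if chrom_sizes else {}
    rows = []
    with _opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#chromsize:") and not chrom_sizes:
                    _, chrom, ln = line.split()
                    sizes[chrom] = int(ln)
                continue
            fields = line.split("\t")
            if len(fields) != len(COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(COLUMNS)} columns, got {len(fields)}"
                )
            rows.append(fields)
    df = pd.DataFrame(rows, columns=COLUMNS)
    for col in ("pos1", "pos2", "mapq1", "mapq2"):
        df[col] = df[col].astype("int64")
    order = {c: i for i, c in enumerate(sizes)}
    return canonicalize_frame(df, order), sizes


def write_pairs_frame(path, df: pd.DataFrame, chrom_sizes: dict):
    with _opener(path, "wt") as fh:
        fh.write("## pairs-like drophic contacts v1\n")
        for chrom, ln in chrom_sizes.items():
            fh.write(f"#chromsize: {chrom} {ln}\n")
        fh.write("#columns: " + " ".join(COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, columns=COLUMNS)
    return len(df)
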