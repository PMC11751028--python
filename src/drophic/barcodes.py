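"""Cell-barcode identification against a whitelist.

Index reads are matched to a known barcode list allowing at most one
mismatch; reads whose barcode has no hit, or is within one mismatch of
several whitelist members, are discarded.  For the multiome assay the
chromatin-side barcode list comes paired line-for-line with an RNA
barcode list, and called barcodes are translated to their RNA partner.

Matching enumerates the 3L single-base mutations of the observed barcode
against a hash set rather than scanning the whitelist, which keeps a
737K-entry 16-mer list fast; results are identical to a brute-force
Hamming search (property-tested).  ``N`` bases count as mismatches.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

__all__ = ["Whitelist", "TagSummary", "match_barcode", "tag_reads", "translate_multiome"]

_BASES = "ACGT"
_RC = str.maketrans("ACGTN", "TGCAN")


@dataclass
class Whitelist:
    """Fixed-length barcode list with optional paired translation list."""

    barcodes: list
    paired: list | None = None
    length: int = field(init=False)

    def __post_init__(self):
        if not self.barcodes:
            raise ValueError("empty whitelist")
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) != 1:
            raise ValueError(f"whitelist barcodes have mixed lengths {sorted(lengths)}")
        self.length = lengths.pop()
        self._index = {b: i for i, b in enumerate(self.barcodes)}
        if len(self._index) != len(self.barcodes):
            raise ValueError("duplicate barcodes in whitelist")
        if self.paired is not None and len(self.paired) != len(self.barcodes):
            raise ValueError("paired list length differs from primary list")

    @classmethod
    def from_file(cls, path, paired_path=None) -> "Whitelist":
        """One barcode per line; plain or gzip-compressed text."""
        return cls(_read_list(path), _read_list(paired_path) if paired_path else None)

    def __contains__(self, barcode) -> bool:
        return barcode in self._index

    def __len__(self) -> int:
        return len(self.barcodes)

    def index_of(self, barcode):
        return self._index.get(barcode)


def _read_list(path) -> list:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [line.strip() for line in fh if line.strip()]


def match_barcode(observed: str, wl: Whitelist, max_mismatch: int = 1):
    """Correct an observed barcode against the whitelist.

    Returns the whitelist member if the observed barcode matches exactly
    or has a unique member within ``max_mismatch`` Hamming distance;
    returns None when there are no hits or several.
    """
    if len(observed) != wl.length:
        raise ValueError(
            f"barcode length {len(observed)} != whitelist length {wl.length}"
        )
    if observed in wl:
        return observed
    if max_mismatch <= 0:
        return None
    if max_mismatch == 1:
        hits = set()
        obs = list(observed)
        for i, orig in enumerate(obs):
            for b in _BASES:
                if b == orig:
                    continue
                obs[i] = b
                cand = "".join(obs)
                if cand in wl:
                    hits.add(cand)
            obs[i] = orig
        return hits.pop() if len(hits) == 1 else None
    # general (rarely used) fallback: scan the whitelist
    hits = [
        b for b in wl.barcodes
        if sum(x != y for x, y in zip(observed, b)) <= max_mismatch
    ]
    return hits[0] if len(hits) == 1 else None


@dataclass
class TagSummary:
    total: int = 0
    matched: int = 0     # exact whitelist hits
    corrected: int = 0   # unique one-mismatch rescues
    discarded: int = 0   # zero or multiple hits

    def as_dict(self):
        return {
            "total": self.total,
            "matched": self.matched,
            "corrected": self.corrected,
            "discarded": self.discarded,
        }


def tag_reads(index_fastq, wl: Whitelist, max_mismatch: int = 1,
              reverse_complement: bool = False):
    """Match each index read's barcode; returns (records, summary).

    The barcode is the first L bases of the read (optionally
    reverse-complemented first).  ``records`` is a list of
    ``(read_id, barcode-or-None)``; matched + corrected + discarded ==
    total always holds.
    """
    import pysam

    records = []
    summary = TagSummary()
    with pysam.FastxFile(str(index_fastq)) as fh:
        for read in fh:
            seq = read.sequence.upper()
            if reverse_complement:
                seq = seq.translate(_RC)[::-1]
            obs = seq[: wl.length]
            summary.total += 1
            if len(obs) < wl.length:
                summary.discarded += 1
                records.append((read.name, None))
                continue
            hit = match_barcode(obs, wl, max_mismatch)
            if hit is None:
                summary.discarded += 1
            elif hit == obs:
                summary.matched += 1
            else:
                summary.corrected += 1
            records.append((read.name, hit))
    return records, summary


def translate_multiome(atac_barcode: str, wl: Whitelist):
    """Translate a chromatin-side barcode to its paired RNA barcode.

    Lists pair line-for-line; non-members return None.
    """
    if wl.paired is None:
        raise ValueError("whitelist has no paired translation list")
    i = wl.index_of(atac_barcode)
    return None if i is None else wl.paired[i]
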