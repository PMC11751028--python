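"""Seeded droplet scHi-C simulator with known truth at every stage.

The generator emulates the statistical structure the analysis modules
assume: a genome of alternating A/B compartment blocks whose sequence
composition realizes per-bin CpG densities; per-cell contact sets with a
truncated power-law distance decay, within-compartment enrichment and a
trans fraction; PCR/optical duplicates re-emitted with small leg jitter;
barcode substitution errors; ambient barcodes with tiny counts; barnyard
two-genome mixtures with planted doublets; and a three-timepoint aging
cohort with planted compartment shifts.  Every generator is
deterministic given (seed, config) and emits truth tables sufficient to
score the downstream operations.

Randomness uses one root ``SeedSequence`` with named child streams per
component, so toggling one feature does not shift another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBins, make_bins
from .pairs import COLUMNS, canonicalize_frame

__all__ = [
    "SimConfig",
    "sim_genome",
    "sim_cells",
    "sim_barcode_counts",
    "sim_barnyard",
    "sim_aging_cohort",
    "sim_index_fastq",
    "sim_joint_qc_table",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the droplet-assay regime the toolkit targets: a
    desk-scale two-chromosome genome binned at 10 kb with 100-kb
    compartment blocks, CpG densities of 0.02 (A) vs 0.005 (B), 500 true
    cells with log-normal contact counts of mean ~20,000 against 50,000
    ambient barcodes of mean ~20 contacts, 30% duplicate rate, s^-1
    distance decay, 5x within-compartment enrichment, 15% trans
    contacts, and an aging cohort with 50 bins shifted by 0.2 (z-scale
    scA/B) in old cells.
    """

    seed: int = 0
    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 5_000_000,
                                                       "chr2": 5_000_000})
    bin_size: int = 10_000
    block_size: int = 100_000
    cpg_high: float = 0.02
    cpg_low: float = 0.005
    cpg_sd_frac: float = 0.10
    n_cells: int = 500
    contacts_mean: float = 20_000.0
    contacts_sigma: float = 0.6
    n_ambient: int = 50_000
    ambient_mean: float = 20.0
    dup_rate: float = 0.30
    dup_dist: int = 100
    barcode_error_rate: float = 0.01          # raw index reads (pre-correction)
    residual_barcode_error_rate: float = 0.001  # contact records (post-correction)
    barcode_length: int = 12
    ps_exponent: float = -1.0
    min_cis_distance: int = 1_000
    enrichment: float = 5.0
    trans_rate: float = 0.15
    doublet_rate: float = 0.05
    cell_types: dict = field(default_factory=lambda: {"type1": []})
    aging_n_shift: int = 50
    aging_delta: float = 0.2
    # ratio of the total across-bin z spread to the pure A/B separation;
    # compensates dilution of the planted z shift by within-compartment
    # variance (matches the default genome geometry)
    aging_flip_calibration: float = 1.4
    aging_cells_per_timepoint: int = 200

    def __post_init__(self):
        for r in (self.dup_rate, self.barcode_error_rate, self.trans_rate,
                  self.doublet_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        if self.block_size % self.bin_size:
            raise ValueError("block_size must be a multiple of bin_size")
        if any(ln <= 0 for ln in self.chrom_sizes.values()) or not self.chrom_sizes:
            raise ValueError("chromosome lengths must be positive")


def _stream(cfg: SimConfig, name: str) -> np.random.Generator:
    """Named child RNG stream of the config's root seed."""
    key = tuple(ord(c) for c in name)
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=key))


@dataclass
class SimGenome:
    cfg: SimConfig
    bins: GenomeBins
    sequences: dict                 # chrom -> str
    compartments: np.ndarray        # +1 (A) / -1 (B) per bin
    cpg_truth: np.ndarray           # planted per-bin CpG density

    def write_fasta(self, path):
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")

    def truth_table(self) -> pd.DataFrame:
        df = self.bins.bin_table()
        df["compartment"] = np.where(self.compartments > 0, "A", "B")
        df["cpg_truth"] = self.cpg_truth
        return df


def sim_genome(cfg: SimConfig) -> SimGenome:
    """Genome of alternating A/B blocks realized in sequence.

    Per bin, a target CpG density is drawn around the block's mean
    (cpg_high for A, cpg_low for B) and realized by placing that many CG
    dinucleotides among A/T filler, so measured CpG density recovers the
    planted value up to rounding.  CpGs never straddle bin edges, and no
    CpG arises by accident (filler contains no C or G).
    """
    rng = _stream(cfg, "genome")
    bins = make_bins(cfg.chrom_sizes, cfg.bin_size)
    bpb = cfg.block_size // cfg.bin_size
    comp = np.empty(bins.n_bins, dtype=np.int8)
    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        n = bins.n_bins_of(chrom)
        blocks = (np.arange(n) // bpb) % 2
        comp[sl] = np.where(blocks == 0, 1, -1)
    mean = np.where(comp > 0, cfg.cpg_high, cfg.cpg_low)
    cpg = rng.normal(mean, mean * cfg.cpg_sd_frac)
    cpg = np.clip(cpg, 0.0, 0.45)
    sequences = {}
    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        ln = cfg.chrom_sizes[chrom]
        parts = []
        for j, b in enumerate(range(sl.start, sl.stop)):
            start = j * cfg.bin_size
            width = min(cfg.bin_size, ln - start)
            n_slots = width // 2
            n_cpg = min(int(round(cpg[b] * width)), n_slots)
            slots = np.full(n_slots, b"A", dtype="S2")
            fill = rng.integers(0, 2, size=n_slots)
            slots[:] = np.where(fill == 0, b"AT", b"TA")
            pos = rng.choice(n_slots, size=n_cpg, replace=False)
            slots[pos] = b"CG"
            s = b"".join(slots)
            if width % 2:
                s += b"T"
            parts.append(s)
        sequences[chrom] = b"".join(parts).decode("ascii")
    return SimGenome(cfg, bins, sequences, comp, cpg)


def _random_barcodes(rng, n, length):
    seen = set()
    out = []
    while len(out) < n:
        arr = rng.integers(0, 4, size=(n - len(out), length))
        for row in arr:
            bc = "".join("ACGT"[i] for i in row)
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def _draw_cis(rng, cfg, chrom_sizes, n):
    """Cis legs with counts(s) ~ s^alpha * (L - s): draw s from the
    truncated power law and place uniformly, rejecting out-of-range."""
    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    p = lengths / lengths.sum()
    ci = rng.choice(len(chroms), size=n, p=p)
    L = lengths[ci]
    smin = float(cfg.min_cis_distance + 1)
    alpha = cfg.ps_exponent
    out_p1 = np.empty(n, dtype=np.int64)
    out_p2 = np.empty(n, dtype=np.int64)
    pending = np.arange(n)
    while len(pending):
        m = len(pending)
        u = rng.random(m)
        smax = L[pending] - 1.0
        if abs(alpha + 1.0) < 1e-12:
            s = smin * (smax / smin) ** u
        else:
            a1 = alpha + 1.0
            s = (smin ** a1 + u * (smax ** a1 - smin ** a1)) ** (1.0 / a1)
        s = np.floor(s).astype(np.int64)
        p1 = rng.integers(1, L[pending].astype(np.int64) + 1)
        sign = rng.choice([-1, 1], size=m)
        p2 = p1 + sign * s
        ok = (p2 >= 1) & (p2 <= L[pending].astype(np.int64))
        idx = pending[ok]
        out_p1[idx] = p1[ok]
        out_p2[idx] = p2[ok]
        pending = pending[~ok]
    return np.array(chroms, dtype=object)[ci], out_p1, out_p2


def _draw_trans(rng, chrom_sizes, n):
    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    p = lengths / lengths.sum()
    c1 = rng.choice(len(chroms), size=n, p=p)
    c2 = rng.choice(len(chroms), size=n, p=p)
    clash = c1 == c2
    while clash.any():
        c2[clash] = rng.choice(len(chroms), size=int(clash.sum()), p=p)
        clash = c1 == c2
    p1 = rng.integers(1, lengths[c1].astype(np.int64) + 1)
    p2 = rng.integers(1, lengths[c2].astype(np.int64) + 1)
    arr = np.array(chroms, dtype=object)
    return arr[c1], p1, arr[c2], p2


def _cell_contacts(rng, cfg, genome: SimGenome, n, labels, flip_prob=0.0,
                   flip_bins=None):
    """Contacts of one cell under a compartment assignment.

    ``labels`` is the +-1 compartment sign per bin for this cell's type;
    with ``flip_prob`` > 0 the bins in ``flip_bins`` are treated as the
    opposite compartment with that probability per leg (aging shifts).
    Cross-compartment pairs are accepted with probability 1/enrichment.
    """
    bins = genome.bins
    n_trans = int(rng.binomial(n, cfg.trans_rate)) if len(cfg.chrom_sizes) > 1 else 0
    n_cis = n - n_trans
    rows_c1 = []
    rows_p1 = []
    rows_c2 = []
    rows_p2 = []

    def leg_labels(chrom_arr, pos_arr):
        lab = np.empty(len(pos_arr), dtype=np.int8)
        for chrom in pd.unique(chrom_arr):
            m = chrom_arr == chrom
            b = bins.bin_of(chrom, pos_arr[m])
            lab[m] = labels[b]
            if flip_prob > 0.0 and flip_bins is not None:
                shifted = flip_bins[b]
                flip = shifted & (rng.random(int(m.sum())) < flip_prob)
                lab_m = lab[m]
                lab_m[flip] = -lab_m[flip]
                lab[m] = lab_m
        return lab

    def fill(n_needed, draw):
        got = 0
        while got < n_needed:
            m = n_needed - got
            c1, p1, c2, p2 = draw(m)
            l1 = leg_labels(c1, p1)
            l2 = leg_labels(c2, p2)
            same = l1 == l2
            accept = same | (rng.random(m) < 1.0 / cfg.enrichment)
            idx = np.flatnonzero(accept)[: n_needed - got]
            rows_c1.append(c1[idx])
            rows_p1.append(p1[idx])
            rows_c2.append(c2[idx])
            rows_p2.append(p2[idx])
            got += len(idx)

    fill(n_cis, lambda m: (lambda c, a, b: (c, a, c, b))(
        *_draw_cis(rng, cfg, cfg.chrom_sizes, m)))
    if n_trans:
        fill(n_trans, lambda m: _draw_trans(rng, cfg.chrom_sizes, m))
    c1 = np.concatenate(rows_c1)
    p1 = np.concatenate(rows_p1)
    c2 = np.concatenate(rows_c2)
    p2 = np.concatenate(rows_p2)
    return c1, p1, c2, p2


def _mutate_barcodes(rng, barcodes, rate):
    """Substitute one random base with probability ``rate`` per record."""
    out = list(barcodes)
    hit = np.flatnonzero(rng.random(len(out)) < rate)
    for i in hit:
        bc = out[i]
        pos = int(rng.integers(len(bc)))
        base = "ACGT"[int(rng.integers(4))]
        out[i] = bc[:pos] + base + bc[pos + 1:]
    return out, hit


@dataclass
class SimCells:
    contacts: pd.DataFrame          # emitted records incl. duplicates, shuffled
    barcode_truth: pd.DataFrame     # barcode, kind, cell_type, n_unique, n_dup
    is_duplicate: np.ndarray        # per emitted row, aligned with contacts
    true_barcode: np.ndarray        # per emitted row, before substitution errors
    genome: SimGenome


def sim_cells(cfg: SimConfig, genome: SimGenome | None = None,
              assignment_overrides: dict | None = None,
              timepoint_of: dict | None = None) -> SimCells:
    """Simulate cells + ambient barcodes as an emitted contact stream.

    Per cell: a log-normal unique-contact count; cis distances from the
    truncated power law; partners enriched within the cell type's
    compartment assignment; duplicates re-emitted with per-leg jitter
    uniform on [0, dup_dist]; barcode substitution errors at
    ``residual_barcode_error_rate`` (contact records carry
    whitelist-corrected barcodes, so only uncorrectable errors survive to
    this stage; raw index-read errors at ``barcode_error_rate`` live in
    :func:`sim_index_fastq`).  Ambient barcodes draw Poisson counts
    around ``ambient_mean``.  Output order is shuffled.
    """
    genome = genome or sim_genome(cfg)
    if cfg.enrichment > 1 and len(np.unique(genome.compartments)) < 2:
        raise ValueError("compartment enrichment needs two compartments")
    rng = _stream(cfg, "cells")
    types = list(cfg.cell_types)
    assignments = {}
    for t in types:
        lab = genome.compartments.copy()
        for b in cfg.cell_types[t]:
            lab[b] = -lab[b]
        if assignment_overrides and t in assignment_overrides:
            lab = assignment_overrides[t]
        assignments[t] = lab

    barcodes = _random_barcodes(rng, cfg.n_cells + cfg.n_ambient, cfg.barcode_length)
    cell_bcs = barcodes[: cfg.n_cells]
    ambient_bcs = barcodes[cfg.n_cells:]

    mu = np.log(cfg.contacts_mean) - cfg.contacts_sigma ** 2 / 2.0
    n_per_cell = np.maximum(
        1, np.rint(rng.lognormal(mu, cfg.contacts_sigma, cfg.n_cells))
    ).astype(int)
    cell_type = [types[i] for i in rng.integers(0, len(types), cfg.n_cells)]

    frames = []
    truth_rows = []
    for i, bc in enumerate(cell_bcs):
        n = n_per_cell[i]
        lab = assignments[cell_type[i]]
        c1, p1, c2, p2 = _cell_contacts(rng, cfg, genome, n, lab)
        frames.append(pd.DataFrame({
            "barcode": bc, "chrom1": c1, "pos1": p1, "chrom2": c2, "pos2": p2,
        }))
        truth_rows.append((bc, "cell", cell_type[i], n))
    n_amb = rng.poisson(cfg.ambient_mean, cfg.n_ambient)
    for bc, n in zip(ambient_bcs, n_amb):
        if n == 0:
            truth_rows.append((bc, "ambient", "", 0))
            continue
        c1, p1, c2, p2 = _cell_contacts(rng, cfg, genome, int(n),
                                        genome.compartments)
        frames.append(pd.DataFrame({
            "barcode": bc, "chrom1": c1, "pos1": p1, "chrom2": c2, "pos2": p2,
        }))
        truth_rows.append((bc, "ambient", "", int(n)))
    df = pd.concat(frames, ignore_index=True)
    df["mapq1"] = 60
    df["mapq2"] = 60

    # plant duplicates: each unique record spawns one jittered copy w.p. dup_rate
    dup_rng = _stream(cfg, "dups")
    dup_of = np.flatnonzero(dup_rng.random(len(df)) < cfg.dup_rate)
    dups = df.iloc[dup_of].copy()
    sizes = {c: ln for c, ln in cfg.chrom_sizes.items()}
    for col_c, col_p in (("chrom1", "pos1"), ("chrom2", "pos2")):
        jit = dup_rng.integers(0, cfg.dup_dist + 1, size=len(dups))
        limit = dups[col_c].map(sizes).values
        dups[col_p] = np.minimum(dups[col_p].values + jit, limit)
    emitted = pd.concat([df, dups], ignore_index=True)
    is_dup = np.zeros(len(emitted), dtype=bool)
    is_dup[len(df):] = True

    # barcode substitution errors on emitted records
    err_rng = _stream(cfg, "bcerr")
    true_bc = emitted["barcode"].to_numpy(copy=True)
    mutated, _ = _mutate_barcodes(err_rng, true_bc, cfg.residual_barcode_error_rate)
    emitted["barcode"] = mutated

    order = _stream(cfg, "shuffle").permutation(len(emitted))
    emitted = emitted.iloc[order].reset_index(drop=True)
    is_dup = is_dup[order]
    true_bc = true_bc[order]

    chrom_order = {c: i for i, c in enumerate(cfg.chrom_sizes)}
    emitted = canonicalize_frame(emitted[COLUMNS], chrom_order)

    dup_counts = pd.Series(true_bc[is_dup]).value_counts()
    truth = pd.DataFrame(truth_rows,
                         columns=["barcode", "kind", "cell_type", "n_unique"])
    truth["n_dup"] = truth["barcode"].map(dup_counts).fillna(0).astype(int)
    if timepoint_of:
        truth["timepoint"] = truth["cell_type"].map(timepoint_of)
    return SimCells(emitted, truth, is_dup, true_bc, genome)


def sim_barcode_counts(cfg: SimConfig):
    """Barcode-rank mixture as counts only (no contact records).

    True cells draw log-normal contact counts (mean ``contacts_mean``);
    ambient barcodes draw Poisson(``ambient_mean``).  Returns
    ``(counts Series indexed by barcode, truth DataFrame)``.
    """
    rng = _stream(cfg, "counts")
    barcodes = _random_barcodes(rng, cfg.n_cells + cfg.n_ambient, cfg.barcode_length)
    mu = np.log(cfg.contacts_mean) - cfg.contacts_sigma ** 2 / 2.0
    cell_counts = np.maximum(
        1, np.rint(rng.lognormal(mu, cfg.contacts_sigma, cfg.n_cells))
    ).astype(int)
    amb_counts = rng.poisson(cfg.ambient_mean, cfg.n_ambient)
    counts = pd.Series(
        np.concatenate([cell_counts, amb_counts]), index=barcodes, name="n_contacts"
    )
    truth = pd.DataFrame({
        "barcode": barcodes,
        "kind": ["cell"] * cfg.n_cells + ["ambient"] * cfg.n_ambient,
        "n_contacts": counts.values,
    })
    return counts, truth


def sim_barnyard(cfg: SimConfig, genome_prefixes=("hg", "mm"),
                 cross_noise: float = 0.01, contacts_mean: float = 1000.0):
    """Two-species mixture with planted doublets.

    Droplets are doublets with probability ``doublet_rate``; singlets
    draw each contact from the wrong genome with probability
    ``cross_noise`` (<= 2%), doublets mix the genomes ~1:1.  Returns
    ``(per-barcode counts DataFrame, truth DataFrame)`` with genome
    counts n_genomeA / n_genomeB.
    """
    rng = _stream(cfg, "barnyard")
    n = cfg.n_cells
    barcodes = _random_barcodes(rng, n, cfg.barcode_length)
    is_doublet = rng.random(n) < cfg.doublet_rate
    total = np.maximum(
        20, np.rint(rng.lognormal(np.log(contacts_mean) - 0.125, 0.5, n))
    ).astype(int)
    rows = []
    truth = []
    for i, bc in enumerate(barcodes):
        if is_doublet[i]:
            w = float(np.clip(rng.normal(0.5, 0.05), 0.3, 0.7))
            nA = int(rng.binomial(total[i], w))
            truth.append((bc, "doublet", ""))
        else:
            genome = "A" if rng.random() < 0.5 else "B"
            nX = int(rng.binomial(total[i], 1.0 - cross_noise))
            nA = nX if genome == "A" else total[i] - nX
            truth.append((bc, "singlet", genome))
        rows.append((bc, nA, total[i] - nA))
    counts = pd.DataFrame(rows, columns=["barcode", "n_genomeA", "n_genomeB"])
    truth = pd.DataFrame(truth, columns=["barcode", "kind", "genome"])
    return counts, truth


def sim_aging_cohort(cfg: SimConfig):
    """Three-timepoint cohort with compartment shifts planted in "old".

    Young and middle-aged cells share the genome's compartment
    assignment; in old cells, ``aging_n_shift`` randomly chosen bins are
    treated as the opposite compartment with probability
    ``aging_delta / 2`` per contact leg, which yields a z-scale scA/B
    median shift of about ``aging_delta`` at these bins.  Returns
    ``(dict timepoint -> SimCells-like contacts DataFrame, truth dict)``.
    """
    genome = sim_genome(cfg)
    pick_rng = _stream(cfg, "aging-bins")
    shifted = np.sort(pick_rng.choice(genome.bins.n_bins, cfg.aging_n_shift,
                                      replace=False))
    flip_bins = np.zeros(genome.bins.n_bins, dtype=bool)
    flip_bins[shifted] = True
    flip_prob = min(0.5, cfg.aging_delta / 2.0 * cfg.aging_flip_calibration)

    cohort = {}
    for tp in ("young", "middle", "old"):
        rng = _stream(cfg, f"aging-{tp}")
        n_cells = cfg.aging_cells_per_timepoint
        barcodes = [f"{tp}-{i:05d}" for i in range(n_cells)]
        mu = np.log(cfg.contacts_mean) - cfg.contacts_sigma ** 2 / 2.0
        n_per = np.maximum(
            1, np.rint(rng.lognormal(mu, cfg.contacts_sigma, n_cells))
        ).astype(int)
        frames = []
        for bc, n in zip(barcodes, n_per):
            c1, p1, c2, p2 = _cell_contacts(
                rng, cfg, genome, int(n), genome.compartments,
                flip_prob=flip_prob if tp == "old" else 0.0,
                flip_bins=flip_bins,
            )
            frames.append(pd.DataFrame({
                "barcode": bc, "chrom1": c1, "pos1": p1,
                "chrom2": c2, "pos2": p2,
            }))
        df = pd.concat(frames, ignore_index=True)
        df["mapq1"] = 60
        df["mapq2"] = 60
        chrom_order = {c: i for i, c in enumerate(cfg.chrom_sizes)}
        cohort[tp] = canonicalize_frame(df[COLUMNS], chrom_order)
    # expected shift direction: B->A raises partner CpG (positive delta)
    direction = np.where(genome.compartments[shifted] < 0, 1, -1)
    truth = {"shifted_bins": shifted, "direction": direction, "genome": genome}
    return cohort, truth


def sim_index_fastq(cfg: SimConfig, path, whitelist, n_reads: int = 300,
                    error_rate: float | None = None):
    """Index-read FASTQ over a whitelist, with substitution errors.

    Returns the truth table (read id, true barcode, emitted barcode).
    """
    rng = _stream(cfg, "fastq")
    error_rate = cfg.barcode_error_rate if error_rate is None else error_rate
    wl = list(whitelist)
    picks = rng.integers(0, len(wl), n_reads)
    true = [wl[i] for i in picks]
    emitted, _ = _mutate_barcodes(rng, true, error_rate)
    rows = []
    with open(path, "w") as fh:
        for i, (t, e) in enumerate(zip(true, emitted)):
            rid = f"read{i:06d}"
            fh.write(f"@{rid}\n{e}\n+\n" + "I" * len(e) + "\n")
            rows.append((rid, t, e))
    return pd.DataFrame(rows, columns=["read_id", "true_barcode", "emitted_barcode"])


def sim_joint_qc_table(cfg: SimConfig, n_cells: int = 200,
                       fail_fraction: float = 0.3) -> pd.DataFrame:
    """Per-cell RNA + chromatin QC metrics with a planted failing subset."""
    rng = _stream(cfg, "jointqc")
    n_fail = int(round(n_cells * fail_fraction))
    good = pd.DataFrame({
        "umis": rng.integers(800, 5000, n_cells - n_fail),
        "genes": rng.integers(500, 3000, n_cells - n_fail),
        "contacts": rng.integers(1500, 50000, n_cells - n_fail),
        "mito_frac": rng.uniform(0.0, 0.08, n_cells - n_fail),
        "trans_rate": rng.uniform(0.05, 0.40, n_cells - n_fail),
        "truth_pass": True,
    })
    # each failing cell violates exactly one threshold
    metrics = ["umis", "genes", "contacts", "mito_frac", "trans_rate"]
    fails = []
    for i in range(n_fail):
        row = {
            "umis": int(rng.integers(800, 5000)),
            "genes": int(rng.integers(500, 3000)),
            "contacts": int(rng.integers(1500, 50000)),
            "mito_frac": float(rng.uniform(0.0, 0.08)),
            "trans_rate": float(rng.uniform(0.05, 0.40)),
            "truth_pass": False,
        }
        which = metrics[int(rng.integers(5))]
        if which == "umis":
            row["umis"] = int(rng.integers(0, 501))
        elif which == "genes":
            row["genes"] = int(rng.integers(0, 401))
        elif which == "contacts":
            row["contacts"] = int(rng.integers(0, 1001))
        elif which == "mito_frac":
            row["mito_frac"] = float(rng.uniform(0.10, 0.5))
        else:
            row["trans_rate"] = float(rng.uniform(0.45, 0.9))
        fails.append(row)
    df = pd.concat([good, pd.DataFrame(fails)], ignore_index=True)
    df.insert(0, "barcode", [f"bc{i:05d}" for i in range(len(df))])
    return df
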