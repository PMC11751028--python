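# drophic

Droplet single-cell Hi-C (scHi-C) preprocessing and chromatin-architecture
statistics: from barcode-annotated read pairs to called cells, per-cell
A/B-compartment scores, pseudobulk/metacell contact maps, insulation and
TAD-boundary analysis, and metacell-level differential tests — with a
seeded synthetic-data generator that carries ground truth for every stage.

## Who it is for

Droplet microfluidics makes scHi-C cheap at the cost of a messy readout:
tens of thousands of ambient barcodes with a handful of ligation products
surround the real cells, duplicates inflate counts, and per-cell contact
maps are too sparse for eigenvector compartment calling. `drophic`
implements the computational path a droplet scHi-C experiment needs:

- **Barcode calling** — index reads matched to a whitelist allowing one
  mismatch; reads with zero or multiple hits are discarded; multiome
  (ATAC↔RNA) barcode translation.
- **Contact extraction & dedup** — mapq ≥ 20 on both legs, cis contacts
  > 1 kb; barcode-aware duplicate collapse: two contacts are duplicates
  iff they share the barcode and chromosome pair and both legs lie within
  `dup_dist` (100 bp) of each other.
- **Cell calling** — knee of the log-log barcode-rank curve via the
  kneedle algorithm, with the sensitivity swept over 1..10 and the
  setting whose called cells retain just over 85% of all contacts
  selected.
- **QC** — barnyard (species-mixing) collision analysis with the strict
  rule `mixing rate = min(nA, nB)/(nA+nB) > 20% ⇒ doublet`; distance-band
  cell-cycle metrics; the joint multiome filter (> 500 UMIs, > 400 genes,
  > 1000 contacts, < 10% mito, < 45% trans).
- **scA/B compartment scores** — per cell and bin,
  `scA/B(b) = mean CpG density of the partner bins of b's contacts`;
  CpG-rich partners ⇒ A compartment. Raw scores feed gene-module means,
  per-cell z-scores feed cross-cell comparisons.
- **Maps & topology** — pseudobulk/metacell aggregation, iterative
  correction balancing, P(s) distance-decay curves, diamond insulation
  scores `log2(raw_square / chromosome mean)`, TAD boundaries as
  prominence-filtered insulation minima, per-gene TSS boundary usage, and
  domain melting via a two-sample KS test on insulation-square values
  (genes > 300 kb at 50-kb resolution).
- **Differential statistics** — metacells (not single cells) as the unit
  of replication; per-bin Wilcoxon rank-sum on metacell median scA/B,
  Benjamini–Hochberg adjustment, significance at adjusted p < 0.01 with an
  effect filter |ΔscA/B| > 0.05; gene-module scores with between-timepoint
  tests.
- **Simulator** — seeded generator for every regime above (compartment
  genomes realized in sequence, power-law contact decay, planted
  duplicates, barnyard doublets, aging compartment shifts) with truth
  tables.

## Worked example

`python examples/01_cell_calling.py` simulates 500 true cells (log-normal
contact counts, mean ≈ 20,000) among 50,000 ambient barcodes (≈ 20
contacts each) and calls cells adaptively:

```
sensitivity selected : 1
knee rank            : 500
count threshold      : 2177
retained contacts    : 90.9%
barcodes called      : 500 (true cells: 500)
recall / precision   : 1.000 / 1.000
```

The knee lands exactly at the cell/ambient cliff: all 500 true cells are
called, no ambient barcode passes, and the called cells hold 90.9% of all
contacts — above the 85% retention target that drives the sensitivity
selection. `examples/05_aging_differential.py` continues the pipeline to
the differential stage and recovers 96% of 50 planted compartment shifts
at adjusted p < 0.01 with zero false positives.

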