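# Methods

This note records the models and procedures `drophic` implements, the
parameters that matter, what the simulator does and does not emulate, and
the numerical choices made where the design was genuinely open. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Coordinates and containers

Contacts are 1-based (pairs-file convention); genome bins are 0-based
half-open and tile each chromosome at a fixed `bin_size` (last bin may be
short). Chromosome order is the order of the chromosome-sizes input, and
contact legs are stored canonically (chrom1 ≤ chrom2 in that order,
pos1 ≤ pos2 for cis). Contacts are unstranded. All per-bin quantities are
`BinTrack`s (one float per bin, NaN = missing); missing is never
zero-filled.

## Barcode calling

Observed index barcodes are corrected against a whitelist allowing one
mismatch: an exact member is returned as-is; otherwise the unique member
at Hamming distance 1 is returned; zero or several candidates discard the
read. Matching enumerates the 3L single-base mutations of the query
against a hash set — identical to a brute-force all-pairs scan (property
tested) but O(L) per read at 737K-whitelist scale. `N` counts as a
mismatch at its position. The barcode is the first L bases of the read;
reverse-complement handling is a flag (off by default) since index
orientation is platform-specific.

## Contact extraction and deduplication

Read pairs become contacts when both legs are mapped with
mapq ≥ `min_mapq` (20) and, for cis pairs, the separation exceeds
`min_cis_distance` (1 kb) — shorter products are dominated by
self-ligation/religation artefacts. Trans pairs are always eligible.

Duplicates are collapsed barcode-aware: within records sorted by
(barcode, chrom1, chrom2, pos1, pos2), a contact is a duplicate iff some
already-retained contact shares its barcode and chromosome pair and both
legs differ by ≤ `dup_dist` (100 bp). The first record in sort order is
the retained representative, so duplicate chains collapse onto their
earliest member; the comparison runs after canonical leg ordering. This
greedy rule is deterministic, idempotent, and matched against an O(n²)
clustering oracle in the tests. The sliding window over pos1 makes the
pass linear for realistic densities.

## Cell calling

Cells are separated from ambient barcodes at the knee of the barcode-rank
curve, detected on log10(rank) vs log10(count) axes with the kneedle
algorithm: min–max normalize both axes, reflect the decreasing convex
curve to concave increasing, form the difference curve d = y′ − x′, and
accept the first local maximum of d that the curve later undercuts by
more than S · mean(Δx′), where S is the sensitivity.

Two robustness choices, both config-exposed:

- **Uniform-grid resampling (default 1000 points).** Kneedle's
  sensitivity threshold presumes uniformly spaced x. A raw 50,000-point
  rank curve has mean Δx′ ≈ 2×10⁻⁵ on log axes — the threshold becomes
  vacuous and count noise in the cell plateau fires a spurious knee at
  rank ~5, discarding >90% of library mass. Linear interpolation onto a
  uniform log-rank grid restores the threshold's meaning.
- **Positive-d candidates.** A genuinely convex decreasing curve has
  d ≥ 0 everywhere after reflection, so local maxima with d < 0 are local
  shape violations (noise), not knees; they are not eligible candidates.
- **Cliff snapping.** The grid has ~1% rank resolution; the returned knee
  is snapped to the steepest log-log drop of the raw curve within ±20% in
  rank, so the count threshold sits exactly at the cell/ambient cliff
  when one exists. Barcodes tied with the threshold count are called.

The sensitivity is swept (1..10 by default) and, among settings whose
called cells retain at least `target_retention` (85%) of all contacts,
the one with the smallest retained fraction — closest above the target —
is selected; if none reaches the target the best is returned with a
warning, and a curve with no knee at any sensitivity calls everything
with a warning rather than guessing.

## Species mixing, cycle metrics, joint QC

Barnyard reads are assigned to a genome by chromosome-name prefix of a
concatenated reference; the per-barcode mixing rate is
min(nA, nB)/(nA + nB) ∈ [0, 0.5] and a barcode is a doublet iff the rate
is strictly greater than 0.20. The unit counted here is the contact
(each simulated contact is genome-pure); an optional summary doubling of
the observed cross-species rate to estimate total collisions is off by
default.

Cell-cycle metrics summarise each cell's cis-distance mass into bands —
short [25 kb, 2 Mb), mitotic [2 Mb, 12 Mb), far [12 Mb, ∞) — plus the
trans fraction. Band fractions are taken over all cis contacts, so
sub-25-kb mass makes them sum below one. Phase labels are deliberately
not assigned: the decision boundaries are a lab prior, and a user-given
rule table can map metrics to phases.

The joint multiome filter keeps cells with UMIs > 500, genes > 400,
contacts > 1000, mitochondrial fraction < 0.10 and trans rate < 0.45 —
all strict inequalities; any missing metric fails the cell as
"incomplete".

## scA/B compartment scores

For one cell, scA/B(b) is the mean CpG density of the partner bins of
all contacts with exactly one leg in bin b; a contact within a single bin
has no partner and is excluded; bins touched by fewer than
`min_partner_contacts` (1) contacts are masked. Both cis (> 1 kb,
inherited from extraction) and trans partners contribute with weight 1;
`--cis-only` and a minimum-distance flag cover the plausible variants.
Raw values are bounded by the CpG track's range. Z-scoring is per cell
over unmasked bins (population SD); cells with < 2 unmasked bins or zero
spread are left raw and flagged. Gene-level scores average unmasked bins
overlapped by the gene body (any overlap, no flanks); marker-set scores
average each set's gene bins, and cluster labels take the type with the
maximal mean score over the cluster's cells (ties broken by type order
and flagged).

CpG density itself counts CG dinucleotides by the bin of the C, so an
edge-straddling CpG counts once; counting is case-insensitive and
ambiguous bases never form a CpG.

## Maps, balancing, topology

Aggregation pools contacts by group label into symmetric binned count
matrices; the upper-triangle mass equals the number of labeled contacts,
and unlabeled contacts are dropped and counted. Balancing is iterative
correction: per-bin factors w are updated by the weighted marginals until
their coefficient of variation falls below `tol` (1e-6) or `max_iter`
(200), with bins excluded when their coverage is zero or their log10
marginal lies more than `mad_max` (5) MADs below the median; excluded
bins carry NaN weights.

P(s) divides observed cis contacts in log-spaced distance bins by the
exact number of bp locus pairs at those separations (Σ over chromosomes
of L − s), so a homogeneous polymer with P(s) ∝ s^a gives a log-log line
of slope a.

Insulation is the diamond score: raw_square(i) = mean (balanced)
interaction over [i−w, i) × [i, i+w) with w = window/bin_size, and
normalized(i) = log2(raw_square(i)/chromosome mean); bins within w of a
chromosome end are missing, and an empty diamond gives −inf — a genuine
deep minimum, kept (only NaN means "missing"). Boundaries are local
minima of the normalized track with prominence ≥ `min_strength` (0.1 in
log2 units). Boundary usage for a gene is the fraction of a cluster's
members (cells or metacells — both are accepted membership lists) whose
boundary set contains the gene's TSS bin.

Domain melting compares per-bin insulation-square values over a gene's
body between two conditions with a two-sample Kolmogorov–Smirnov test on
genes longer than 300 kb (50-kb bins by default); score = −log10 p, and
the domain is "melted" when the target condition's mean decreased,
"established" when it increased. Genes with fewer than 4 finite bins in
either condition are flagged underpowered.

## Differential statistics

The unit of replication is the metacell: a user-supplied sub-clustering
pools cells, and each metacell's per-bin value is the median over its
members' unmasked values, masked when fewer than half the members are
unmasked. Bin-level differential tests run on per-cell **z-scored**
scA/B; gene-module scores use **raw** scA/B — the two scales' intended
uses. Per bin, groups are compared with the Wilcoxon rank-sum test
(exact enumeration when the pooled size is ≤ 12 with no ties, otherwise
the normal approximation with midrank tie correction and continuity
correction; identical constant samples give p = 1). P-values are BH
step-up adjusted within one comparison; bins pass at adjusted p < 0.01,
and summary direction counts additionally require |Δ| > 0.05, where Δ is
the difference of group medians of metacell medians. Bins masked in more
than half of either group are left untested and recorded.

## Simulator

The generator emulates the statistical structure the analyses assume,
with named RNG substreams per component so toggling one feature does not
shift another's draws, and truth tables sufficient to score every
downstream operation.

- **Genome**: alternating A/B blocks (100 kb) over two 5-Mb chromosomes
  at 10-kb bins; per-bin CpG targets ~ Normal(block mean, 10%) with
  A = 0.02, B = 0.005, realized by placing exactly that many CG
  dinucleotides among A/T filler — measured CpG density recovers the
  planted value to rounding, no accidental or edge-straddling CpGs.
- **Cells**: log-normal contact counts (default mean 20,000, σ_log 0.6 —
  the deep-library droplet regime); cis distances from a truncated power
  law with exponent −1, placed by rejection so counts(s) ∝ s^a(L−s),
  which is exactly what the P(s) estimator inverts; trans contacts at
  rate 0.15; cross-compartment pairs accepted with probability
  1/enrichment (5). The acceptance step modulates P(s) only through the
  same/cross probability profile; the fitted slope stays within the
  tested ±0.1 band.
- **Duplicates**: each unique record spawns a jittered copy (per-leg
  jitter uniform on [0, dup_dist]) with probability 0.30, so duplicates
  are 0.30/1.30 ≈ 23% of emitted records.
- **Barcode errors**: contact records carry whitelist-corrected barcodes,
  so only residual uncorrectable errors (0.001) appear there; raw
  index-read errors (0.01) live in the FASTQ emitter for the barcode
  module.
- **Ambient**: 50,000 barcodes with Poisson(20) contacts drawn from the
  genome-wide assignment.
- **Barnyard**: singlets draw each contact from the wrong genome with
  probability 0.01; doublets (rate 0.05) mix genomes with weight
  ~ Normal(0.5, 0.05).
- **Aging cohort**: three timepoints; "old" cells treat 50 randomly
  chosen bins as the opposite compartment with probability
  Δ/2 × calibration when drawing partners. The calibration (1.4) is the
  ratio of the total across-bin z spread to the pure A/B separation for
  the default genome geometry: without it the realized z-scale shift
  under-delivers the planted Δ because within-compartment CpG variance
  inflates the z denominator. With it, the realized metacell median
  shift matches Δ = 0.2. The default cohort is 200 cells per timepoint
  pooled into 20 metacells of 10 — a design sized so the rank-sum
  p-floor (≈7×10⁻⁸ at 20 vs 20) sits far below the BH threshold for 50
  true bins among 1000; at 10 vs 10 the floor (1.8×10⁻⁴) is itself above
  that threshold and no design can pass.

What the simulator does **not** emulate: read-level alignment (contacts
are generated directly), restriction-fragment geometry, polymer-model 3D
structure, copy-number variation, distance-dependent compartment mixing
beyond the block profile, or an RNA modality beyond per-cell QC counts.
Passing tests therefore validate the statistical machinery — knee
geometry, dedup semantics, score recovery, test calibration — not
alignment artefacts or fine-scale map structure in real libraries.

## Numerical choices and degenerate inputs

- Rank curves drop zero-count barcodes; a curve with < 2 distinct counts
  raises and advises a manual threshold.
- Balancing non-convergence emits weights with a warning flag rather
  than failing.
- KS p-values are floored at 1e-300 before −log10.
- Empty inputs return empty outputs (stats tables, BH on an empty
  vector); an empty cell yields an all-masked scA/B vector.
- Problem sizes in tests (cells, contacts per cell, cohort size) are the
  package's desk-scale study conditions; the acceptance criteria's stated
  sizes (500 cells / 50,000 ambient / mean 20,000 contacts; 50 shifted
  bins among 1000 at Δ = 0.2) are kept exactly where stated.

## Known limitations

- Eigenvector (PCA) compartment calling on pseudobulk, loop calling,
  saddle plots and imputation-based embeddings are out of scope.
- The kneedle resampling grid (1000 points) and snap window (±20% rank)
  are robust defaults, not fitted constants; pathological curves (e.g.
  multimodal cell populations spanning the ambient range) may need the
  manual threshold escape hatch.
- The rank-sum asymptotic branch is conservative at very small group
  sizes; designs with < 12 metacells per group cannot reach BH-adjusted
  p < 0.01 over ~1000 bins (see the power note above) — this is a
  property of the test, not of the implementation.
- Cycle-phase labels are not assigned; only metrics are computed.
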