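# Methods

This note documents the models and procedures implemented in `mabid`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Read model and demultiplexing

A raw read is expected to start directly with the barcoded adapter:

```
[UMI1 (3 nt)][SBC1 (4 nt)][UMI2 (3 nt)][SBC2 (4 nt)][AGGGCCGC][ABBC (8 nt)][genomic]
```

The two sample-barcode halves concatenate to an 8-nt sample barcode (SBC);
the antibody barcode field (ABBC) is stored as the full observed 8-mer —
the 6-nt antibody barcode proper plus the 2-nt restriction-site remnant the
adapter chemistry leaves next to the genomic insert. Whitelists therefore
hold 8-nt entries for both fields, and the remnant content travels with the
whitelist rather than being hard-coded.

**Matching.** The adapter is anchored at position 0. UMI positions are
wildcards; mismatches are counted against the SBC fields (versus the
whitelist), the constant linker and the ABBC field (versus the whitelist),
with `N`/non-ACGT counting as a mismatch. A single 1-nt insertion or
deletion is additionally tolerated inside either UMI (at the read start for
the first UMI), costing one error. A read matches when total errors ≤ 2 and
at least 29 adapter positions are covered. Because the segments are
disjoint, the best decomposition factorizes into per-field minima; the test
suite cross-checks this against an exhaustive enumerator over all
(whitelist pair × indel placement) candidates. Ties are broken by fewest
errors, then indel position (none, read start, second UMI), then
lexicographic barcode. Barcode rescue at Hamming distance 1 is only
accepted when unambiguous: a field whose minimal distance is achieved by two
whitelist entries rejects the read rather than guessing, so one whitelist
barcode can never be corrected into another.

**Classification ladder.** Class 1: perfect structure, zero non-UMI errors.
Class 2: the sole defect is a 1-nt indel in the first UMI. Class 3: full
structure with 1–2 mismatches, barcodes rescued unambiguously. Class 4: a
1-nt indel in a UMI plus at most one mismatch. Classes 5–7 cover reads where
only the constant linker is recognizable (shifted by one; one mismatch;
intact at the expected offset), and class 0 is everything else. Only
classes 1–2 enter the default pipeline; 3–7 exist for QC reporting. The
ladder below class 2 is a package definition (configurable), since only the
top two tiers have a fixed published meaning; we restrict class-4 indels to
the second UMI because an indel inside a 4-nt barcode field is not
distinguishable from substitutions within a 2-error budget.

## Ligation-site filtering and counting

Only reads whose 5′ end sits exactly where restriction digestion plus
adapter ligation would place it are counted. For MboI (`^GATC`) that is the
motif start on the plus strand and the motif's last base on the minus
strand; for MseI (`T^TAA`) it is motif start + 1 on the plus strand and
motif start + 2 on the minus strand (the mirror of the cut site on the
palindromic motif — published processing states the rule once, for the plus
strand; the minus-strand mirror is our reading and is configurable).
Alignments below MAPQ 10 are discarded. The reported site coordinate is
always the motif start, so site coordinates are by construction a subset of
motif coordinates.

UMIs are flattened per (sample, epitope, site): the count is the number of
distinct UMIs, capped at 1,000 for bulk samples and 2 for single cells (the
single-cell cap acknowledges that two alleles bound the true molecule count
per site). Species assignment on composite two-genome references keeps the
strictly better-scoring species and discards cross-species score ties;
allele assignment prefers lower edit distance, then higher alignment score,
else ambiguous.

Counts are binned into half-open, 0-based fixed-width bins; bins overlapping
blacklist/low-mappability intervals are zeroed and flagged, and stay flagged
through normalization (as missing values) and segmentation (excluded from
emission sequences; enriched-domain runs may bridge masked gaps of at most
one bin by default).

## Normalization

The no-antibody control captures the accessibility background of the
restriction–ligation chemistry, so sample tracks are expressed as log2 fold
change over control on depth-normalized values:

- `TPM_bin = UMI_bin / (total_UMI / 10⁶)`, `RPKM_bin = TPM_bin / (bin_size / 1000)`
- `logcounts_bin = log₂((φ + RPKM_sample) / (φ + RPKM_control))` with φ = 1.

`logcounts` is exactly antisymmetric in its arguments and identically zero
for a sample normalized against itself; both identities are asserted to
1e-12 in the tests. Browser export clips negative values to zero for
display only — analysis values are never clipped.

## HMM segmentation

Tracks are segmented with a Gaussian-emission hidden Markov model fitted by
EM on the genome-wide concatenation of unmasked bins and Viterbi-decoded per
chromosome. Initializations: means [0, 1] with σ [0, 1] for raw tracks and
means [−1, 0, 1] with σ [1, 1, 1] for normalized tracks. A zero initial σ is
degenerate for a Gaussian, so initial standard deviations are floored at
10⁻². The transition matrix starts at 0.9 self-transition (uniform
off-diagonal) to encourage contiguous domains; all parameters are then
re-estimated by EM (tolerance 10⁻⁶, ≤ 500 iterations, no random restarts —
fitting is deterministic given the seed). The enriched state is the fitted
state with the highest mean; domains are maximal runs of that state. EM can
empty a state on degenerate input (e.g. a constant track); zero-sum
probability rows are repaired to uniform after fitting so decoding stays
defined. The likelihood sequence is non-decreasing up to the convergence
tolerance; the terminal step may jitter by ~1e-8 in floating point.

## FRiP and SEiP

FRiP is the fraction of raw counts inside a region set (a bin belongs to a
region when they share ≥ 1 bp). Normalized tracks carry negative,
non-integer values, for which SEiP replaces the read-sum with the mean
signal over region bins and calibrates it against a randomization null:
every interval is re-placed uniformly at random on the unmasked genome,
preserving its length and chromosome (placed intervals may overlap each
other — the simplest null consistent with uniform re-placement);
`SEiP_scaled = (observed − μ_null) / σ_null` over 1,500 permutations by
default. The statistic is invariant to adding a constant to the track, and
on exchangeable noise its distribution over replicate region sets is
standard normal within sampling error (checked at 100 replicates × 200
permutations; 200 permutations keep the check fast and only widen the null
moments by ~0.5%).

Reference region sets follow the published construction rules: ChromHMM
states are merged by name-prefix groups (Enh\*, ReprPC\*, TssA/TssFlnk\*,
Tx\*), peaks below 5 kb are dropped (1.5 kb floor for active-TSS peaks), and
at most the 100,000 largest entries are retained; the operation is
idempotent. Polycomb domains merge fine-grained repressed-state calls
across gaps ≤ 10 kb and keep regions ≥ 100 kb.

**Track correlations.** Published filtering omits negative values,
blacklisted bins and "bins with low variability (μ ± 2σ)". Taken literally
the last rule excludes ~95% of bins; we default to dropping bins whose
cross-track variance falls below the 5th percentile (removing uninformative
bins while keeping the estimate usable) and expose the literal rule behind
`low_variability="literal"`.

**Expression strata.** Genes are split low/mid/high at the 33.4 and 66.7
TPM percentiles; boundary ties go to the lower stratum in stable input
order, so the strata always partition the gene set.

## Single-cell analyses

QC keeps cells with ≥ 800 total UMIs and ≥ 64 UMIs for every epitope
(bone-marrow-style runs use a 256-UMI cell total instead; thresholds are
arguments). Pseudobulk "in silico population" (ISP) tracks sum member cells
per group at 20-kb resolution, optionally depth-normalized to a common
total.

**Pan-epitope integration.** Per epitope, cell profiles on 100-kb bins are
binarized (count > 0) and pairwise Jaccard distances computed
(`D = 1 − |∩|/|∪|`; two empty profiles are defined maximally dissimilar,
D = 1, with the diagonal pinned to 0 — such cells should not survive QC).
Each epitope's matrix is min–max rescaled to [0, 1] using off-diagonal
entries only (the zero diagonal would otherwise pin the minimum), the
matrices are summed, rows are Z-scored, and PCA is run on the
rows-as-features matrix (the alternative double-centered variant was
considered; rows-as-features matches the "PCA as above" treatment of other
inputs in the source protocol). Defaults: 30 components (18 for ISP-level
embeddings, 4 before diffusion maps, matching the published component
counts). 2-D UMAP embedding of the component scores is delegated to
`umap-learn` and kept out of the test path.

**Information gain** of a clustering against true labels is
`H(labels) − Σ_c (n_c/n)·H(labels | c)` with entropy in bits and
`0·log 0 ≡ 0`. It is non-negative, bounded by `H(labels)`, and refining a
clustering can only increase it — all asserted numerically.

**XCI calls.** Per cell, the inactive X (Xi) is the parental allele with
the higher X-linked count of the XCI marker (H3K27me3, which accumulates on
the Xi), called when the |log2 ratio| exceeds 1 with ≥ 10 marker counts
(both configurable; the published analysis states no cutoff). Ratios are
log2(counts Xi / counts Xa); zero counts are floored at 1 so ratios stay
finite without shifting cells that have counts on both alleles. Other
epitopes' ratios are reported relative to the called Xi.

**Marker genes.** Promoter windows span TSS − 2 kb to TSS + 500 bp,
strand-aware. Promoter counts are CPM-normalized per cell type and scored
as log2(CPM this type / mean CPM of the others), CPM values floored at 1.
Unbiased markers use a two-sided Wilcoxon rank-sum test per gene and cell
type versus all other cells on gene-level activity (gene body + 2 kb
upstream), skipping genes detected in < 1% of cells in both groups and
retaining p < 0.001; groups with fewer than 3 cells are skipped.

## Synthetic data

The generator defines the conditions under which everything is tested.

- **Bulk genome:** two chromosomes (300 kb + 200 kb) of uniform random
  sequence with `TTAA`/`GATC` motifs planted at a mean spacing of 300 bp on
  top of the incidental 4⁻⁴ background; the motif index is derived by
  scanning the emitted sequence, so planted and incidental occurrences are
  treated identically.
- **Domains and accessibility:** per epitope, 8 exponential-length domains
  (mean 20 kb) with 8-fold enrichment; accessibility is a smoothed lognormal
  (σ = 0.6) profile at 5-kb resolution. Reads sample restriction sites with
  probability ∝ accessibility × enrichment; the control antibody samples
  accessibility alone, emulating the mock-IP background.
- **Errors:** substitutions at 0.002/base and read-start indels at 0.01/read
  put ~94–95% of reads in class 1, matching the published average for the
  defect-free class.
- **Single cells:** per-cell per-epitope totals are negative-binomial
  (mean 300, size 2), targeting the published median range of 119–706
  counts per epitope per cell. Cell simulations use a larger genome
  (25 + 15 Mb) so that occupancy at the 100-kb integration resolution stays
  sparse — with a few hundred UMIs over 400 bins, binary Jaccard profiles
  carry information, as they do in real data where counts scatter over tens
  of thousands of bins. Each cell type gets its own 20-domain layout per
  epitope (mean 150 kb).
- **XCI:** cells draw 20–80 X-linked marker counts; XCI cells put an
  `xci_skew = 0.8` share (4:1) on the Xi allele, non-XCI cells are binomial
  1:1.
- **Species mixtures** are modeled at the alignment-score level (a read
  scores higher on its own genome except for a 0.2% divergence-artifact
  rate), since the aligner itself is out of scope.

What the generator does **not** emulate: base-quality structure (qualities
are constant), PCR chimeras, mappability variation (masks are consumed as
given, never derived), fragment-length effects, and real genomic sequence
composition. Passing tests therefore demonstrate correctness of the
*computations* under controlled truth, not recovery of any published
biological dataset — the published headline figures depend on deposited
sequencing data and external references and are out of reach at these
scales.

## Problem sizes

Tests and the acceptance script run at desk scale by design: 10,000 reads
for the demultiplexer/oracle cross-check, ~200,000 reads for end-to-end
conservation, 5,000 bins for HMM recovery, 100 replicates × 200 permutations
for SEiP null calibration, 2 × 200 cells × 6 epitopes for integration, and
1,000 cells for XCI detection. All randomness flows from explicit seeds;
the simulator is byte-for-byte reproducible under a fixed seed.

## Known limitations

- The pipeline's `count` stage consumes the simulator's pre-aligned truth
  tables or external SAM/BAM; it never invokes an aligner.
- Internal indel detection (class 4) is limited to the second UMI, see
  above.
- `randomize_regions` re-places intervals on their own chromosome; a
  cross-chromosome null is not offered.
- The diffusion-map eigen-solver and UMAP/Leiden internals are delegated to
  external implementations; only their documented pre-processing is owned
  here.
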