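# mabid

Processing and analysis toolkit for **antibody-barcode genomic profiling**
(MAbID-style assays), in which antibodies are conjugated to barcoded DNA
adapters that are ligated into restriction-digested chromatin. One sequencing
library then carries the genomic positions of many epitopes — histone
modifications and chromatin proteins across active, facultative- and
constitutive-heterochromatin states — distinguishable by their antibody
barcodes, down to single cells. The package is aimed at computational
epigenomics groups running or reanalyzing such multiplexed restriction–ligation
experiments.

It covers the full chain from raw reads to integrated single-cell analyses:

1. **Demultiplexing** (`mabid.barcodes`) — raw reads follow the layout
   `5'-[3-nt UMI][4-nt SBC₁][3-nt UMI][4-nt SBC₂]AGGGCCGC[8-nt ABBC][genomic]-3'`.
   Reads are matched against the anchored adapter with up to 2 errors (UMI
   positions are wildcards; a single 1-nt indel at the read start is
   tolerated), classified on a seven-tier structure ladder, and written per
   (sample, antibody) with the UMI carried in the read identifier.
2. **Site counting** (`mabid.sites`) — alignments are kept only when the
   read's 5′ end sits exactly at the expected ligation offset of a
   restriction motif (MboI `GATC`: motif start; MseI `TTAA`: start + 1;
   mirrored on the minus strand), MAPQ ≥ 10. UMIs are flattened per site
   (cap 1,000 bulk / 2 single-cell); species and parental allele are assigned
   from composite-reference alignments.
3. **Normalization and segmentation** (`mabid.tracks`) — the no-antibody
   control mirrors chromatin accessibility, so tracks are normalized as

   ```
   RPKM_bin  = (UMI_bin / (total/10⁶)) / (bin_size/1000)
   logcounts = log₂((1 + RPKM_sample) / (1 + RPKM_control))
   ```

   and segmented with a Gaussian-emission HMM (EM from μ = [0, 1] on raw or
   μ = [−1, 0, 1] on normalized tracks; Viterbi decoding per chromosome).
4. **Enrichment metrics** (`mabid.enrichment`) — FRiP on raw counts; for
   normalized signal the **SEiP** statistic
   `SEiP_scaled = (SEiP_observed − μ_permuted) / σ_permuted`, with the null
   from uniform re-placement of the regions (1,500 permutations by default);
   ChromHMM-style reference-region construction; meta-profiles; filtered
   track correlations; expression-percentile gene strata.
5. **Single cells** (`mabid.singlecell`) — QC (≥ 800 UMIs/cell,
   ≥ 64 UMIs/epitope), pseudobulk "in silico populations", pan-epitope
   integration (per-epitope binary Jaccard distances on 100-kb bins,
   rescaled, summed, PCA), information gain of cluster assignments,
   allele-resolved X-inactivation calls, and promoter/rank-sum marker genes.
6. **Simulation** (`mabid.simulate`) — generates every input with recorded
   ground truth: genomes with planted motifs, epitope domains, accessibility
   backgrounds, barcoded reads with injected errors, and multi-plate cell
   populations. All tests and the acceptance script run on these.

## Worked example

End-to-end on simulated data (one sample, H3K27me3 + control, 40,000 reads):

```python
import numpy as np
from mabid import SimConfig, default_scheme, MotifIndex
from mabid.simulate import (simulate_genome, simulate_domains,
                            simulate_accessibility, simulate_reads,
                            truth_to_alignments, write_fastq)
from mabid.barcodes import demultiplex_fastq
from mabid.sites import count_sites, bin_counts
from mabid.tracks import logcounts, hmm_segment, HmmSpec
from mabid.enrichment import frip, seip_scaled

cfg = SimConfig(seed=1)
scheme = default_scheme(n_samples=1,
                        epitopes=[("H3K27me3", "TTAA"), ("control", "TTAA")])
genome = simulate_genome(cfg)
rng = np.random.default_rng(2)
index = MotifIndex.from_genome(genome)
domains = simulate_domains(cfg, ["H3K27me3"], rng)
accessibility = simulate_accessibility(cfg, rng)

records, truth = simulate_reads(cfg, scheme, genome, index, domains,
                                accessibility, 40_000, rng=rng)
write_fastq(records, "reads.fastq")
stats = demultiplex_fastq("reads.fastq", scheme, "demux/")
print(f"{stats.total_reads} reads, "
      f"{100 * stats.fraction_correct_structure:.1f}% with correct structure, "
      f"{100 * stats.per_class_counts[1] / stats.total_reads:.1f}% in class 1")

table, rejects = count_sites(truth_to_alignments(truth, scheme, cfg.read_length),
                             index, "TTAA")
print(f"{table.total()} unique UMIs at {len(table.df)} TTAA sites "
      f"({rejects['off_site']} reads off-site)")

tracks = bin_counts(table, genome.chrom_sizes, 5_000)
norm = logcounts(tracks[("sample1", "H3K27me3")], tracks[("sample1", "control")])
seg = hmm_segment(norm, HmmSpec.normalized(), seed=1)
print(f"HMM found {len(seg.domains)} enriched domains "
      f"(fitted state means {np.round(seg.fitted_means, 2)})")

res = seip_scaled(norm, domains["H3K27me3"], genome.chrom_sizes,
                  n_perm=200, seed=1)
print(f"FRiP = {frip(tracks[('sample1', 'H3K27me3')], domains['H3K27me3']):.3f}, "
      f"SEiP_scaled = {res.scaled:.1f}")
```

prints

```
40000 reads, 100.0% with correct structure, 94.4% in class 1
39955 unique UMIs at 6815 TTAA sites (0 reads off-site)
HMM found 3 enriched domains (fitted state means [-1.35 -0.05  1.62])
FRiP = 0.716, SEiP_scaled = 2.8
```

Reading the numbers: at the simulator's default error rates ~94% of reads
are defect-free (class 1) and all carry a resolvable barcode structure;
UMI flattening removes the handful of per-site duplicates; every read sits
at its expected ligation offset. The fitted three-state means bracket the
depleted/background/enriched levels of the normalized track, 72% of the
antibody counts fall inside the planted domains, and the mean normalized
signal over those domains sits ~2.8 null standard deviations above the
region-randomization background.

The same chain is available from the shell:

```bash
mabid run --out out/ --seed 3          # full simulated stage chain + manifest
mabid demux --fastq in.fastq --scheme scheme.yaml --keep-classes 1,2 --out demux/
mabid count --sam aln.sam --motifs motifs.tsv --chemistry TTAA --binsize 5000 --out counts
mabid normalize --sample s.tsv --control c.tsv --out norm
mabid segment --track norm.tsv --states 3 --out domains.bed
mabid seip --track norm.tsv --regions peaks.bed --n-perm 1500 --seed 7
mabid sc-qc / sc-integrate / sc-xci / sc-markers ...
```

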