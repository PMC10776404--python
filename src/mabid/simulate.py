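"""Synthetic data generation for the whole pipeline.

Everything downstream is exercised on simulated inputs with recorded ground
truth: toy genomes with planted restriction motifs, per-epitope enrichment
domains, an accessibility background (mirrored by the no-antibody control,
as in the real assay), raw barcoded reads with injected errors, pre-aligned
site tables (so counting is testable without an external aligner), and
multi-plate single-cell populations with species, allele and X-inactivation
structure.

Defaults are chosen to resemble the real assay at desk scale: per-cell
per-epitope UMI totals are negative-binomial with means in the few-hundred
range (published medians per epitope fall between 119 and 706), domain
enrichment is several-fold over the accessibility background, and adapter
error rates put ~95% of reads in the defect-free class.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import Genome, MotifIndex
from .regions import RegionSet
from .scheme import BarcodeScheme
from .sites import AlignmentRecord, expected_five_prime
from .singlecell import CellEpitopeMatrix
from .tracks import BinnedTrack

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Study conditions for all simulations; the seed fixes every draw."""

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 300_000, "chr2": 200_000}
    )
    motif_spacing: dict[str, int] = field(
        default_factory=lambda: {"TTAA": 300, "GATC": 300}
    )  # mean bp between planted motifs
    n_domains_per_epitope: int = 8
    domain_mean_len: int = 20_000
    enrichment_fold: float = 8.0
    accessibility_bin: int = 5_000
    read_length: int = 75
    substitution_rate: float = 0.002  # per base
    start_indel_rate: float = 0.01  # per read
    cells_per_type: int = 200
    mean_umis_per_cell_epitope: float = 300.0
    nb_dispersion: float = 2.0  # negative-binomial size parameter
    # single-cell simulations use a larger genome so that occupancy at the
    # 100-kb integration resolution stays sparse, as in real data where a few
    # hundred UMIs scatter over tens of thousands of bins
    cell_chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 25_000_000, "chr2": 15_000_000}
    )
    cell_n_domains: int = 20
    cell_domain_mean_len: int = 150_000
    xci_fraction: float = 0.5
    xci_skew: float = 0.8  # Xi share of X-linked XCI-marker counts (4:1)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# genome, domains, accessibility


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> Genome:
    """Random genome with motifs planted at the configured mean spacing."""
    rng = np.random.default_rng(config.seed if rng is None else rng)
    seqs = {}
    for chrom, size in config.chrom_sizes.items():
        if size < 10_000:
            raise ValueError("chromosomes must be at least 10 kb")
        arr = rng.choice(4, size=size)
        seq = list(_BASES[arr])
        for motif, spacing in config.motif_spacing.items():
            if spacing <= 0:
                continue
            if spacing < len(motif) * 2:
                raise ValueError(f"motif spacing too dense for {motif}")
            pos = 0
            while True:
                pos += int(rng.exponential(spacing)) + len(motif)
                if pos + len(motif) > size:
                    break
                seq[pos : pos + len(motif)] = list(motif)
        seqs[chrom] = "".join(seq)
    return Genome({c: len(s) for c, s in seqs.items()}, seqs)


def simulate_domains(
    config: SimConfig,
    epitopes: list[str],
    rng: np.random.Generator,
) -> dict[str, RegionSet]:
    """Random enrichment-domain layouts per epitope."""
    out = {}
    for epi in epitopes:
        rows = []
        for _ in range(config.n_domains_per_epitope):
            chrom = str(rng.choice(list(config.chrom_sizes)))
            size = config.chrom_sizes[chrom]
            length = max(5_000, int(rng.exponential(config.domain_mean_len)))
            length = min(length, size // 2)
            start = int(rng.integers(0, size - length))
            rows.append((chrom, start, start + length, epi))
        out[epi] = RegionSet.from_records(rows, name=epi).merge(by_label=True)
    return out


def simulate_accessibility(config: SimConfig, rng: np.random.Generator) -> BinnedTrack:
    """Smooth positive accessibility background at the accessibility bin size."""
    values = {}
    for chrom, size in config.chrom_sizes.items():
        n = -(-size // config.accessibility_bin)
        raw = rng.lognormal(mean=0.0, sigma=0.6, size=n + 8)
        kernel = np.ones(9) / 9.0
        values[chrom] = np.convolve(raw, kernel, mode="same")[:n] + 0.05
    return BinnedTrack(config.accessibility_bin, values)


# ---------------------------------------------------------------------------
# raw reads


def _site_weights(
    motif_index: MotifIndex,
    motif: str,
    accessibility: BinnedTrack,
    domains: RegionSet | None,
    fold: float,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (site positions, sampling weights)."""
    out = {}
    for chrom in accessibility.values:
        sites = motif_index.sites(chrom, motif)
        if len(sites) == 0:
            continue
        acc = accessibility.values[chrom][sites // accessibility.bin_size]
        w = acc.copy()
        if domains is not None and fold != 1.0:
            sub = domains.df[domains.df["chrom"] == chrom]
            inside = np.zeros(len(sites), dtype=bool)
            for s, e in zip(sub["start"], sub["end"]):
                inside |= (sites >= s) & (sites < e)
            w[inside] *= fold
        out[chrom] = (sites, w)
    return out


def simulate_reads(
    config: SimConfig,
    scheme: BarcodeScheme,
    genome: Genome,
    motif_index: MotifIndex,
    domains: dict[str, RegionSet],
    accessibility: BinnedTrack,
    n_reads: int,
    control_epitope: str = "control",
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate raw barcoded reads plus a record-for-record truth table.

    Reads are drawn from restriction sites with probability proportional to
    accessibility times the epitope's domain enrichment; the control epitope
    (no primary antibody) samples accessibility alone.  Substitutions are
    injected per base and 1-nt insertions/deletions at the read start per
    read.  Returns FASTQ records ``(read_id, seq, qual)`` and the truth
    table, aligned record-for-record.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    pairs = [
        (sbc, entry)
        for sbc in scheme.sbc_whitelist
        for entry in scheme.abbc_whitelist
    ]
    weights_cache = {}
    for _, entry in pairs:
        motifs = ("TTAA", "GATC") if entry.chemistry == "both" else (entry.chemistry,)
        for motif in motifs:
            key = (entry.epitope, motif)
            if key not in weights_cache:
                dom = None if entry.epitope == control_epitope else domains.get(entry.epitope)
                sw = _site_weights(
                    motif_index, motif, accessibility, dom, config.enrichment_fold
                )
                # precompute cumulative weights for fast inverse-CDF sampling
                chroms = list(sw)
                chrom_cum = np.cumsum([sw[c][1].sum() for c in chroms])
                chrom_cum /= chrom_cum[-1]
                site_cum = {}
                for c in chroms:
                    cum = np.cumsum(sw[c][1])
                    site_cum[c] = cum / cum[-1]
                weights_cache[key] = (sw, chroms, chrom_cum, site_cum)

    records = []
    truth_rows = []
    per_pair = np.full(len(pairs), n_reads // len(pairs))
    per_pair[: n_reads % len(pairs)] += 1
    idx = 0
    for (sbc, entry), n_pair in zip(pairs, per_pair):
        motifs = ("TTAA", "GATC") if entry.chemistry == "both" else (entry.chemistry,)
        for _ in range(n_pair):
            motif = motifs[int(rng.integers(len(motifs)))] if len(motifs) > 1 else motifs[0]
            sw, chroms, chrom_cum, site_cum = weights_cache[(entry.epitope, motif)]
            chrom = chroms[int(np.searchsorted(chrom_cum, rng.random()))]
            sites, _ = sw[chrom]
            site = int(sites[int(np.searchsorted(site_cum[chrom], rng.random()))])
            strand = "+" if rng.random() < 0.5 else "-"
            glen = config.read_length - scheme.adapter_len
            fp = expected_five_prime(site, motif, strand)
            if strand == "+":
                gseq = genome.sequences[chrom][fp : fp + glen]
            else:
                gseq = _revcomp(genome.sequences[chrom][max(0, fp - glen + 1) : fp + 1])
            umi = "".join(_BASES[rng.integers(0, 4, size=scheme.umi_len)])
            seq = (
                umi[: scheme.umi1_len]
                + sbc[: scheme.sbc1_len]
                + umi[scheme.umi1_len :]
                + sbc[scheme.sbc1_len :]
                + scheme.constant
                + entry.barcode
                + gseq
            )
            # error injection
            indel = ""
            if rng.random() < config.start_indel_rate:
                if rng.random() < 0.5:
                    seq = str(rng.choice(list("ACGT"))) + seq[:-1]
                    indel = "insertion"
                else:
                    seq = seq[1:]
                    indel = "deletion"
            arr = np.frombuffer(seq.encode(), dtype="S1").copy()
            hit = np.flatnonzero(rng.random(len(arr)) < config.substitution_rate)
            n_sub_adapter = 0
            sl = scheme.segment_slices()
            umi_pos = set(range(*sl["umi1"].indices(len(seq)))) | set(
                range(*sl["umi2"].indices(len(seq)))
            )
            for p in hit:
                old = arr[p : p + 1].tobytes().decode()
                new = str(rng.choice([b for b in "ACGT" if b != old]))
                arr[p] = new.encode()
                if indel == "" and p < scheme.adapter_len and p not in umi_pos:
                    n_sub_adapter += 1
            seq = arr.tobytes().decode()
            read_id = f"sim:{idx}"
            records.append((read_id, seq, "I" * len(seq)))
            truth_rows.append(
                (read_id, scheme.sample_of(sbc), entry.epitope, sbc, entry.barcode,
                 umi, chrom, site, motif, strand, n_sub_adapter, len(hit), indel)
            )
            idx += 1
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "sample", "epitope", "sbc", "abbc", "umi", "chrom",
                 "site", "motif", "strand", "n_sub_adapter", "n_sub_total", "start_indel"],
    )
    return records, truth


def write_fastq(records, path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def truth_to_alignments(
    truth: pd.DataFrame,
    scheme: BarcodeScheme,
    read_length: int,
    mapq: int = 42,
) -> list[AlignmentRecord]:
    """Emit the alignments a perfect aligner would produce for truth reads.

    This bypasses the external aligner so site counting can be tested
    directly against the simulator's ground truth.
    """
    glen = read_length - scheme.adapter_len
    out = []
    for row in truth.itertuples(index=False):
        fp = expected_five_prime(row.site, row.motif, row.strand)
        if row.strand == "+":
            pos, end = fp, fp + glen
        else:
            pos, end = max(0, fp - glen + 1), fp + 1
        out.append(
            AlignmentRecord(
                read_id=row.read_id,
                chrom=row.chrom,
                pos=pos,
                end=end,
                strand=row.strand,
                mapq=mapq,
                sample=row.sample,
                epitope=row.epitope,
                umi=row.umi,
            )
        )
    return out


def write_sam(alignments: list[AlignmentRecord], chrom_sizes: dict[str, int], path) -> None:
    """Minimal coordinate-sorted SAM with UMI-suffixed read names."""
    recs = sorted(alignments, key=lambda a: (a.chrom, a.pos))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, size in chrom_sizes.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{size}\n")
        for a in recs:
            flag = 16 if a.strand == "-" else 0
            length = a.end - a.pos
            name = f"{a.read_id}:UMI:{a.umi}" if a.umi else a.read_id
            fh.write(
                f"{name}\t{flag}\t{a.chrom}\t{a.pos + 1}\t{a.mapq}\t{length}M\t*\t0\t0"
                f"\t{'N' * length}\t*\n"
            )


# ---------------------------------------------------------------------------
# single cells


def _negbin(rng: np.random.Generator, mean: float, size_param: float, n: int) -> np.ndarray:
    lam = rng.gamma(shape=size_param, scale=mean / size_param, size=n)
    return rng.poisson(lam)


def simulate_cells(
    config: SimConfig,
    epitopes: list[str] | None = None,
    cell_types: tuple[str, ...] = ("typeA", "typeB"),
    cell_bin_size: int = 20_000,
    n_plates: int = 2,
    rng: np.random.Generator | None = None,
) -> tuple[CellEpitopeMatrix, dict[str, RegionSet]]:
    """Simulate a multi-plate single-cell population with known structure.

    Each cell type gets its own enrichment-domain layout per epitope; cells
    draw a negative-binomial total per epitope and scatter counts over bins
    proportionally to accessibility times their type's domain profile.
    Ground-truth cell types live in ``obs['cell_type']``; the per-type
    domain layouts are returned for profile-recovery checks.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    if epitopes is None:
        epitopes = [f"epi{i + 1}" for i in range(6)]
    chrom_sizes = config.cell_chrom_sizes
    bins = []
    offsets = {}
    for chrom, size in chrom_sizes.items():
        offsets[chrom] = len(bins)
        for start in range(0, size, cell_bin_size):
            bins.append((chrom, start))
    bins = pd.DataFrame(bins, columns=["chrom", "start"])
    n_bins = len(bins)
    # smooth accessibility background at the cell bin size
    acc = np.empty(n_bins)
    for chrom, size in chrom_sizes.items():
        n = -(-size // cell_bin_size)
        raw = rng.lognormal(0.0, 0.6, n + 8)
        acc[offsets[chrom] : offsets[chrom] + n] = (
            np.convolve(raw, np.ones(9) / 9.0, mode="same")[:n] + 0.05
        )

    def draw_domains(epi: str) -> RegionSet:
        rows = []
        chroms = list(chrom_sizes)
        for _ in range(config.cell_n_domains):
            chrom = chroms[int(rng.integers(len(chroms)))]
            size = chrom_sizes[chrom]
            length = max(cell_bin_size, int(rng.exponential(config.cell_domain_mean_len)))
            length = min(length, size // 4)
            start = int(rng.integers(0, size - length))
            rows.append((chrom, start, start + length, epi))
        return RegionSet.from_records(rows, name=epi).merge(by_label=True)

    type_domains: dict[str, RegionSet] = {}
    profiles: dict[tuple[str, str], np.ndarray] = {}
    for ct in cell_types:
        for epi in epitopes:
            dom = draw_domains(epi)
            type_domains[f"{ct}:{epi}"] = dom
            w = acc.copy()
            for chrom, idx in dom.bin_indices(cell_bin_size).items():
                n = -(-chrom_sizes[chrom] // cell_bin_size)
                idx = idx[idx < n]
                w[offsets[chrom] + idx] *= config.enrichment_fold
            profiles[(ct, epi)] = w / w.sum()

    n_cells = config.cells_per_type * len(cell_types)
    obs = pd.DataFrame(
        {
            "cell_type": np.repeat(list(cell_types), config.cells_per_type),
            "plate": [f"plate{i % n_plates + 1}" for i in range(n_cells)],
        },
        index=[f"cell{i:04d}" for i in range(n_cells)],
    )
    counts = {}
    for epi in epitopes:
        mat = np.zeros((n_bins, n_cells), dtype=np.int64)
        totals = _negbin(rng, config.mean_umis_per_cell_epitope, config.nb_dispersion, n_cells)
        for ci in range(n_cells):
            p = profiles[(obs["cell_type"].iloc[ci], epi)]
            if totals[ci] > 0:
                mat[:, ci] = rng.multinomial(totals[ci], p)
        counts[epi] = sp.csr_matrix(mat)
    return CellEpitopeMatrix(counts, bins, obs, cell_bin_size), type_domains


def simulate_xci_counts(
    config: SimConfig,
    n_cells: int = 1000,
    count_low: int = 20,
    count_high: int = 80,
    xci_epitope: str = "H3K27me3",
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Allele-resolved X-linked counts for XCI and non-XCI cells.

    XCI cells put a ``xci_skew`` share of their XCI-marker counts on the
    inactive allele (default 4:1); non-XCI cells are binomial 1:1.  Returns
    the allele-count table and the ground-truth XCI status per cell.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    is_xci = rng.random(n_cells) < config.xci_fraction
    xi_is_allele1 = rng.random(n_cells) < 0.5
    rows = []
    for i in range(n_cells):
        total = int(rng.integers(count_low, count_high + 1))
        p = config.xci_skew if is_xci[i] else 0.5
        xi_counts = rng.binomial(total, p)
        a1, a2 = (
            (xi_counts, total - xi_counts)
            if xi_is_allele1[i]
            else (total - xi_counts, xi_counts)
        )
        rows.append((f"cell{i:04d}", xci_epitope, a1, a2))
    table = pd.DataFrame(rows, columns=["cell", "epitope", "allele1", "allele2"])
    status = pd.Series(is_xci, index=[f"cell{i:04d}" for i in range(n_cells)], name="is_xci")
    return table, status


def simulate_species_mixture(
    config: SimConfig,
    n_reads: int = 2000,
    misalign_rate: float = 0.002,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Alignment scores of reads from a two-species mixture.

    Reads align best to their own genome; a small ``misalign_rate`` fraction
    score better on the wrong genome (divergence artifacts).  Returns the
    per-read alignment table (read_id, species, score) and the truth.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    truth = np.where(rng.random(n_reads) < 0.5, "human", "mouse")
    rows = []
    for i, sp_true in enumerate(truth):
        own = int(rng.integers(60, 100))
        cross_hit = rng.random() < 0.10  # read also maps somewhere in the other genome
        flip = rng.random() < misalign_rate
        other = "mouse" if sp_true == "human" else "human"
        if flip:
            rows.append((f"r{i}", other, own + 5))
            rows.append((f"r{i}", sp_true, own))
        else:
            rows.append((f"r{i}", sp_true, own))
            if cross_hit:
                rows.append((f"r{i}", other, own - int(rng.integers(5, 30))))
    table = pd.DataFrame(rows, columns=["read_id", "species", "score"])
    return table, pd.Series(truth, index=[f"r{i}" for i in range(n_reads)], name="species")
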