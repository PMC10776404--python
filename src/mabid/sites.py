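"""From alignments to unique-UMI counts at expected restriction-ligation sites.

A read is only informative if its 5' end sits exactly where ligation of the
antibody adapter to a restriction cut would place it: at the motif start for
the MboI ``GATC`` motif, or one base inside for the MseI ``TTAA`` motif
(T^TAA cutting leaves the fragment starting at motif start + 1).  On the
minus strand the rule mirrors: the read's 5' end is its rightmost base and
the expected position reflects the cut on the opposite side of the
palindromic motif.  Reads elsewhere, or with mapping quality below 10, are
discarded.  UMIs are then flattened per (sample, epitope, site) with a
configurable cap: 1,000 for bulk samples, 2 for single cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .genome import MotifIndex
from .regions import RegionSet
from .tracks import BinnedTrack

#: 5'-end offset from motif start on the plus strand, per chemistry.
PLUS_OFFSETS = {"TTAA": 1, "GATC": 0}

DEFAULT_UMI_CAP = 1000
SINGLE_CELL_UMI_CAP = 2


@dataclass
class AlignmentRecord:
    read_id: str
    chrom: str
    pos: int  # 0-based leftmost reference position
    end: int  # exclusive rightmost reference position
    strand: str  # '+' or '-'
    mapq: int
    sample: str = ""
    epitope: str = ""
    umi: str = ""
    edit_distance: int = 0
    score: int = 0
    ref_tag: str = ""  # species/allele label when aligned to a composite reference

    @property
    def five_prime(self) -> int:
        return self.pos if self.strand == "+" else self.end - 1


def parse_read_name(name: str) -> tuple[str, str]:
    """Split off the ``:UMI:<seq>`` suffix the demultiplexer appends."""
    if ":UMI:" in name:
        base, umi = name.rsplit(":UMI:", 1)
        return base, umi
    return name, ""


def read_sam(path, sample: str = "", epitope: str = "") -> Iterator[AlignmentRecord]:
    """Iterate mapped records of a SAM/BAM file as :class:`AlignmentRecord`."""
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            base, umi = parse_read_name(aln.query_name)
            yield AlignmentRecord(
                read_id=base,
                chrom=aln.reference_name,
                pos=aln.reference_start,
                end=aln.reference_end,
                strand="-" if aln.is_reverse else "+",
                mapq=aln.mapping_quality,
                sample=sample,
                epitope=epitope,
                umi=umi,
                edit_distance=aln.get_tag("NM") if aln.has_tag("NM") else 0,
                score=aln.get_tag("AS") if aln.has_tag("AS") else 0,
            )


def expected_five_prime(motif_start: int, motif: str, strand: str) -> int:
    """Where a ligation-derived read's 5' end must fall for this motif."""
    off = PLUS_OFFSETS[motif]
    if strand == "+":
        return motif_start + off
    return motif_start + (len(motif) - 1) - off


def filter_and_assign_site(
    aln: AlignmentRecord,
    motif_index: MotifIndex,
    chemistry: str,
    min_mapq: int = 10,
) -> tuple[int | None, str]:
    """Return (site coordinate, motif) for a valid record, else (None, reason).

    The site coordinate is always the motif start.  ``chemistry`` is
    ``"TTAA"``, ``"GATC"`` or ``"both"``.
    """
    if aln.mapq < min_mapq:
        return None, "low_mapq"
    motifs = ("TTAA", "GATC") if chemistry == "both" else (chemistry,)
    known_chrom = False
    for motif in motifs:
        starts = motif_index.sites(aln.chrom, motif)
        if (aln.chrom, motif) in motif_index.positions:
            known_chrom = True
        if len(starts) == 0:
            continue
        off = PLUS_OFFSETS[motif]
        delta = off if aln.strand == "+" else (len(motif) - 1) - off
        cand = aln.five_prime - delta
        i = np.searchsorted(starts, cand)
        if i < len(starts) and starts[i] == cand:
            return int(cand), motif
    if not known_chrom:
        return None, "unknown reference"
    return None, "off_site"


def flatten_umis(umis: Iterable[str], cap: int = DEFAULT_UMI_CAP) -> int:
    """Unique-UMI count at one site, saturating at ``cap``."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    return min(len(set(umis)), cap)


@dataclass
class SiteCountTable:
    """Unique-UMI counts keyed by (sample, epitope, chrom, site, motif)."""

    df: pd.DataFrame  # columns: sample, epitope, chrom, pos, motif, count

    COLUMNS = ["sample", "epitope", "chrom", "pos", "motif", "count"]

    def __post_init__(self) -> None:
        self.df = self.df[self.COLUMNS].reset_index(drop=True)

    def total(self) -> int:
        return int(self.df["count"].sum())

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SiteCountTable":
        return cls(pd.read_csv(path, sep="\t"))

    def subset(self, sample: str | None = None, epitope: str | None = None) -> "SiteCountTable":
        df = self.df
        if sample is not None:
            df = df[df["sample"] == sample]
        if epitope is not None:
            df = df[df["epitope"] == epitope]
        return SiteCountTable(df.reset_index(drop=True))

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(set(zip(self.df["sample"], self.df["epitope"])))


def count_sites(
    alignments: Iterable[AlignmentRecord],
    motif_index: MotifIndex,
    chemistry: str | dict[str, str] = "TTAA",
    min_mapq: int = 10,
    umi_cap: int = DEFAULT_UMI_CAP,
) -> tuple[SiteCountTable, dict[str, int]]:
    """UMI-flatten alignments into per-site counts.

    ``chemistry`` may be a single motif chemistry or a per-epitope mapping
    (an antibody conjugated to both adapter types uses ``"both"``).
    Returns the count table and a tally of rejection reasons.
    """
    umis: dict[tuple, set] = {}
    rejects = {"low_mapq": 0, "off_site": 0, "unknown reference": 0}
    for aln in alignments:
        chem = chemistry.get(aln.epitope, "TTAA") if isinstance(chemistry, dict) else chemistry
        site, verdict = filter_and_assign_site(aln, motif_index, chem, min_mapq)
        if site is None:
            rejects[verdict] += 1
            continue
        key = (aln.sample, aln.epitope, aln.chrom, site, verdict)
        umis.setdefault(key, set()).add(aln.umi)
    rows = [
        (s, e, c, p, m, min(len(u), umi_cap))
        for (s, e, c, p, m), u in sorted(umis.items())
    ]
    table = SiteCountTable(pd.DataFrame(rows, columns=SiteCountTable.COLUMNS))
    return table, rejects


def assign_species(
    alignments: pd.DataFrame,
    chrom_species: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assign each read to a species from alignments to a composite genome.

    ``alignments`` needs columns read_id, chrom (or species), score.  A read
    aligning to chromosomes of both species keeps the strictly better-scoring
    species; an across-species score tie is discarded (species = None).
    """
    df = alignments.copy()
    if "species" not in df.columns:
        if chrom_species is None:
            raise ValueError("need chrom_species mapping or a species column")
        df["species"] = df["chrom"].map(chrom_species)
    out = []
    for read_id, grp in df.groupby("read_id", sort=False):
        best = grp.loc[grp["score"].idxmax()]
        top = grp[grp["score"] == best["score"]]
        if top["species"].nunique() > 1:
            out.append((read_id, None))
        else:
            out.append((read_id, best["species"]))
    return pd.DataFrame(out, columns=["read_id", "species"])


def assign_allele(
    aln1: tuple[int, int] | None,
    aln2: tuple[int, int] | None,
) -> str:
    """Pick the parental genome a read maps better to.

    Each argument is ``(edit_distance, alignment_score)`` against one
    reference, or None if unaligned.  Strictly lower edit distance wins;
    ties fall back to the higher alignment score; a full tie is ambiguous.
    """
    if aln1 is None and aln2 is None:
        return "ambiguous"
    if aln2 is None:
        return "genome1"
    if aln1 is None:
        return "genome2"
    if aln1[0] != aln2[0]:
        return "genome1" if aln1[0] < aln2[0] else "genome2"
    if aln1[1] != aln2[1]:
        return "genome1" if aln1[1] > aln2[1] else "genome2"
    return "ambiguous"


def bin_counts(
    table: SiteCountTable,
    chrom_sizes: dict[str, int],
    bin_size: int,
    mask: RegionSet | None = None,
) -> dict[tuple[str, str], BinnedTrack]:
    """Bin site counts into half-open fixed-width bins per (sample, epitope).

    Bins overlapping a mask interval are zeroed and flagged.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    out = {}
    for sample, epitope in table.pairs():
        sub = table.subset(sample, epitope).df
        track = BinnedTrack.zeros(chrom_sizes, bin_size)
        for chrom, grp in sub.groupby("chrom"):
            if chrom not in track.values:
                continue
            idx = grp["pos"].to_numpy(dtype=np.int64) // bin_size
            np.add.at(track.values[chrom], idx, grp["count"].to_numpy(dtype=float))
        if mask is not None:
            track = track.apply_mask(mask, zero=True)
        out[(sample, epitope)] = track
    return out


def motif_density(genome, motif: str, bin_size: int) -> BinnedTrack:
    """Per-bin counts of (possibly overlapping) motif occurrences."""
    from .genome import scan_motif

    track = BinnedTrack.zeros(genome.chrom_sizes, bin_size)
    for chrom, seq in genome.sequences.items():
        hits = scan_motif(seq, motif)
        if len(hits):
            np.add.at(track.values[chrom], hits // bin_size, 1.0)
    return track
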