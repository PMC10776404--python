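"""Genome model: chromosome sizes, sequences, and restriction-motif indices.

The assay anchors reads at restriction-enzyme motifs (MseI ``TTAA`` or MboI
``GATC``), so downstream counting only needs the motif coordinates, not the
full sequence.  A :class:`MotifIndex` can be scanned from FASTA or loaded
from a precomputed TSV (chrom, pos, motif).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO


@dataclass
class Genome:
    """Chromosome sizes plus (optionally) their sequences."""

    chrom_sizes: dict[str, int]
    sequences: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls({c: len(s) for c, s in seqs.items()}, seqs)

    def to_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return -(-self.chrom_sizes[chrom] // bin_size)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_sizes)


def scan_motif(seq: str, motif: str) -> np.ndarray:
    """Start coordinates of all (possibly overlapping) motif occurrences."""
    if len(motif) < 2:
        raise ValueError("motif length must be >= 2")
    hits = []
    start = seq.find(motif)
    while start != -1:
        hits.append(start)
        start = seq.find(motif, start + 1)
    return np.asarray(hits, dtype=np.int64)


@dataclass
class MotifIndex:
    """Motif start coordinates per chromosome, for one or more motifs."""

    positions: dict[tuple[str, str], np.ndarray]  # (chrom, motif) -> sorted starts
    motif_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (_, motif) in self.positions:
            self.motif_lengths.setdefault(motif, len(motif))

    @classmethod
    def from_genome(cls, genome: Genome, motifs=("TTAA", "GATC")) -> "MotifIndex":
        pos = {}
        for chrom, seq in genome.sequences.items():
            for motif in motifs:
                pos[(chrom, motif)] = scan_motif(seq, motif)
        return cls(pos)

    @classmethod
    def from_tsv(cls, path) -> "MotifIndex":
        df = pd.read_csv(path, sep="\t")
        pos = {
            (chrom, motif): np.sort(grp["pos"].to_numpy(dtype=np.int64))
            for (chrom, motif), grp in df.groupby(["chrom", "motif"])
        }
        return cls(pos)

    def to_tsv(self, path) -> None:
        rows = []
        for (chrom, motif), arr in sorted(self.positions.items()):
            for p in arr:
                rows.append((chrom, int(p), motif))
        pd.DataFrame(rows, columns=["chrom", "pos", "motif"]).to_csv(path, sep="\t", index=False)

    def sites(self, chrom: str, motif: str) -> np.ndarray:
        return self.positions.get((chrom, motif), np.empty(0, dtype=np.int64))

    def chromosomes(self) -> list[str]:
        return sorted({c for c, _ in self.positions})

    def motifs(self) -> list[str]:
        return sorted({m for _, m in self.positions})
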