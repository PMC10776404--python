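"""Anchored-adapter matching, seven-tier read classification and demultiplexing.

Reads must start directly with the barcoded adapter (anchored 5' match).
Matching tolerates up to ``max_errors`` defects, where UMI positions are
wildcards and mismatches are only counted against the sample barcode, the
constant linker and the antibody barcode; a single 1-nt insertion or deletion
is additionally allowed inside either UMI (at the read start for the first
UMI), costing one error.

Classification tiers (class 0 = unmatched):

1. perfect structure, zero non-UMI errors;
2. sole defect is a 1-nt indel in the first UMI (read start);
3. full structure with 1-2 non-UMI mismatches, barcodes rescued to the
   whitelist at Hamming distance <= 1 (unambiguously);
4. full structure with a 1-nt indel in a UMI plus at most one mismatch;
5. constant linker found intact but offset by +/-1 from its expected position;
6. constant linker at its expected position with exactly one mismatch;
7. only the intact constant linker at its expected position.

The production pipeline keeps classes {1, 2}; the remaining tiers exist for
QC reporting and are configurable.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .scheme import BarcodeScheme

#: (shift_start, shift_umi2) decompositions tried, in tie-break order:
#: no indel first, then read-start (first UMI) indels, then second-UMI indels;
#: deletions before insertions for determinism.
_DECOMPOSITIONS = ((0, 0), (-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass
class AdapterMatch:
    """Best decomposition of a read prefix into adapter segments."""

    errors: int
    mismatches: int
    shift_start: int
    shift_umi2: int
    umi: str
    sbc: str
    abbc: str
    adapter_end: int
    overlap: int

    @property
    def has_indel(self) -> bool:
        return self.shift_start != 0 or self.shift_umi2 != 0


@dataclass
class ParsedRead:
    read_id: str
    umi: str = ""
    sbc: str = ""
    abbc: str = ""
    genomic_seq: str = ""
    quality: str = ""
    structure_class: int = 0


@dataclass
class DemuxStats:
    total_reads: int = 0
    per_class_counts: dict[int, int] = field(default_factory=lambda: {c: 0 for c in range(8)})
    per_pair_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def fraction_correct_structure(self) -> float:
        """Fraction of reads whose full barcode structure was resolved (classes 1-4)."""
        if self.total_reads == 0:
            return 0.0
        return sum(self.per_class_counts[c] for c in (1, 2, 3, 4)) / self.total_reads

    def count(self, cls: int, sbc: str = "", abbc: str = "") -> None:
        self.total_reads += 1
        self.per_class_counts[cls] += 1
        if sbc and abbc:
            key = (sbc, abbc)
            self.per_pair_counts[key] = self.per_pair_counts.get(key, 0) + 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "total_reads": self.total_reads,
                "fraction_correct_structure": self.fraction_correct_structure,
                "per_class_counts": {str(k): v for k, v in self.per_class_counts.items()},
                "per_pair_counts": {f"{s}:{a}": n for (s, a), n in self.per_pair_counts.items()},
            },
            indent=2,
        )


def _whitelist_lookup(observed: str, whitelist: tuple[str, ...]) -> tuple[str, int] | None:
    """Best whitelist entry for an observed barcode field.

    Distances are computed over the observed prefix (the field may be
    truncated at the read end); N or any non-ACGT base counts as a mismatch.
    Returns ``(entry, distance)`` or None when the minimum is ambiguous.
    An exact hit is always unambiguous because whitelists carry no duplicates.
    """
    best: str | None = None
    best_d = len(whitelist[0]) + 1
    tied = False
    for entry in whitelist:
        # zip stops at the observed prefix: uncovered tail positions unscored
        d = sum(1 for a, b in zip(observed, entry) if a != b)
        if d < best_d:
            best, best_d, tied = entry, d, False
        elif d == best_d:
            tied = True
            if entry < best:  # keep lexicographically smallest for reporting
                best = entry
    if tied and best_d > 0:
        return None
    return best, best_d  # type: ignore[return-value]


def match_anchored_adapter(
    seq: str,
    scheme: BarcodeScheme,
    max_errors: int = 2,
    min_overlap: int = 29,
    allow_umi2_indel: bool = True,
) -> AdapterMatch | None:
    """Match the anchored barcode adapter against a read prefix.

    Returns the best-scoring decomposition (fewest errors, ties broken by
    indel position then lexicographic barcodes) or None if no decomposition
    has <= ``max_errors`` errors with >= ``min_overlap`` matched adapter
    positions.
    """
    best: AdapterMatch | None = None
    for shift_start, shift_umi2 in _DECOMPOSITIONS:
        if not allow_umi2_indel and shift_umi2 != 0:
            continue
        m = _match_one(seq, scheme, shift_start, shift_umi2, max_errors, min_overlap)
        if m is None:
            continue
        # decompositions are tried in tie-break order (no indel, then leftmost
        # indel), so only a strictly better error count replaces the incumbent
        if best is None or m.errors < best.errors:
            best = m
        if best.errors == 0:
            break
    return best


def _match_one(
    seq: str,
    scheme: BarcodeScheme,
    shift_start: int,
    shift_umi2: int,
    max_errors: int,
    min_overlap: int,
) -> AdapterMatch | None:
    slices = scheme.segment_slices(shift_start, shift_umi2)
    adapter_end = slices["abbc"].stop
    covered = min(len(seq), adapter_end)
    # overlap in adapter coordinates: with a deletion the read consumes one
    # fewer base for the same adapter span
    overlap = covered - shift_start - shift_umi2
    if overlap < min_overlap:
        return None
    const_field = seq[slices["constant"]]
    if len(const_field) < len(scheme.constant):
        return None
    n_indels = int(shift_start != 0) + int(shift_umi2 != 0)
    mm = sum(1 for a, b in zip(const_field, scheme.constant) if a != b)
    if mm + n_indels > max_errors:
        return None
    sbc_field = seq[slices["sbc1"]] + seq[slices["sbc2"]]
    if len(sbc_field) < scheme.sbc_len:
        return None
    hit = _whitelist_lookup(sbc_field, scheme.sbc_whitelist)
    if hit is None:
        return None
    sbc, d_sbc = hit
    if mm + d_sbc + n_indels > max_errors:
        return None
    abbc_field = seq[slices["abbc"]]
    abbc_whitelist = tuple(e.barcode for e in scheme.abbc_whitelist)
    hit = _whitelist_lookup(abbc_field, abbc_whitelist)
    if hit is None:
        return None
    abbc, d_abbc = hit
    errors = mm + d_sbc + d_abbc + n_indels
    if errors > max_errors:
        return None
    umi = seq[slices["umi1"]] + seq[slices["umi2"]]
    return AdapterMatch(
        errors=errors,
        mismatches=mm + d_sbc + d_abbc,
        shift_start=shift_start,
        shift_umi2=shift_umi2,
        umi=umi,
        sbc=sbc,
        abbc=abbc,
        adapter_end=adapter_end,
        overlap=overlap,
    )


def _constant_only_class(seq: str, scheme: BarcodeScheme) -> int:
    """Tiers 5-7: the constant linker is recognizable but the structure is not."""
    off = scheme.constant_offset
    const = scheme.constant
    for delta in (-1, 1):  # tier 5: intact linker shifted by one
        f = seq[off + delta : off + delta + len(const)]
        if f == const:
            return 5
    f = seq[off : off + len(const)]
    if len(f) == len(const):
        mm = sum(1 for a, b in zip(f, const) if a != b)
        if mm == 1:
            return 6
        if mm == 0:
            return 7
    return 0


def classify_read(
    read_id: str,
    seq: str,
    quality: str,
    scheme: BarcodeScheme,
    max_errors: int = 2,
    min_overlap: int = 29,
) -> ParsedRead:
    """Assign a structure class and extract barcodes/UMI from one raw read."""
    # fast path: the overwhelming majority of reads are defect-free
    sl = scheme.segment_slices()
    if (
        len(seq) >= scheme.adapter_len
        and seq[sl["constant"]] == scheme.constant
        and seq[sl["sbc1"]] + seq[sl["sbc2"]] in scheme.sbc_whitelist
        and seq[sl["abbc"]] in {e.barcode for e in scheme.abbc_whitelist}
    ):
        end = scheme.adapter_len
        return ParsedRead(
            read_id=read_id,
            umi=seq[sl["umi1"]] + seq[sl["umi2"]],
            sbc=seq[sl["sbc1"]] + seq[sl["sbc2"]],
            abbc=seq[sl["abbc"]],
            genomic_seq=seq[end:],
            quality=quality[end:],
            structure_class=1,
        )

    m = match_anchored_adapter(seq, scheme, max_errors=max_errors, min_overlap=min_overlap)
    if m is None:
        return ParsedRead(read_id=read_id, quality="", structure_class=_constant_only_class(seq, scheme))
    if m.errors == 0:
        cls = 1
    elif m.shift_start != 0 and m.mismatches == 0 and m.shift_umi2 == 0:
        cls = 2
    elif not m.has_indel:
        cls = 3
    else:
        cls = 4
    return ParsedRead(
        read_id=read_id,
        umi=m.umi,
        sbc=m.sbc,
        abbc=m.abbc,
        genomic_seq=seq[m.adapter_end :],
        quality=quality[m.adapter_end :],
        structure_class=cls,
    )


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) from a plain or gzipped FASTQ file."""
    with _open_text(path) as fh:
        yield from FastqGeneralIterator(fh)


def demultiplex_fastq(
    fastq_in,
    scheme: BarcodeScheme,
    out_dir,
    keep_classes: Iterable[int] = (1, 2),
    max_errors: int = 2,
    min_overlap: int = 29,
) -> DemuxStats:
    """Demultiplex a FASTQ file into per-(sample, epitope) trimmed FASTQ files.

    Retained reads are written with the adapter removed and the observed UMI
    appended to the read identifier as ``:UMI:<seq>``; the quality string is
    truncated to match.  All reads are tallied in the returned
    :class:`DemuxStats` regardless of retention.
    """
    keep = set(keep_classes)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handles: dict[tuple[str, str], IO[str]] = {}
    stats = DemuxStats()
    try:
        it = iter_fastq(fastq_in)
        i = 0
        while True:
            try:
                read_id, seq, qual = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record at index {i}: {exc}") from exc
            i += 1
            pr = classify_read(read_id.split()[0], seq, qual, scheme, max_errors, min_overlap)
            stats.count(pr.structure_class, pr.sbc, pr.abbc)
            if pr.structure_class not in keep or not pr.sbc:
                continue
            key = (pr.sbc, pr.abbc)
            fh = handles.get(key)
            if fh is None:
                sample = scheme.sample_of(pr.sbc)
                epitope = scheme.epitope_of(pr.abbc)
                fh = open(out_dir / f"{sample}_{epitope}.fastq", "w")
                handles[key] = fh
            fh.write(f"@{pr.read_id}:UMI:{pr.umi}\n{pr.genomic_seq}\n+\n{pr.quality}\n")
    finally:
        for fh in handles.values():
            fh.close()
    return stats


def write_stats(stats: DemuxStats, json_path, tsv_path=None) -> None:
    Path(json_path).write_text(stats.to_json())
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("sbc\tabbc\tcount\n")
            for (s, a), n in sorted(stats.per_pair_counts.items()):
                fh.write(f"{s}\t{a}\t{n}\n")
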