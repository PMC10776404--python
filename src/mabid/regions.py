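"""Named genomic interval sets (domains, peaks, masks) with BED round-trip.

Coordinates are 0-based half-open throughout, matching BED conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_COLUMNS = ["chrom", "start", "end", "label"]


@dataclass
class RegionSet:
    """A sorted collection of labeled genomic intervals."""

    df: pd.DataFrame
    name: str = ""

    def __post_init__(self) -> None:
        df = self.df
        if "label" not in df.columns:
            df = df.assign(label=self.name or ".")
        df = df[_COLUMNS].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        self.df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)

    @classmethod
    def from_records(cls, records, name: str = "") -> "RegionSet":
        """Build from an iterable of (chrom, start, end[, label]) tuples."""
        rows = []
        for rec in records:
            chrom, start, end = rec[0], rec[1], rec[2]
            label = rec[3] if len(rec) > 3 else (name or ".")
            rows.append((chrom, start, end, label))
        return cls(pd.DataFrame(rows, columns=_COLUMNS), name=name)

    @classmethod
    def from_bed(cls, path, name: str = "") -> "RegionSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = df.iloc[:, : min(4, df.shape[1])]
        df.columns = _COLUMNS[: df.shape[1]]
        return cls(df, name=name)

    def to_bed(self, path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return self.df.itertuples(index=False)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def total_span(self) -> int:
        return int(self.lengths.sum())

    def chromosomes(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def subset(self, mask_or_label) -> "RegionSet":
        if isinstance(mask_or_label, str):
            df = self.df[self.df["label"] == mask_or_label]
        else:
            df = self.df[mask_or_label]
        return RegionSet(df.reset_index(drop=True), name=self.name)

    def merge(self, gap: int = 0, by_label: bool = True) -> "RegionSet":
        """Single-linkage merge of intervals closer than or equal to ``gap`` bp.

        ``gap=0`` merges overlapping or book-ended intervals.  With
        ``by_label`` intervals only merge within the same label.
        """
        keys = ["chrom", "label"] if by_label else ["chrom"]
        out = []
        for key, grp in self.df.groupby(keys, sort=True):
            chrom = key[0]
            label = key[1] if by_label else "."
            cur_s = cur_e = None
            for s, e in zip(grp["start"], grp["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s - cur_e <= gap:
                    cur_e = max(cur_e, e)
                else:
                    out.append((chrom, cur_s, cur_e, label))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                out.append((chrom, cur_s, cur_e, label))
        return RegionSet(pd.DataFrame(out, columns=_COLUMNS), name=self.name)

    def filter_min_size(self, min_size: int) -> "RegionSet":
        return self.subset((self.lengths >= min_size))

    def bin_indices(self, bin_size: int) -> dict[str, np.ndarray]:
        """Indices of bins overlapping any interval, per chromosome.

        A bin belongs to a region if they share at least 1 bp.
        """
        out: dict[str, set] = {}
        for chrom, start, end, _ in self.df.itertuples(index=False):
            lo = int(start) // bin_size
            hi = (int(end) - 1) // bin_size
            out.setdefault(chrom, set()).update(range(lo, hi + 1))
        return {c: np.array(sorted(s), dtype=np.int64) for c, s in out.items()}

    def contains(self, chrom: str, pos: int) -> bool:
        sub = self.df[self.df["chrom"] == chrom]
        return bool(((sub["start"] <= pos) & (pos < sub["end"])).any())
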