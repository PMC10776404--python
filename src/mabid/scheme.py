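"""Barcode scheme for antibody-barcoded (MAbID-style) reads.

A raw read carries, 5' to 3':

    [UMI part 1][SBC part 1][UMI part 2][SBC part 2][constant][ABBC][genomic]

where the two sample-barcode (SBC) halves identify the well/sample, the
antibody barcode (ABBC) identifies the epitope being profiled, and the two
UMI halves form the unique molecular identifier used to collapse duplicate
ligation events at a restriction site.  The read-side ABBC field is the
antibody barcode proper plus the restriction-site remnant left by adapter
digestion, so whitelist entries are the full observed 8-mers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

DNA_ALPHABET = frozenset("ACGT")

#: Motif chemistries an antibody adapter can target.
CHEMISTRIES = ("TTAA", "GATC", "both")


@dataclass(frozen=True)
class AbbcEntry:
    """One antibody barcode: observed read-side sequence, epitope, chemistry."""

    barcode: str
    epitope: str
    chemistry: str = "TTAA"

    def __post_init__(self) -> None:
        if self.chemistry not in CHEMISTRIES:
            raise ValueError(f"chemistry must be one of {CHEMISTRIES}, got {self.chemistry!r}")
        if not self.epitope:
            raise ValueError("epitope name must be non-empty")


@dataclass(frozen=True)
class BarcodeScheme:
    """Layout and whitelists for the barcoded read prefix.

    Defaults follow the published layout: 3-nt UMI halves, 4-nt SBC halves,
    the constant ``AGGGCCGC`` linker and an 8-nt read-side ABBC field.
    """

    sbc_whitelist: tuple[str, ...]
    abbc_whitelist: tuple[AbbcEntry, ...]
    umi1_len: int = 3
    sbc1_len: int = 4
    umi2_len: int = 3
    sbc2_len: int = 4
    constant: str = "AGGGCCGC"
    abbc_len: int = 8
    sample_names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.constant:
            raise ValueError("constant segment must be non-empty")
        if set(self.constant) - DNA_ALPHABET:
            raise ValueError("constant segment must be ACGT only")
        sbc_len = self.sbc1_len + self.sbc2_len
        for bc in self.sbc_whitelist:
            if len(bc) != sbc_len or set(bc) - DNA_ALPHABET:
                raise ValueError(f"bad SBC whitelist entry {bc!r} (need {sbc_len} nt ACGT)")
        for entry in self.abbc_whitelist:
            if len(entry.barcode) != self.abbc_len or set(entry.barcode) - DNA_ALPHABET:
                raise ValueError(
                    f"bad ABBC whitelist entry {entry.barcode!r} (need {self.abbc_len} nt ACGT)"
                )
        if len(set(self.sbc_whitelist)) != len(self.sbc_whitelist):
            raise ValueError("duplicate SBC whitelist entries")
        abbc_seqs = [e.barcode for e in self.abbc_whitelist]
        if len(set(abbc_seqs)) != len(abbc_seqs):
            raise ValueError("duplicate ABBC whitelist entries")

    # -- layout arithmetic -------------------------------------------------

    @property
    def sbc_len(self) -> int:
        return self.sbc1_len + self.sbc2_len

    @property
    def constant_offset(self) -> int:
        return self.umi1_len + self.sbc1_len + self.umi2_len + self.sbc2_len

    @property
    def abbc_offset(self) -> int:
        return self.constant_offset + len(self.constant)

    @property
    def adapter_len(self) -> int:
        """Total length of the non-genomic read prefix."""
        return self.abbc_offset + self.abbc_len

    @property
    def umi_len(self) -> int:
        return self.umi1_len + self.umi2_len

    def segment_slices(self, shift_start: int = 0, shift_umi2: int = 0) -> dict[str, slice]:
        """Read-coordinate slices of each segment.

        ``shift_start`` of +1/-1 models a 1-nt insertion/deletion at the read
        start (a defect in the first UMI); ``shift_umi2`` models the same in
        the second UMI.  Shifts accumulate downstream.
        """
        out = {}
        out["umi1"] = slice(0, self.umi1_len + shift_start)
        pos = self.umi1_len + shift_start
        out["sbc1"] = slice(pos, pos + self.sbc1_len)
        pos += self.sbc1_len
        out["umi2"] = slice(pos, pos + self.umi2_len + shift_umi2)
        pos += self.umi2_len + shift_umi2
        out["sbc2"] = slice(pos, pos + self.sbc2_len)
        pos += self.sbc2_len
        out["constant"] = slice(pos, pos + len(self.constant))
        pos += len(self.constant)
        out["abbc"] = slice(pos, pos + self.abbc_len)
        out["genomic"] = slice(pos + self.abbc_len, None)
        return out

    # -- lookups -----------------------------------------------------------

    def epitope_of(self, abbc: str) -> str:
        for entry in self.abbc_whitelist:
            if entry.barcode == abbc:
                return entry.epitope
        raise KeyError(abbc)

    def chemistry_of(self, abbc: str) -> str:
        for entry in self.abbc_whitelist:
            if entry.barcode == abbc:
                return entry.chemistry
        raise KeyError(abbc)

    def sample_of(self, sbc: str) -> str:
        return dict(self.sample_names).get(sbc, sbc)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "umi1_len": self.umi1_len,
            "sbc1_len": self.sbc1_len,
            "umi2_len": self.umi2_len,
            "sbc2_len": self.sbc2_len,
            "constant": self.constant,
            "abbc_len": self.abbc_len,
            "sbc_whitelist": list(self.sbc_whitelist),
            "abbc_whitelist": [
                {"barcode": e.barcode, "epitope": e.epitope, "chemistry": e.chemistry}
                for e in self.abbc_whitelist
            ],
            "sample_names": dict(self.sample_names),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BarcodeScheme":
        return cls(
            sbc_whitelist=tuple(d["sbc_whitelist"]),
            abbc_whitelist=tuple(
                AbbcEntry(e["barcode"], e["epitope"], e.get("chemistry", "TTAA"))
                for e in d["abbc_whitelist"]
            ),
            umi1_len=int(d.get("umi1_len", 3)),
            sbc1_len=int(d.get("sbc1_len", 4)),
            umi2_len=int(d.get("umi2_len", 3)),
            sbc2_len=int(d.get("sbc2_len", 4)),
            constant=d.get("constant", "AGGGCCGC"),
            abbc_len=int(d.get("abbc_len", 8)),
            sample_names=dict(d.get("sample_names", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "BarcodeScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_scheme(
    n_samples: int = 2,
    epitopes: Iterable[tuple[str, str]] = (
        ("H3K4me1", "TTAA"),
        ("H3K27me3", "GATC"),
        ("LaminB1", "TTAA"),
    ),
) -> BarcodeScheme:
    """A small ready-made scheme, mainly for simulations and examples."""
    sbc_pool = ["TTCCAGGA", "GGAACTTC", "ACGTCAGT", "CAGTACGT", "GTACGTCA", "TCAGGTAC"]
    abbc_pool = [
        "CATGCGTA", "GTACTAGC", "TGCAAGTC", "ACCTGTTG", "GAATCCGG", "TTGGCATC",
        "CGTTAACG", "AGCCATGA",
    ]
    eps = list(epitopes)
    if n_samples > len(sbc_pool) or len(eps) > len(abbc_pool):
        raise ValueError("pool exhausted; supply explicit whitelists")
    return BarcodeScheme(
        sbc_whitelist=tuple(sbc_pool[:n_samples]),
        abbc_whitelist=tuple(
            AbbcEntry(abbc_pool[i], name, chem) for i, (name, chem) in enumerate(eps)
        ),
        sample_names={sbc_pool[i]: f"sample{i + 1}" for i in range(n_samples)},
    )
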