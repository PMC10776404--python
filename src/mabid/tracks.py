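"""Binned genomic tracks, control normalization and HMM domain segmentation.

A no-primary-antibody control sample captures the accessibility background of
the restriction-ligation assay, so antibody tracks are normalized as a log2
fold change over that control on depth-normalized (RPKM) values:

    RPKM_bin   = (UMI_bin / (total_UMI / 1e6)) / (bin_size / 1000)
    logcounts  = log2((phi + RPKM_sample) / (phi + RPKM_control)),  phi = 1

Enriched domains are then delimited by fitting a Gaussian-emission hidden
Markov model on the genome-wide track and Viterbi-decoding per chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM

from .regions import RegionSet


@dataclass
class BinnedTrack:
    """Fixed-width per-chromosome bin vectors with an optional bad-bin mask."""

    bin_size: int
    values: dict[str, np.ndarray]
    mask: dict[str, np.ndarray] = field(default_factory=dict)  # True = masked out

    def __post_init__(self) -> None:
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        for chrom, v in self.values.items():
            if chrom not in self.mask:
                self.mask[chrom] = np.zeros(len(v), dtype=bool)
            elif len(self.mask[chrom]) != len(v):
                raise ValueError(f"mask length mismatch on {chrom}")

    @classmethod
    def zeros(cls, chrom_sizes: dict[str, int], bin_size: int) -> "BinnedTrack":
        return cls(
            bin_size,
            {c: np.zeros(-(-size // bin_size)) for c, size in chrom_sizes.items()},
        )

    @property
    def chromosomes(self) -> list[str]:
        return list(self.values)

    def total(self, unmasked_only: bool = True) -> float:
        tot = 0.0
        for chrom, v in self.values.items():
            if unmasked_only:
                tot += v[~self.mask[chrom]].sum()
            else:
                tot += v.sum()
        return float(tot)

    def flat(self, unmasked_only: bool = True) -> np.ndarray:
        """Genome-wide concatenation of bin values (chromosome order preserved)."""
        parts = []
        for chrom in self.values:
            v = self.values[chrom]
            parts.append(v[~self.mask[chrom]] if unmasked_only else v)
        return np.concatenate(parts) if parts else np.empty(0)

    def same_grid(self, other: "BinnedTrack") -> bool:
        if self.bin_size != other.bin_size or set(self.values) != set(other.values):
            return False
        return all(len(self.values[c]) == len(other.values[c]) for c in self.values)

    def apply_mask(self, regions: RegionSet, zero: bool = True) -> "BinnedTrack":
        """Flag (and optionally zero) bins overlapping any masked interval."""
        new_vals = {c: v.copy() for c, v in self.values.items()}
        new_mask = {c: m.copy() for c, m in self.mask.items()}
        for chrom, idx in regions.bin_indices(self.bin_size).items():
            if chrom not in new_vals:
                continue
            idx = idx[idx < len(new_vals[chrom])]
            new_mask[chrom][idx] = True
            if zero:
                new_vals[chrom][idx] = 0.0
        return BinnedTrack(self.bin_size, new_vals, new_mask)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tvalue\tmasked\n")
            for chrom, v in self.values.items():
                m = self.mask[chrom]
                for i, x in enumerate(v):
                    fh.write(
                        f"{chrom}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}"
                        f"\t{x:.6g}\t{int(m[i])}\n"
                    )

    def to_bedgraph(self, path, clip_negative: bool = False) -> None:
        """bedGraph export; masked bins are skipped.

        ``clip_negative`` floors values at 0 for browser display (the
        convention for showing positive log2-over-control signal); the
        in-memory values are untouched.
        """
        with open(path, "w") as fh:
            for chrom, v in self.values.items():
                m = self.mask[chrom]
                for i, x in enumerate(v):
                    if m[i]:
                        continue
                    y = max(x, 0.0) if clip_negative else x
                    fh.write(f"{chrom}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}\t{y:.6g}\n")

    @classmethod
    def from_tsv(cls, path) -> "BinnedTrack":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        bin_size = int(df["end"].iloc[0] - df["start"].iloc[0])
        values, mask = {}, {}
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            values[chrom] = grp["value"].to_numpy(dtype=float)
            mask[chrom] = grp["masked"].to_numpy(dtype=bool)
        return cls(bin_size, values, mask)


@dataclass
class NormalizedTrack(BinnedTrack):
    """Log2 fold change over control; defined on unmasked bins only."""

    sample_id: str = ""
    control_id: str = ""
    pseudocount: float = 1.0


def rpkm(track: BinnedTrack) -> BinnedTrack:
    """Depth- and bin-size-normalized values (reads per kilobase per million)."""
    total = track.total()
    if total <= 0:
        raise ValueError("empty sample: zero total counts")
    scale = 1.0 / (total / 1e6) / (track.bin_size / 1000.0)
    return BinnedTrack(
        track.bin_size,
        {c: v * scale for c, v in track.values.items()},
        {c: m.copy() for c, m in track.mask.items()},
    )


def logcounts(
    sample: BinnedTrack,
    control: BinnedTrack,
    pseudocount: float = 1.0,
    already_rpkm: bool = False,
    sample_id: str = "",
    control_id: str = "",
) -> NormalizedTrack:
    """Log2 fold change of sample over control on RPKM values."""
    if not sample.same_grid(control):
        raise ValueError("sample and control tracks are on different bin grids")
    s = sample if already_rpkm else rpkm(sample)
    c = control if already_rpkm else rpkm(control)
    values = {}
    mask = {}
    for chrom in s.values:
        values[chrom] = np.log2((pseudocount + s.values[chrom]) / (pseudocount + c.values[chrom]))
        mask[chrom] = sample.mask[chrom] | control.mask[chrom]
        values[chrom][mask[chrom]] = np.nan
    return NormalizedTrack(
        s.bin_size, values, mask,
        sample_id=sample_id, control_id=control_id, pseudocount=pseudocount,
    )


@dataclass
class HmmSpec:
    """Initialization and fitting controls for the segmentation HMM.

    The stock initializations are means [0, 1] for raw tracks and
    [-1, 0, 1] for normalized tracks, with unit standard deviations
    (zero entries are floored at ``sigma_floor`` since a degenerate
    Gaussian cannot seed EM).
    """

    means: tuple[float, ...] = (-1.0, 0.0, 1.0)
    sigmas: tuple[float, ...] = (1.0, 1.0, 1.0)
    self_transition: float = 0.9
    max_iter: int = 500
    tol: float = 1e-6
    sigma_floor: float = 1e-2

    def __post_init__(self) -> None:
        if len(self.means) != len(self.sigmas):
            raise ValueError("means and sigmas must have equal length")
        if len(self.means) < 2:
            raise ValueError("need at least two states")

    @property
    def n_states(self) -> int:
        return len(self.means)

    @classmethod
    def raw(cls) -> "HmmSpec":
        return cls(means=(0.0, 1.0), sigmas=(0.0, 1.0))

    @classmethod
    def normalized(cls) -> "HmmSpec":
        return cls(means=(-1.0, 0.0, 1.0), sigmas=(1.0, 1.0, 1.0))


@dataclass
class Segmentation:
    """Per-bin Viterbi labels and the derived enriched-domain intervals."""

    states: dict[str, np.ndarray]  # -1 on masked bins
    enriched_state: int
    domains: RegionSet
    fitted_means: np.ndarray
    fitted_sigmas: np.ndarray
    log_likelihoods: np.ndarray
    converged: bool


def _fit_hmm(flat: np.ndarray, lengths: list[int], spec: HmmSpec, seed: int) -> GaussianHMM:
    k = spec.n_states
    model = GaussianHMM(
        n_components=k,
        covariance_type="diag",
        n_iter=spec.max_iter,
        tol=spec.tol,
        init_params="",
        params="stmc",
        random_state=seed,
    )
    model.startprob_ = np.full(k, 1.0 / k)
    off = (1.0 - spec.self_transition) / (k - 1)
    model.transmat_ = np.full((k, k), off) + np.eye(k) * (spec.self_transition - off)
    model.means_ = np.asarray(spec.means, dtype=float).reshape(-1, 1)
    sig = np.maximum(np.asarray(spec.sigmas, dtype=float), spec.sigma_floor)
    model.covars_ = (sig**2).reshape(-1, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(flat.reshape(-1, 1), lengths)
    # EM can empty a state on (near-)degenerate input, leaving zero-sum
    # probability rows; repair them so decoding stays well defined
    sp = np.asarray(model.startprob_, dtype=float)
    if not np.isfinite(sp).all() or sp.sum() <= 0:
        sp = np.full(k, 1.0 / k)
    model.startprob_ = sp / sp.sum()
    tm = np.asarray(model.transmat_, dtype=float)
    bad = ~np.isfinite(tm).all(axis=1) | (tm.sum(axis=1) <= 0)
    tm[bad] = 1.0 / k
    model.transmat_ = tm / tm.sum(axis=1, keepdims=True)
    return model


def hmm_segment(
    track: BinnedTrack,
    spec: HmmSpec | None = None,
    seed: int = 0,
    gap_tolerance: int = 1,
) -> Segmentation:
    """Fit a Gaussian HMM genome-wide and Viterbi-decode enriched domains.

    Masked bins are excluded from the emission sequences and break decoding
    runs; domains may bridge masked gaps of at most ``gap_tolerance`` bins.
    The enriched state is the fitted state with the highest mean.
    """
    spec = spec or HmmSpec.normalized()
    chroms = []
    seqs = []
    for chrom, v in track.values.items():
        keep = ~track.mask[chrom] & np.isfinite(v)
        if keep.sum() >= 2:
            chroms.append((chrom, keep))
            seqs.append(v[keep])
    if not seqs:
        raise ValueError("no unmasked bins to segment")
    flat = np.concatenate(seqs)
    lengths = [len(s) for s in seqs]
    model = _fit_hmm(flat, lengths, spec, seed)
    history = np.asarray(model.monitor_.history, dtype=float)
    converged = bool(model.monitor_.converged)
    if not converged:
        warnings.warn("EM did not converge within max_iter; using best-so-far parameters")

    means = model.means_.ravel()
    sigmas = np.sqrt(model.covars_.ravel())
    enriched = int(np.argmax(means))

    states: dict[str, np.ndarray] = {}
    intervals = []
    for (chrom, keep), seq in zip(chroms, seqs):
        path = model.predict(seq.reshape(-1, 1))
        full = np.full(len(keep), -1, dtype=int)
        full[keep] = path
        states[chrom] = full
        intervals.extend(_runs_to_intervals(full, enriched, chrom, track.bin_size, gap_tolerance))
    for chrom, v in track.values.items():  # chromosomes with no usable bins
        if chrom not in states:
            states[chrom] = np.full(len(v), -1, dtype=int)
    domains = (
        RegionSet.from_records(intervals, name="enriched")
        if intervals
        else RegionSet.from_records([("__none__", 0, 1)], name="enriched").subset([False])
    )
    return Segmentation(
        states=states,
        enriched_state=enriched,
        domains=domains,
        fitted_means=means,
        fitted_sigmas=sigmas,
        log_likelihoods=history,
        converged=converged,
    )


def _runs_to_intervals(full_states, enriched, chrom, bin_size, gap_tolerance):
    """Maximal runs of the enriched state, bridging short masked (-1) gaps."""
    out = []
    start = None
    gap = 0
    for i, s in enumerate(full_states):
        if s == enriched:
            if start is None:
                start = i
            gap = 0
        elif s == -1 and start is not None and gap < gap_tolerance:
            gap += 1
        else:
            if start is not None:
                end = i - gap
                out.append((chrom, start * bin_size, end * bin_size, "enriched"))
            start, gap = None, 0
    if start is not None:
        end = len(full_states) - gap
        out.append((chrom, start * bin_size, end * bin_size, "enriched"))
    return out


def export_browser_track(norm: BinnedTrack, path) -> None:
    """Write a display bedGraph with negative values clipped to zero."""
    norm.to_bedgraph(path, clip_negative=True)
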