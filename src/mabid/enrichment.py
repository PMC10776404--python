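"""Specificity metrics over reference regions: FRiP, SEiP, profiles.

FRiP (fraction of reads in peaks) works on raw counts.  Normalized
log2-over-control tracks carry negative and non-integer values, for which
SEiP (signal enrichment in peaks) is used instead: the mean signal over the
regions, Z-scaled against a null distribution obtained by re-placing the
regions uniformly at random on the unmasked genome:

    SEiP_scaled = (SEiP_observed - mu_permuted) / sigma_permuted
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import RegionSet
from .sites import SiteCountTable
from .tracks import BinnedTrack

#: ChromHMM state-name prefix groups merged into one reference label.
STATE_GROUPS = {
    "Enh": "Enh",
    "ReprPC": "ReprPC",
    "TssA": "TssA",
    "TssFlnk": "TssA",
    "Tx": "Tx",
}

MAX_REFERENCE_ENTRIES = 100_000
MIN_PEAK_SIZE = 5_000
MIN_TSS_PEAK_SIZE = 1_500


def frip(counts: BinnedTrack | SiteCountTable, regions: RegionSet) -> float:
    """Fraction of total counts falling inside the regions."""
    if isinstance(counts, SiteCountTable):
        total = counts.total()
        if total <= 0:
            raise ValueError("empty sample: zero total counts")
        if len(regions) == 0:
            return 0.0
        inside = 0
        df = counts.df
        for chrom, grp in df.groupby("chrom"):
            sub = regions.df[regions.df["chrom"] == chrom]
            if sub.empty:
                continue
            pos = grp["pos"].to_numpy()
            hit = np.zeros(len(pos), dtype=bool)
            for s, e in zip(sub["start"], sub["end"]):
                hit |= (pos >= s) & (pos < e)
            inside += int(grp["count"].to_numpy()[hit].sum())
        return inside / total
    total = counts.total()
    if total <= 0:
        raise ValueError("empty sample: zero total counts")
    if len(regions) == 0:
        return 0.0
    inside = 0.0
    for chrom, idx in regions.bin_indices(counts.bin_size).items():
        if chrom not in counts.values:
            continue
        v = counts.values[chrom]
        m = counts.mask[chrom]
        idx = idx[idx < len(v)]
        idx = idx[~m[idx]]
        inside += float(v[idx].sum())
    return inside / total


def _group_label(label: str) -> str:
    for prefix, group in STATE_GROUPS.items():
        if label.startswith(prefix):
            return group
    return label


def prepare_reference_regions(
    chromhmm: RegionSet,
    max_entries: int = MAX_REFERENCE_ENTRIES,
    min_size: int = MIN_PEAK_SIZE,
    tss_min_size: int = MIN_TSS_PEAK_SIZE,
) -> RegionSet:
    """Reference peak sets from ChromHMM-style state calls.

    Related states are merged by name-prefix groups (Enh*, ReprPC*,
    TssA/TssFlnk*, Tx*), adjacent same-group intervals are fused, small
    peaks are dropped (below ~5 kb; below 1.5 kb for active-TSS peaks) and
    at most the ``max_entries`` largest entries are retained.
    """
    df = chromhmm.df.copy()
    df["label"] = df["label"].map(_group_label)
    merged = RegionSet(df, name=chromhmm.name).merge(gap=0, by_label=True)
    lengths = merged.lengths
    labels = merged.df["label"].to_numpy()
    keep = np.where(labels == "TssA", lengths >= tss_min_size, lengths >= min_size)
    filtered = merged.subset(keep)
    if len(filtered) > max_entries:
        order = np.argsort(-filtered.lengths, kind="stable")[:max_entries]
        filtered = filtered.subset(np.isin(np.arange(len(filtered)), order))
    return filtered


def build_polycomb_domains(
    calls: RegionSet,
    gap: int = 10_000,
    min_size: int = 100_000,
) -> RegionSet:
    """Broad Polycomb domains from fine-grained repressed-state calls.

    Merges the (typically 200-bp) state calls allowing gaps up to ``gap``
    bp and keeps merged regions of at least ``min_size`` bp.
    """
    merged = calls.merge(gap=gap, by_label=False)
    out = merged.filter_min_size(min_size)
    return RegionSet(out.df.assign(label="ReprPC"), name="polycomb")


def randomize_regions(
    regions: RegionSet,
    chrom_sizes: dict[str, int],
    mask: RegionSet | None = None,
    rng: np.random.Generator | int | None = None,
) -> RegionSet:
    """Re-place every interval uniformly at random on the unmasked genome.

    Lengths and the per-chromosome interval counts are preserved; placed
    intervals avoid masked regions but may overlap each other.
    """
    rng = np.random.default_rng(rng)
    gaps: dict[str, list[tuple[int, int]]] = {}
    for chrom, size in chrom_sizes.items():
        if mask is None:
            gaps[chrom] = [(0, size)]
        else:
            sub = mask.df[mask.df["chrom"] == chrom]
            merged = []
            for s, e in zip(sub["start"], sub["end"]):
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((int(s), int(e)))
            free, prev = [], 0
            for s, e in merged:
                if s > prev:
                    free.append((prev, min(s, size)))
                prev = max(prev, e)
            if prev < size:
                free.append((prev, size))
            gaps[chrom] = free
    out = []
    for chrom, start, end, label in regions.df.itertuples(index=False):
        length = end - start
        eligible = [(g0, g1 - length + 1) for g0, g1 in gaps[chrom] if g1 - g0 >= length]
        weights = np.array([hi - lo for lo, hi in eligible], dtype=float)
        if not eligible:
            raise ValueError(f"no unmasked stretch on {chrom} fits a {length}-bp interval")
        gi = rng.choice(len(eligible), p=weights / weights.sum())
        pos = int(rng.integers(eligible[gi][0], eligible[gi][1]))
        out.append((chrom, pos, pos + length, label))
    return RegionSet(pd.DataFrame(out, columns=["chrom", "start", "end", "label"]))


@dataclass
class SeipResult:
    observed: float
    mu_perm: float
    sigma_perm: float
    scaled: float
    n_perm: int
    seed: int | None

    def to_json(self) -> str:
        return json.dumps(
            {
                "seip_observed": self.observed,
                "mu_permuted": self.mu_perm,
                "sigma_permuted": self.sigma_perm,
                "seip_scaled": self.scaled,
                "n_permutations": self.n_perm,
                "seed": self.seed,
            },
            indent=2,
        )


def _region_mean(track: BinnedTrack, regions: RegionSet) -> float:
    vals = []
    for chrom, idx in regions.bin_indices(track.bin_size).items():
        if chrom not in track.values:
            continue
        v = track.values[chrom]
        m = track.mask[chrom]
        idx = idx[idx < len(v)]
        idx = idx[~m[idx]]
        x = v[idx]
        vals.append(x[np.isfinite(x)])
    if not vals:
        return np.nan
    flat = np.concatenate(vals)
    return float(flat.mean()) if len(flat) else np.nan


def seip_scaled(
    track: BinnedTrack,
    regions: RegionSet,
    chrom_sizes: dict[str, int] | None = None,
    mask: RegionSet | None = None,
    n_perm: int = 1500,
    seed: int | None = None,
) -> SeipResult:
    """Mean-signal-in-peaks, Z-scaled against a region-randomization null."""
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if chrom_sizes is None:
        chrom_sizes = {c: len(v) * track.bin_size for c, v in track.values.items()}
    observed = _region_mean(track, regions)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _region_mean(track, randomize_regions(regions, chrom_sizes, mask, rng))
    mu = float(np.nanmean(null))
    sigma = float(np.nanstd(null, ddof=1))
    if sigma == 0 or not np.isfinite(sigma):
        raise ValueError("degenerate null: permuted SEiP scores have zero spread")
    return SeipResult(
        observed=observed,
        mu_perm=mu,
        sigma_perm=sigma,
        scaled=(observed - mu) / sigma,
        n_perm=n_perm,
        seed=seed,
    )


def metaprofile(
    track: BinnedTrack,
    regions: RegionSet,
    flank: int = 50_000,
    mode: str = "reference_point",
    anchor: str = "center",
    n_body_bins: int = 20,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signal matrix around regions plus its column-mean profile.

    ``reference_point`` mode anchors a fixed window at each region's start or
    center; ``scale_region`` mode warps region bodies to ``n_body_bins``
    columns and adds fixed flanks.  Positions outside the chromosome are NaN.
    Returns ``(matrix, mean_profile, sort_order)`` with rows ordered as in
    ``regions`` and ``sort_order`` ranking rows by decreasing mean signal.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    b = track.bin_size
    nf = flank // b
    rows = []
    for chrom, start, end, _ in regions.df.itertuples(index=False):
        v = track.values.get(chrom)
        if v is None:
            rows.append(None)
            continue
        masked = track.mask[chrom]

        def grab(lo: int, hi: int) -> np.ndarray:
            out = np.full(hi - lo, np.nan)
            a, z = max(lo, 0), min(hi, len(v))
            if z > a:
                seg = v[a:z].copy()
                seg[masked[a:z]] = np.nan
                out[a - lo : z - lo] = seg
            return out

        if mode == "reference_point":
            pos = (start + end) // 2 if anchor == "center" else start
            center_bin = pos // b
            rows.append(grab(center_bin - nf, center_bin + nf + 1))
        elif mode == "scale_region":
            body = grab(start // b, max(start // b + 1, -(-end // b)))
            warped = np.interp(
                np.linspace(0, len(body) - 1, n_body_bins), np.arange(len(body)), body
            )
            rows.append(np.concatenate([grab(start // b - nf, start // b), warped,
                                        grab(-(-end // b), -(-end // b) + nf)]))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    width = max(len(r) for r in rows if r is not None)
    mat = np.full((len(rows), width), np.nan)
    for i, r in enumerate(rows):
        if r is not None:
            mat[i, : len(r)] = r
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns/rows
        profile = np.nanmean(mat, axis=0)
        row_means = np.nanmean(mat, axis=1)
    order = np.argsort(-np.nan_to_num(row_means, nan=-np.inf), kind="stable")
    return mat, profile, order


def correlate_tracks(
    a: BinnedTrack,
    b: BinnedTrack,
    omit_negative: bool = True,
    low_variability: str | None = "percentile",
    percentile: float = 5.0,
) -> float:
    """Pearson correlation of two tracks on informative bins.

    Masked bins and (by default) bins with a negative value in either track
    are omitted.  Low-variability filtering removes uninformative bins:
    ``"percentile"`` (default) drops bins whose cross-track variance is below
    the given percentile; ``"literal"`` drops bins whose reference-track
    value lies within mean +/- 2 sd.
    """
    if not a.same_grid(b):
        raise ValueError("tracks are on different bin grids")
    xs, ys = [], []
    for chrom in a.values:
        keep = ~a.mask[chrom] & ~b.mask[chrom]
        keep &= np.isfinite(a.values[chrom]) & np.isfinite(b.values[chrom])
        xs.append(a.values[chrom][keep])
        ys.append(b.values[chrom][keep])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if omit_negative:
        keep = (x >= 0) & (y >= 0)
        x, y = x[keep], y[keep]
    if low_variability == "percentile":
        var = np.var(np.stack([x, y]), axis=0)
        thresh = np.percentile(var, percentile)
        keep = ~(var < thresh)
        x, y = x[keep], y[keep]
    elif low_variability == "literal":
        mu, sd = x.mean(), x.std()
        keep = np.abs(x - mu) > 2 * sd
        x, y = x[keep], y[keep]
    elif low_variability is not None:
        raise ValueError(f"unknown low_variability rule {low_variability!r}")
    if len(x) < 3:
        raise ValueError("fewer than 3 bins retained for correlation")
    return float(np.corrcoef(x, y)[0, 1])


def stratify_by_expression(
    tpm: pd.Series,
    percentiles: tuple[float, float] = (33.4, 66.7),
) -> dict[str, list]:
    """Split genes into low/mid/high strata on TPM percentile cuts.

    The strata partition the input; ties at a boundary go to the lower
    stratum in stable input order.
    """
    if (tpm < 0).any():
        raise ValueError("TPM values must be non-negative")
    q1, q2 = np.percentile(tpm.to_numpy(dtype=float), percentiles)
    low = tpm.index[tpm <= q1].tolist()
    mid = tpm.index[(tpm > q1) & (tpm <= q2)].tolist()
    high = tpm.index[tpm > q2].tolist()
    return {"low": low, "mid": mid, "high": high}
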