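"""Single-cell multi-epitope analyses.

Each cell carries one sparse genomic count vector per measured epitope.
This module covers QC filtering, pseudobulk ("in silico population", ISP)
aggregation, the pan-epitope integration used for clustering (per-epitope
binary Jaccard distances, rescaled and summed, then PCA), cluster evaluation
by information gain, allele-resolved X-inactivation calls, and marker-gene
scoring from promoter/gene-body activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from .regions import RegionSet
from .tracks import BinnedTrack

DEFAULT_MIN_CELL_UMI = 800
DEFAULT_MIN_EPITOPE_UMI = 64
BM_MIN_CELL_UMI = 256


@dataclass
class CellEpitopeMatrix:
    """Sparse bins x cells UMI counts per epitope, with cell metadata."""

    counts: dict[str, sp.csr_matrix]  # epitope -> (n_bins x n_cells)
    bins: pd.DataFrame  # columns: chrom, start
    obs: pd.DataFrame  # indexed by cell id; species / cell_type / plate / ...
    bin_size: int

    def __post_init__(self) -> None:
        n_bins, n_cells = len(self.bins), len(self.obs)
        for epi, m in self.counts.items():
            if m.shape != (n_bins, n_cells):
                raise ValueError(f"matrix shape mismatch for epitope {epi}")
            self.counts[epi] = sp.csr_matrix(m)

    @property
    def epitopes(self) -> list[str]:
        return list(self.counts)

    @property
    def cells(self) -> list[str]:
        return list(self.obs.index)

    def epitope_totals(self) -> pd.DataFrame:
        """Per-cell UMI totals per epitope (cells x epitopes)."""
        data = {epi: np.asarray(m.sum(axis=0)).ravel() for epi, m in self.counts.items()}
        return pd.DataFrame(data, index=self.obs.index)

    def cell_totals(self) -> pd.Series:
        return self.epitope_totals().sum(axis=1)

    def subset_cells(self, keep) -> "CellEpitopeMatrix":
        keep = np.asarray(keep)
        keep_idx = np.flatnonzero(keep) if keep.dtype == bool else self.obs.index.get_indexer(keep)
        return CellEpitopeMatrix(
            {e: m[:, keep_idx] for e, m in self.counts.items()},
            self.bins,
            self.obs.iloc[keep_idx].copy(),
            self.bin_size,
        )

    def rebin(self, target_bin_size: int) -> "CellEpitopeMatrix":
        """Aggregate counts into coarser bins (target must be a multiple)."""
        if target_bin_size % self.bin_size:
            raise ValueError("target bin size must be a multiple of the current bin size")
        key = self.bins["chrom"] + ":" + (
            self.bins["start"] // target_bin_size * target_bin_size
        ).astype(str)
        codes, uniques = pd.factorize(key, sort=True)
        agg = sp.csr_matrix(
            (np.ones(len(codes)), (codes, np.arange(len(codes)))),
            shape=(len(uniques), len(codes)),
        )
        new_bins = pd.DataFrame(
            [(u.split(":")[0], int(u.split(":")[1])) for u in uniques],
            columns=["chrom", "start"],
        )
        return CellEpitopeMatrix(
            {e: sp.csr_matrix(agg @ m) for e, m in self.counts.items()},
            new_bins,
            self.obs.copy(),
            target_bin_size,
        )

    # -- MTX-triplet exchange ---------------------------------------------

    def to_mtx_dir(self, out_dir) -> None:
        from scipy.io import mmwrite

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for epi, m in self.counts.items():
            mmwrite(out_dir / f"{epi}.mtx", sp.coo_matrix(m))
        self.bins.to_csv(out_dir / "bins.tsv", sep="\t", index=False)
        self.obs.to_csv(out_dir / "cells.tsv", sep="\t")
        (out_dir / "bin_size.txt").write_text(str(self.bin_size))

    @classmethod
    def from_mtx_dir(cls, in_dir) -> "CellEpitopeMatrix":
        from scipy.io import mmread

        in_dir = Path(in_dir)
        bins = pd.read_csv(in_dir / "bins.tsv", sep="\t")
        obs = pd.read_csv(in_dir / "cells.tsv", sep="\t", index_col=0)
        bin_size = int((in_dir / "bin_size.txt").read_text())
        counts = {
            p.stem: sp.csr_matrix(mmread(p)) for p in sorted(in_dir.glob("*.mtx"))
        }
        return cls(counts, bins, obs, bin_size)

    def to_anndata(self):
        """Cells x bins AnnData with one layer per epitope (X = sum)."""
        import anndata as ad

        total = sum(self.counts.values())
        var = self.bins.copy()
        var.index = var["chrom"] + ":" + var["start"].astype(str)
        return ad.AnnData(
            X=sp.csr_matrix(total.T),
            obs=self.obs.copy(),
            var=var,
            layers={e: sp.csr_matrix(m.T) for e, m in self.counts.items()},
        )


def qc_filter(
    matrix: CellEpitopeMatrix,
    min_cell_umi: int = DEFAULT_MIN_CELL_UMI,
    min_epitope_umi: int | None = DEFAULT_MIN_EPITOPE_UMI,
) -> tuple[CellEpitopeMatrix, pd.DataFrame]:
    """Drop cells below the total-UMI or any per-epitope UMI threshold."""
    totals = matrix.epitope_totals()
    cell_total = totals.sum(axis=1)
    pass_cell = cell_total >= min_cell_umi
    if min_epitope_umi:
        pass_epi = (totals >= min_epitope_umi).all(axis=1)
    else:
        pass_epi = pd.Series(True, index=totals.index)
    keep = pass_cell & pass_epi
    report = pd.DataFrame(
        {
            "cell_total": cell_total,
            "pass_cell_total": pass_cell,
            "pass_epitope_minimum": pass_epi,
            "retained": keep,
        }
    )
    return matrix.subset_cells(keep.to_numpy()), report


def build_isp(
    matrix: CellEpitopeMatrix,
    group_by: str | list[str] = "cell_type",
    depth_normalize_to: float | None = None,
) -> dict[tuple, dict[str, BinnedTrack]]:
    """Pseudobulk tracks by summing member cells per group and epitope.

    ``depth_normalize_to`` optionally rescales each group track to a common
    total before any log transform downstream.
    """
    cols = [group_by] if isinstance(group_by, str) else list(group_by)
    groups = matrix.obs.groupby(cols, sort=True).indices
    chroms = list(dict.fromkeys(matrix.bins["chrom"]))
    out: dict[tuple, dict[str, BinnedTrack]] = {}
    for gkey, idx in groups.items():
        gkey = gkey if isinstance(gkey, tuple) else (gkey,)
        if len(idx) == 0:
            continue
        tracks = {}
        for epi, m in matrix.counts.items():
            vec = np.asarray(m[:, idx].sum(axis=1)).ravel()
            if depth_normalize_to and vec.sum() > 0:
                vec = vec * (depth_normalize_to / vec.sum())
            values = {
                chrom: vec[(matrix.bins["chrom"] == chrom).to_numpy()] for chrom in chroms
            }
            tracks[epi] = BinnedTrack(matrix.bin_size, values)
        out[gkey] = tracks
    return out


def jaccard_distance(profiles: sp.spmatrix | np.ndarray) -> np.ndarray:
    """Pairwise Jaccard distance between binarized cell profiles.

    ``profiles`` is cells x bins; entries are binarized as count > 0.
    ``D[i, j] = 1 - |intersection| / |union|`` of the nonzero bin sets; a
    pair of empty profiles is maximally dissimilar (D = 1) by convention,
    while the diagonal is always 0.
    """
    B = sp.csr_matrix(profiles, dtype=bool).astype(np.int32)
    sizes = np.asarray(B.sum(axis=1)).ravel()
    inter = np.asarray((B @ B.T).todense(), dtype=float)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    D = 1.0 - jac
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class IntegratedDistance:
    """Summed rescaled per-epitope Jaccard distances between cells."""

    matrix: np.ndarray
    cells: list[str]
    epitopes: list[str] = field(default_factory=list)


def _rescale_offdiag(D: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1] using off-diagonal entries only."""
    off = ~np.eye(len(D), dtype=bool)
    lo, hi = D[off].min(), D[off].max()
    if hi == lo:
        out = np.zeros_like(D)
    else:
        out = (D - lo) / (hi - lo)
    np.fill_diagonal(out, 0.0)
    return out


def integrate_epitopes(
    distances: dict[str, np.ndarray],
    cells: list[str],
    n_pcs: int = 30,
    seed: int = 0,
) -> tuple[IntegratedDistance, np.ndarray]:
    """Combine per-epitope distance matrices into one embedding input.

    Each matrix is min-max rescaled to [0, 1] (off-diagonal entries), the
    rescaled matrices are summed, rows are Z-score normalized, and principal
    components are computed on the rows-as-features matrix.  Returns the
    integrated distance and the cells x n_pcs component scores; a
    low-dimensional neighbor embedding (UMAP) can be run on those scores.
    """
    from sklearn.decomposition import PCA

    n = len(cells)
    mats = []
    for epi, D in distances.items():
        if D.shape != (n, n):
            raise ValueError(f"cell-set mismatch for epitope {epi}")
        mats.append(_rescale_offdiag(np.asarray(D, dtype=float)))
    summed = np.sum(mats, axis=0)
    integrated = IntegratedDistance(summed, list(cells), list(distances))
    Z = summed - summed.mean(axis=1, keepdims=True)
    sd = summed.std(axis=1, keepdims=True)
    Z = np.divide(Z, sd, out=np.zeros_like(Z), where=sd > 0)
    n_pcs = min(n_pcs, n - 1, Z.shape[1])
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(Z)
    return integrated, pcs


def umap_embedding(pcs: np.ndarray, seed: int = 0, **kwargs) -> np.ndarray:
    """2-D UMAP of component scores (delegated to umap-learn)."""
    import umap

    return umap.UMAP(random_state=seed, **kwargs).fit_transform(pcs)


def entropy(freqs) -> float:
    """Shannon entropy in bits of a frequency vector (renormalized)."""
    f = np.asarray(freqs, dtype=float)
    if (f < 0).any():
        raise ValueError("frequencies must be non-negative")
    total = f.sum()
    if total == 0:
        raise ValueError("all-zero frequency vector")
    f = f / total
    nz = f[f > 0]
    return float(-(nz * np.log2(nz)).sum())


def information_gain(true_labels, cluster_assignments) -> float:
    """Entropy of the true labels minus cluster-weighted conditional entropy."""
    labels = pd.Series(list(true_labels))
    clusters = pd.Series(list(cluster_assignments))
    if len(labels) != len(clusters):
        raise ValueError("label vectors must have equal length")
    if len(labels) == 0:
        raise ValueError("empty input")
    h_total = entropy(labels.value_counts().to_numpy())
    n = len(labels)
    h_cond = 0.0
    for _, idx in clusters.groupby(clusters).groups.items():
        sub = labels.loc[idx]
        h_cond += (len(sub) / n) * entropy(sub.value_counts().to_numpy())
    return h_total - h_cond


def xci_allelic_ratio(
    allele_counts: pd.DataFrame,
    xci_epitope: str = "H3K27me3",
    ratio_threshold: float = 1.0,
    min_counts: int = 10,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Call the inactive X allele per cell and compute per-epitope ratios.

    ``allele_counts`` has columns cell, epitope, allele1, allele2 holding
    X-linked unique counts per parental allele.  The Xi is the allele with
    the higher count for the XCI marker epitope (H3K27me3 accumulates on the
    inactive X), called when |log2 ratio| exceeds ``ratio_threshold`` with at
    least ``min_counts`` marker counts on the X.  Ratios for the other
    epitopes are reported as log2(counts Xi / counts Xa) relative to the
    called Xi.  Zero allele counts are floored at ``pseudocount`` so ratios
    stay finite without shifting the ratio of cells with counts on both
    alleles.
    """

    def log2_ratio(num: float, den: float) -> float:
        return float(np.log2(max(num, pseudocount) / max(den, pseudocount)))

    out = []
    for cell, grp in allele_counts.groupby("cell", sort=True):
        marker = grp[grp["epitope"] == xci_epitope]
        xi_allele = None
        marker_ratio = np.nan
        if len(marker):
            a1 = float(marker["allele1"].sum())
            a2 = float(marker["allele2"].sum())
            marker_ratio = log2_ratio(max(a1, a2), min(a1, a2))
            if a1 + a2 >= min_counts and marker_ratio > ratio_threshold:
                xi_allele = "allele1" if a1 > a2 else "allele2"
        row = {"cell": cell, "xi_allele": xi_allele, f"{xci_epitope}_ratio": marker_ratio}
        if xi_allele is not None:
            xa_allele = "allele2" if xi_allele == "allele1" else "allele1"
            for epi, sub in grp.groupby("epitope"):
                row[f"{epi}_log2_xi_over_xa"] = log2_ratio(
                    float(sub[xi_allele].sum()), float(sub[xa_allele].sum())
                )
        out.append(row)
    return pd.DataFrame(out).set_index("cell")


def promoter_regions(
    genes: pd.DataFrame,
    upstream: int = 2000,
    downstream: int = 500,
) -> RegionSet:
    """Strand-aware promoter windows around each gene's TSS.

    ``genes`` needs columns chrom, start, end, strand and gene names as the
    index; the promoter spans [TSS - upstream, TSS + downstream) on the plus
    strand, mirrored on the minus strand.
    """
    rows = []
    for name, g in genes.iterrows():
        if g["strand"] == "+":
            tss = int(g["start"])
            lo, hi = tss - upstream, tss + downstream
        else:
            tss = int(g["end"]) - 1
            lo, hi = tss - downstream + 1, tss + upstream + 1
        rows.append((g["chrom"], max(0, lo), hi, name))
    return RegionSet.from_records(rows, name="promoters")


@dataclass
class MarkerScoreTable:
    """Gene x cell-type promoter enrichment scores (log2 CPM over rest)."""

    scores: pd.DataFrame
    cpm_pseudocount: float

    def top_markers(self, cell_type: str, n: int = 50) -> list:
        return self.scores[cell_type].sort_values(ascending=False).head(n).index.tolist()


def marker_enrichment(
    promoter_counts: pd.DataFrame,
    pseudocount: float = 1.0,
) -> MarkerScoreTable:
    """Promoter-activity marker scores per gene and cell type.

    ``promoter_counts`` is genes x cell types of raw counts over promoter
    windows.  Counts are CPM-normalized per cell type and each gene is scored
    as log2(CPM in this cell type / average CPM in the others); CPM values
    are floored at ``pseudocount`` so genes silent in one group score
    finitely without distorting expressed-vs-expressed ratios.
    """
    totals = promoter_counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every cell type needs nonzero total counts")
    cpm = promoter_counts / totals * 1e6
    scores = {}
    for ct in cpm.columns:
        others = cpm.drop(columns=ct).mean(axis=1)
        scores[ct] = np.log2(cpm[ct].clip(lower=pseudocount) / others.clip(lower=pseudocount))
    return MarkerScoreTable(pd.DataFrame(scores), cpm_pseudocount=pseudocount)


def rank_sum_markers(
    gene_counts: pd.DataFrame,
    labels: pd.Series,
    min_pct: float = 0.01,
    p_max: float = 0.001,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Wilcoxon rank-sum marker genes per cell type versus all other cells.

    ``gene_counts`` is genes x cells (e.g. summed enhancer-mark activity over
    gene bodies); ``labels`` assigns a cell type per cell.  Genes detected in
    fewer than ``min_pct`` of cells in both groups are skipped; markers with
    two-sided p below ``p_max`` are returned.
    """
    labels = labels.loc[gene_counts.columns]
    results = []
    X = gene_counts.to_numpy(dtype=float)
    detected = X > 0
    for ct in sorted(labels.unique()):
        in_grp = (labels == ct).to_numpy()
        if in_grp.sum() < min_cells:
            continue
        pct_in = detected[:, in_grp].mean(axis=1)
        pct_out = detected[:, ~in_grp].mean(axis=1)
        testable = np.maximum(pct_in, pct_out) >= min_pct
        for gi in np.where(testable)[0]:
            a = X[gi, in_grp]
            b = X[gi, ~in_grp]
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                continue
            p = mannwhitneyu(a, b, alternative="two-sided").pvalue
            if p < p_max:
                results.append(
                    (gene_counts.index[gi], ct, p, float(a.mean()), float(b.mean()),
                     float(pct_in[gi]), float(pct_out[gi]))
                )
    return pd.DataFrame(
        results,
        columns=["gene", "cell_type", "p_value", "mean_in", "mean_out", "pct_in", "pct_out"],
    )


def cross_epitope_embedding_input(
    matrix: CellEpitopeMatrix,
    min_umi_epitope: int = 150,
    min_umi_cell: int = 800,
    min_cells_per_bin: int = 10,
    top_n_per_epitope: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-(cell, epitope) feature rows for the cross-epitope embedding.

    A row is kept when its epitope total strictly exceeds ``min_umi_epitope``
    and its cell total strictly exceeds ``min_umi_cell``.  Only bins with
    counts in strictly more than ``min_cells_per_bin`` retained rows are
    used.  Values are log1p-transformed and Z-scored per bin.  Optionally
    only the ``top_n_per_epitope`` highest-depth rows per epitope are kept.
    """
    totals = matrix.epitope_totals()
    cell_total = totals.sum(axis=1)
    rows = []
    for epi in matrix.epitopes:
        ok = (totals[epi] > min_umi_epitope) & (cell_total > min_umi_cell)
        cand = [(epi, c, totals.at[c, epi]) for c in totals.index[ok]]
        if top_n_per_epitope is not None:
            cand = sorted(cand, key=lambda t: -t[2])[:top_n_per_epitope]
        rows.extend(cand)
    if not rows:
        return np.empty((0, 0)), pd.DataFrame(columns=["epitope", "cell", "depth"])
    meta = pd.DataFrame(rows, columns=["epitope", "cell", "depth"])
    cell_pos = {c: i for i, c in enumerate(matrix.obs.index)}
    data = np.stack(
        [
            np.asarray(matrix.counts[epi][:, cell_pos[cell]].todense()).ravel()
            for epi, cell in zip(meta["epitope"], meta["cell"])
        ]
    )
    used = (data > 0).sum(axis=0) > min_cells_per_bin
    data = np.log1p(data[:, used])
    mu = data.mean(axis=0)
    sd = data.std(axis=0)
    data = np.divide(data - mu, sd, out=np.zeros_like(data), where=sd > 0)
    return data, meta


def diffusion_input(
    matrix: CellEpitopeMatrix,
    target_bin_size: int = 1_000_000,
    min_bin_count: int = 20,
    n_pcs: int = 4,
    seed: int = 0,
) -> np.ndarray:
    """Preprocess for diffusion-map embedding: coarse bins, PCs 1..n_pcs.

    Epitope matrices are re-binned, concatenated per cell, bins with fewer
    than ``min_bin_count`` total counts removed, depth-normalized and
    log-transformed, scaled, then reduced by PCA.  The diffusion-map
    eigen-solver itself is delegated to any standard implementation.
    """
    from sklearn.decomposition import PCA

    coarse = matrix.rebin(target_bin_size) if target_bin_size != matrix.bin_size else matrix
    blocks = [np.asarray(coarse.counts[e].todense(), dtype=float) for e in coarse.epitopes]
    feat = np.vstack(blocks)  # (bins * epitopes) x cells
    feat = feat[feat.sum(axis=1) >= min_bin_count]
    depth = feat.sum(axis=0)
    depth[depth == 0] = 1.0
    X = np.log1p(feat / depth * depth.mean()).T  # cells x features
    mu, sd = X.mean(axis=0), X.std(axis=0)
    X = np.divide(X - mu, sd, out=np.zeros_like(X), where=sd > 0)
    n_pcs = min(n_pcs, X.shape[0] - 1, X.shape[1])
    return PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
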