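"""Single-cell QC, ISP aggregation, integration, IG, XCI and marker calling."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from mabid.simulate import SimConfig, simulate_cells, simulate_xci_counts
from mabid.singlecell import (
    CellEpitopeMatrix,
    build_isp,
    cross_epitope_embedding_input,
    diffusion_input,
    entropy,
    information_gain,
    integrate_epitopes,
    jaccard_distance,
    marker_enrichment,
    promoter_regions,
    qc_filter,
    rank_sum_markers,
    xci_allelic_ratio,
)


def small_matrix(counts_by_epitope, cell_ids=None, bin_size=20_000, **obs_cols):
    any_mat = next(iter(counts_by_epitope.values()))
    n_bins, n_cells = np.asarray(any_mat).shape
    cell_ids = cell_ids or [f"c{i}" for i in range(n_cells)]
    bins = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(n_bins) * bin_size}
    )
    obs = pd.DataFrame(obs_cols, index=cell_ids) if obs_cols else pd.DataFrame(index=cell_ids)
    return CellEpitopeMatrix(
        {e: sp.csr_matrix(np.asarray(m)) for e, m in counts_by_epitope.items()},
        bins, obs, bin_size,
    )


class TestQcFilter:
    def test_low_epitope_total_drops_cell_despite_high_total(self):
        mat = small_matrix({
            "A": [[850, 900], [0, 0]],
            "B": [[50, 100], [0, 0]],
        })
        filtered, report = qc_filter(mat, min_cell_umi=800, min_epitope_umi=64)
        assert filtered.cells == ["c1"]
        assert not report.loc["c0", "pass_epitope_minimum"]
        assert report.loc["c0", "pass_cell_total"]

    def test_zero_thresholds_are_identity(self):
        mat = small_matrix({"A": [[1, 0], [0, 2]]})
        filtered, _ = qc_filter(mat, min_cell_umi=0, min_epitope_umi=None)
        assert filtered.cells == mat.cells

    def test_retained_set_matches_analytic_expectation(self):
        rng = np.random.default_rng(0)
        counts = {e: rng.integers(0, 300, size=(5, 100)) for e in ("A", "B")}
        mat = small_matrix(counts)
        totals = mat.epitope_totals()
        expected = (
            (totals.sum(axis=1) >= 800) & (totals >= 64).all(axis=1)
        )
        filtered, report = qc_filter(mat)
        assert filtered.cells == list(totals.index[expected])
        assert report["retained"].sum() == expected.sum()


class TestIsp:
    def test_group_sum_of_two_cells(self):
        mat = small_matrix({"A": [[1, 0], [0, 2]]}, cell_type=["t", "t"])
        isp = build_isp(mat, "cell_type")
        assert isp[("t",)]["A"].values["chr1"].tolist() == [1.0, 2.0]

    def test_singleton_group_equals_cell(self):
        mat = small_matrix({"A": [[3, 7], [1, 0]]}, cell_type=["x", "y"])
        isp = build_isp(mat, "cell_type")
        assert isp[("x",)]["A"].values["chr1"].tolist() == [3.0, 1.0]

    def test_group_totals_conserve_cell_totals(self):
        rng = np.random.default_rng(1)
        mat = small_matrix(
            {"A": rng.integers(0, 9, (10, 30))},
            cell_type=list(rng.choice(["a", "b", "c"], 30)),
        )
        isp = build_isp(mat, "cell_type")
        total = sum(t["A"].total() for t in isp.values())
        assert total == mat.cell_totals().sum()

    def test_simulated_types_recover_their_profiles(self, sim_config):
        cfg = SimConfig(seed=21, cells_per_type=200)
        mat, type_domains = simulate_cells(cfg, epitopes=["e1"], cell_types=("A", "B"))
        isp = build_isp(mat, "cell_type")

        def truth_profile(ct):
            dom = type_domains[f"{ct}:e1"]
            w = np.zeros(len(mat.bins))
            for chrom, idx in dom.bin_indices(mat.bin_size).items():
                chrom_bins = np.flatnonzero((mat.bins["chrom"] == chrom).to_numpy())
                w[chrom_bins[idx[idx < len(chrom_bins)]]] = 1.0
            return w

        for ct in ("A", "B"):
            observed = np.concatenate(
                [isp[(ct,)]["e1"].values[c] for c in isp[(ct,)]["e1"].values]
            )
            own = np.corrcoef(observed, truth_profile(ct))[0, 1]
            assert own > 0.5  # domain indicator vs counts incl. accessibility noise


class TestJaccard:
    def test_identical_profiles_distance_zero(self):
        D = jaccard_distance(np.array([[1, 0, 1], [1, 0, 1]]))
        assert D[0, 1] == 0.0

    def test_disjoint_profiles_distance_one(self):
        D = jaccard_distance(np.array([[1, 1, 0, 0], [0, 0, 1, 1]]))
        assert D[0, 1] == 1.0

    def test_partial_overlap_formula(self):
        a = [1, 1, 1, 1, 0, 0]
        b = [1, 1, 0, 0, 1, 1]
        D = jaccard_distance(np.array([a, b]))
        assert D[0, 1] == pytest.approx(1 - 2 / 6)

    def test_empty_pair_maximally_dissimilar_but_diagonal_zero(self):
        D = jaccard_distance(np.zeros((2, 4)))
        assert D[0, 1] == 1.0
        assert D[0, 0] == 0.0 and D[1, 1] == 0.0

    def test_counts_are_binarized(self):
        D1 = jaccard_distance(np.array([[5, 0, 2], [1, 0, 9]]))
        D2 = jaccard_distance(np.array([[1, 0, 1], [1, 0, 1]]))
        assert D1[0, 1] == D2[0, 1] == 0.0


class TestIntegration:
    def test_single_epitope_equals_rescaled_input(self):
        rng = np.random.default_rng(2)
        D = rng.random((6, 6))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        cells = [f"c{i}" for i in range(6)]
        integrated, _ = integrate_epitopes({"A": D}, cells, n_pcs=2)
        off = ~np.eye(6, dtype=bool)
        expected = (D - D[off].min()) / (D[off].max() - D[off].min())
        np.fill_diagonal(expected, 0)
        np.testing.assert_allclose(integrated.matrix, expected)

    def test_duplicate_epitopes_double_the_sum(self):
        rng = np.random.default_rng(3)
        D = rng.random((5, 5))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        cells = [f"c{i}" for i in range(5)]
        one, _ = integrate_epitopes({"A": D}, cells, n_pcs=2)
        two, _ = integrate_epitopes({"A": D, "B": D.copy()}, cells, n_pcs=2)
        np.testing.assert_allclose(two.matrix, 2 * one.matrix)

    def test_cell_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            integrate_epitopes({"A": np.zeros((3, 3))}, ["c0", "c1"])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        D = rng.random((8, 8))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        cells = [f"c{i}" for i in range(8)]
        perm = rng.permutation(8)
        a, _ = integrate_epitopes({"A": D}, cells)
        b, _ = integrate_epitopes({"A": D[np.ix_(perm, perm)]}, [cells[i] for i in perm])
        np.testing.assert_allclose(b.matrix, a.matrix[np.ix_(perm, perm)])

    def test_two_cell_types_separate_in_pc_space(self):
        """Scaled-down pan-epitope integration still separates cell types."""
        cfg = SimConfig(seed=31, cells_per_type=60, mean_umis_per_cell_epitope=200)
        mat, _ = simulate_cells(cfg, epitopes=[f"e{i}" for i in range(4)])
        coarse = mat.rebin(100_000)
        dists = {e: jaccard_distance(m.T) for e, m in coarse.counts.items()}
        _, pcs = integrate_epitopes(dists, coarse.cells, n_pcs=10, seed=0)
        pred = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(pcs)
        ari = adjusted_rand_score(coarse.obs["cell_type"], pred)
        assert ari >= 0.9


class TestInformationGain:
    @pytest.mark.parametrize(
        "freqs,expected",
        [([0.5, 0.5], 1.0), ([1.0], 0.0), ([0.25] * 4, 2.0), ([2, 2], 1.0)],
    )
    def test_entropy_exact_values(self, freqs, expected):
        assert entropy(freqs) == pytest.approx(expected)

    def test_entropy_rejects_all_zero(self):
        with pytest.raises(ValueError):
            entropy([0.0, 0.0])

    def test_perfect_split_gains_one_bit(self):
        labels = ["a"] * 50 + ["b"] * 50
        clusters = [0] * 50 + [1] * 50
        assert information_gain(labels, clusters) == pytest.approx(1.0)

    def test_independent_clusters_gain_nothing(self):
        rng = np.random.default_rng(5)
        labels = rng.choice(["a", "b"], 4000)
        clusters = rng.choice([0, 1, 2], 4000)
        assert abs(information_gain(labels, clusters)) < 0.01

    def test_bounded_by_label_entropy_and_nonnegative(self):
        rng = np.random.default_rng(6)
        labels = rng.choice(["a", "b", "c"], 500)
        clusters = rng.choice(range(5), 500)
        ig = information_gain(labels, clusters)
        assert 0 <= ig <= entropy(pd.Series(labels).value_counts().to_numpy())

    def test_merging_clusters_never_increases_gain(self):
        rng = np.random.default_rng(7)
        labels = rng.choice(["a", "b"], 600)
        fine = rng.choice(range(6), 600)
        merged = fine // 2
        assert information_gain(labels, merged) <= information_gain(labels, fine) + 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            information_gain([], [])


class TestXci:
    def test_skewed_cell_ratio_and_call(self):
        table = pd.DataFrame(
            [("c1", "H3K27me3", 8, 2)], columns=["cell", "epitope", "allele1", "allele2"]
        )
        out = xci_allelic_ratio(table)
        assert out.loc["c1", "H3K27me3_ratio"] == pytest.approx(2.0)  # log2(8/2)
        assert out.loc["c1", "xi_allele"] == "allele1"

    def test_balanced_cell_not_called(self):
        table = pd.DataFrame(
            [("c1", "H3K27me3", 5, 5)], columns=["cell", "epitope", "allele1", "allele2"]
        )
        out = xci_allelic_ratio(table)
        assert out.loc["c1", "H3K27me3_ratio"] == pytest.approx(0.0)
        assert out.loc["c1", "xi_allele"] is None

    def test_other_epitopes_reported_relative_to_xi(self):
        table = pd.DataFrame(
            [
                ("c1", "H3K27me3", 16, 4),
                ("c1", "H3K4me1", 2, 8),
                ("c1", "H3K9me3", 12, 3),
            ],
            columns=["cell", "epitope", "allele1", "allele2"],
        )
        out = xci_allelic_ratio(table)
        assert out.loc["c1", "xi_allele"] == "allele1"
        assert out.loc["c1", "H3K4me1_log2_xi_over_xa"] == pytest.approx(-2.0)
        assert out.loc["c1", "H3K9me3_log2_xi_over_xa"] == pytest.approx(2.0)

    def test_simulated_sensitivity_and_specificity(self, sim_config):
        table, status = simulate_xci_counts(SimConfig(seed=41), n_cells=1000)
        calls = xci_allelic_ratio(table)["xi_allele"].notna()
        sens = calls[status].mean()
        spec = (~calls[~status]).mean()
        assert sens >= 0.90
        assert spec >= 0.95


class TestMarkers:
    def test_promoter_windows_strand_aware(self):
        genes = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [10_000, 50_000],
                "end": [20_000, 60_000],
                "strand": ["+", "-"],
            },
            index=["gplus", "gminus"],
        )
        prom = promoter_regions(genes)
        plus = prom.df[prom.df["label"] == "gplus"].iloc[0]
        minus = prom.df[prom.df["label"] == "gminus"].iloc[0]
        assert (plus["start"], plus["end"]) == (8_000, 10_500)
        assert (minus["start"], minus["end"]) == (59_500, 62_000)

    def test_enrichment_score_formula(self):
        counts = pd.DataFrame(
            {"A": [100, 100], "B": [25, 100], "C": [25, 100]},
            index=["marker", "house"],
        )
        # equal totals, so counts are proportional to CPM
        table = marker_enrichment(counts * 1.0)
        ratio = table.scores.loc["marker", "A"]
        # CPM ratio: (100/200) / mean(25/125, 25/125) = 2.5
        assert ratio == pytest.approx(np.log2((100 / 200) / (25 / 125)))

    def test_equal_cpm_scores_zero_everywhere(self):
        counts = pd.DataFrame({"A": [10, 30], "B": [10, 30], "C": [10, 30]}, index=["g1", "g2"])
        table = marker_enrichment(counts * 1.0)
        np.testing.assert_allclose(table.scores.to_numpy(), 0.0, atol=1e-12)

    def test_planted_markers_rank_top(self):
        rng = np.random.default_rng(8)
        n_genes = 200
        base = rng.poisson(50, size=(n_genes, 3)).astype(float)
        planted = list(range(10))
        base[planted, 0] *= 4  # 4x enriched in cell type A
        counts = pd.DataFrame(base, columns=["A", "B", "C"],
                              index=[f"g{i}" for i in range(n_genes)])
        table = marker_enrichment(counts)
        top = table.top_markers("A", n=10)
        assert set(top) == {f"g{i}" for i in planted}

    def test_rank_sum_detects_exclusive_gene(self):
        rng = np.random.default_rng(9)
        n_a, n_b = 50, 50
        counts = pd.DataFrame(
            np.zeros((3, n_a + n_b)),
            index=["exclusive", "ubiquitous", "silent"],
            columns=[f"c{i}" for i in range(n_a + n_b)],
        )
        expressed = rng.choice(n_a, 15, replace=False)  # 30% of A cells
        counts.iloc[0, expressed] = rng.poisson(8, 15) + 1
        counts.iloc[1] = rng.poisson(5, n_a + n_b)
        labels = pd.Series(["A"] * n_a + ["B"] * n_b, index=counts.columns)
        out = rank_sum_markers(counts, labels)
        assert ("exclusive", "A") in set(zip(out["gene"], out["cell_type"]))
        assert "silent" not in set(out["gene"])

    def test_identical_distributions_not_retained(self):
        rng = np.random.default_rng(10)
        counts = pd.DataFrame(
            rng.poisson(5, size=(20, 80)).astype(float),
            index=[f"g{i}" for i in range(20)],
            columns=[f"c{i}" for i in range(80)],
        )
        labels = pd.Series(["A"] * 40 + ["B"] * 40, index=counts.columns)
        out = rank_sum_markers(counts, labels)
        assert len(out) == 0  # p < 0.001 on identical distributions is rare

    def test_label_permutation_destroys_calls(self):
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(
            np.vstack([
                np.concatenate([rng.poisson(20, 40), rng.poisson(2, 40)]),
                rng.poisson(5, 80),
            ]).astype(float),
            index=["real_marker", "noise"],
            columns=[f"c{i}" for i in range(80)],
        )
        labels = pd.Series(["A"] * 40 + ["B"] * 40, index=counts.columns)
        assert len(rank_sum_markers(counts, labels)) > 0
        null_hits = 0
        for i in range(40):
            perm = pd.Series(rng.permutation(labels.to_numpy()), index=counts.columns)
            null_hits += len(rank_sum_markers(counts, perm)) > 0
        assert null_hits <= 2  # >= 95% of permutations yield no calls


class TestEmbeddingInput:
    def test_strict_threshold_boundaries(self):
        mat = small_matrix({
            "A": np.array([[150, 151], [0, 0]]),
        })
        data, meta = cross_epitope_embedding_input(
            mat, min_umi_epitope=150, min_umi_cell=0, min_cells_per_bin=0
        )
        # cell with exactly 150 epitope UMIs excluded (strict inequality)
        assert meta["cell"].tolist() == ["c1"]

    def test_bin_cell_support_strict(self):
        rng = np.random.default_rng(12)
        counts = np.ones((2, 12))
        counts[1, 10:] = 0  # bin 1 covered by 10 rows only
        mat = small_matrix({"A": counts})
        data, meta = cross_epitope_embedding_input(
            mat, min_umi_epitope=0, min_umi_cell=0, min_cells_per_bin=10
        )
        assert data.shape[1] == 1  # only bin 0 (12 cells > 10) retained

    def test_row_count_matches_analytic_truth(self):
        cfg = SimConfig(seed=51, cells_per_type=40, mean_umis_per_cell_epitope=180)
        mat, _ = simulate_cells(cfg, epitopes=["e1", "e2"])
        totals = mat.epitope_totals()
        cell_tot = totals.sum(axis=1)
        expected = int(
            ((totals["e1"] > 150) & (cell_tot > 300)).sum()
            + ((totals["e2"] > 150) & (cell_tot > 300)).sum()
        )
        data, meta = cross_epitope_embedding_input(
            mat, min_umi_epitope=150, min_umi_cell=300, min_cells_per_bin=5
        )
        assert len(meta) == expected
        assert data.shape[0] == expected

    def test_top_n_depth_selection(self):
        cfg = SimConfig(seed=52, cells_per_type=30)
        mat, _ = simulate_cells(cfg, epitopes=["e1"])
        _, meta = cross_epitope_embedding_input(
            mat, min_umi_epitope=0, min_umi_cell=0, top_n_per_epitope=10
        )
        assert len(meta) == 10
        totals = mat.epitope_totals()["e1"].sort_values(ascending=False)
        assert set(meta["cell"]) == set(totals.index[:10])

    def test_diffusion_input_shape(self):
        cfg = SimConfig(seed=53, cells_per_type=25)
        mat, _ = simulate_cells(cfg, epitopes=["e1", "e2"], cell_bin_size=100_000)
        pcs = diffusion_input(mat, target_bin_size=100_000, min_bin_count=5, n_pcs=4)
        assert pcs.shape == (50, 4)
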