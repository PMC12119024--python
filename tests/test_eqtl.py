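import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import anndata as ad
import statsmodels.api as sm

from gametiq import (
    BinGrid,
    EqtlEffect,
    SimConfig,
    assign_celltypes,
    call_peaks,
    celltype_scan,
    classify_peaks,
    correct_multiple_testing,
    finemap_hotspot,
    fit_bin_models,
    li_ji_meff,
    preprocess_expression,
    simulate_expression,
    simulate_truth_haplotypes,
)
from gametiq.eqtl import TWO_LN10, EqtlResult, normalize_counts


def make_adata(counts, genes=None):
    n, g = counts.shape
    genes = genes or [f"G{j}" for j in range(g)]
    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.float32)),
        obs=pd.DataFrame(index=[f"b{i}" for i in range(n)]),
        var=pd.DataFrame(index=genes),
    )
    adata.layers["counts"] = adata.X.copy()
    return adata


class TestPreprocess:
    def test_gene_detection_filters(self, rng):
        n = 100
        counts = np.zeros((n, 3))
        counts[:9, 0] = 5  # 9 barcodes -> dropped entirely
        counts[:30, 1] = 5  # 30% of nuclei -> kept, eQTL phenotype
        counts[:4, 2] = 5  # 4% -> kept for PCA but not an eQTL phenotype
        counts[:, 2] += 0  # leave below 5%
        counts[4:12, 2] = 5  # now 12 barcodes (12%) -> phenotype
        counts[:, 2][12:] = 0
        adata = preprocess_expression(make_adata(counts), n_pcs=2)
        assert list(adata.var_names) == ["G1", "G2"]
        assert adata.var["eqtl_phenotype"].tolist() == [True, True]

    def test_exact_five_percent_is_inclusive(self):
        counts = np.zeros((100, 2))
        counts[:5, 0] = 1  # exactly 5%
        counts[:60, 1] = 1
        # relax the 10-barcode filter so the 5-barcode gene survives to the
        # phenotype decision
        adata = preprocess_expression(make_adata(counts), min_barcodes=2, n_pcs=1)
        assert adata.var["eqtl_phenotype"].tolist() == [True, True]

    def test_normalization_formula(self):
        counts = np.array([[10.0, 90.0]])
        norm = normalize_counts(counts, scale=10_000)
        assert norm[0, 0] == pytest.approx(np.log2(1 + 10 * 10_000 / 100))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            preprocess_expression(make_adata(np.zeros((0, 5))))


@pytest.fixture(scope="module")
def scan_fixture():
    rng = np.random.default_rng(31)
    n, B = 500, 40
    grid = BinGrid({"chr1": B * 25_000}, 25_000)
    H = (rng.random((n, B // 2)) < 0.5).astype(float)
    H = np.repeat(H, 2, axis=1)  # correlated neighbouring bins
    pcs = rng.normal(size=(n, 2))
    beta = 0.8
    Y = np.column_stack(
        [
            beta * H[:, 10] + pcs @ [0.5, -0.2] + rng.normal(0, 1, n),
            rng.normal(0, 1, n),
        ]
    )
    return grid, H, pcs, Y, beta


class TestBinModels:
    def test_matches_statsmodels_ols_lrt(self, scan_fixture):
        grid, H, pcs, Y, _ = scan_fixture
        res = fit_bin_models(Y, ["g0", "g1"], H, grid=grid, pcs=pcs, n_pcs=2)
        n = Y.shape[0]
        for gi in (0, 1):
            for b in (0, 10, 33):
                X = np.column_stack([np.ones(n), H[:, b], pcs])
                full = sm.OLS(Y[:, gi], X).fit()
                nested = sm.OLS(Y[:, gi], X[:, [0, 2, 3]]).fit()
                lam = n * np.log(nested.ssr / full.ssr)
                assert res.lrt[gi, b] == pytest.approx(lam, rel=1e-9)
                assert res.coef[0, gi, b] == pytest.approx(full.params[1], rel=1e-9)
                assert res.coef_p[0, gi, b] == pytest.approx(
                    full.pvalues[1], rel=1e-6
                )

    def test_lod_identity(self, scan_fixture):
        grid, H, pcs, Y, _ = scan_fixture
        res = fit_bin_models(Y, ["g0", "g1"], H, grid=grid, pcs=pcs)
        np.testing.assert_allclose(res.lod, res.lrt / TWO_LN10, rtol=0, atol=0)
        assert (4.60517 / TWO_LN10) == pytest.approx(1.0, abs=1e-5)

    def test_constant_haplotype_column_gives_zero_lrt(self, scan_fixture):
        grid, H, pcs, Y, _ = scan_fixture
        H2 = H.copy()
        H2[:, 5] = 1.0  # no recombination at this bin
        res = fit_bin_models(Y, ["g0", "g1"], H2, grid=grid, pcs=pcs)
        assert res.lrt[:, 5] == pytest.approx(0.0)
        assert res.p[:, 5] == pytest.approx(1.0)
        assert res.df[5] == 0

    def test_genotype_split_haplotype_regressors(self, rng):
        n, B = 600, 10
        grid = BinGrid({"chr1": B * 25_000}, 25_000)
        H = (rng.random((n, B)) < 0.5).astype(float)
        geno = rng.integers(0, 2, size=n)
        # effect only in genotype 0
        y = 1.0 * H[:, 3] * (geno == 0) + rng.normal(0, 1, n)
        res = fit_bin_models(
            y[:, None], ["g"], H, grid=grid, genotype=geno, n_genotypes=2
        )
        assert res.coef[0, 0, 3] == pytest.approx(1.0, abs=0.2)
        assert res.coef_p[0, 0, 3] < 1e-6
        assert res.coef_p[1, 0, 3] > 0.01

    def test_missing_genotype_regressor_dropped(self, rng):
        n, B = 200, 5
        grid = BinGrid({"chr1": B * 25_000}, 25_000)
        H = (rng.random((n, B)) < 0.5).astype(float)
        geno = np.zeros(n, dtype=int)  # genotype 1 has no nuclei
        y = rng.normal(size=n)
        res = fit_bin_models(
            y[:, None], ["g"], H, grid=grid, genotype=geno, n_genotypes=2
        )
        assert (res.df <= 1).all()
        assert np.isfinite(res.lrt).all()


class TestMultipleTesting:
    def test_meff_identity_correlation(self, rng):
        H = rng.normal(size=(500, 30))
        assert li_ji_meff(H) == pytest.approx(30, rel=0.15)

    def test_meff_perfect_correlation_is_one(self, rng):
        base = rng.normal(size=(200, 1))
        H = np.tile(base, (1, 10))
        assert li_ji_meff(H) == pytest.approx(1.0, abs=1e-9)

    def test_meff_three_bin_toy_equals_direct_eigen(self, rng):
        # build three bins with pairwise correlation 0.5: eigenvalues of the
        # correlation matrix are {2, 0.5, 0.5}, so Meff = 1 + 0.5 + 0.5 = 2
        n = 200_000
        shared = rng.normal(size=n)
        H = np.column_stack(
            [shared + rng.normal(size=n), shared + rng.normal(size=n), shared + rng.normal(size=n)]
        )
        corr = np.corrcoef(H.T)
        lam = np.linalg.eigvalsh(corr)
        direct = np.sum((lam >= 1) + (lam - np.floor(lam)))
        assert li_ji_meff(H) == pytest.approx(direct, abs=1e-9)
        assert direct == pytest.approx(2.0, abs=0.02)

    def test_meff_bounded_and_reorder_invariant(self, rng):
        H = np.repeat((rng.random((300, 12)) < 0.5).astype(float), 3, axis=1)
        m = li_ji_meff(H)
        assert m <= 36
        perm = rng.permutation(36)
        assert li_ji_meff(H[:, perm]) == pytest.approx(m, abs=1e-8)

    def test_adjusted_p_and_gene_fdr(self, rng):
        grid = BinGrid({"chr1": 20 * 25_000}, 25_000)
        H = (rng.random((300, 20)) < 0.5).astype(float)
        Y = rng.normal(size=(300, 5))
        res = fit_bin_models(Y, [f"g{i}" for i in range(5)], H, grid=grid)
        res = correct_multiple_testing(res, H)
        assert (res.p_adj >= res.p - 1e-12).all()
        assert ((res.gene_fdr >= 0) & (res.gene_fdr <= 1)).all()

    def test_type_one_error_controlled_under_permutation(self, rng):
        # null: haplotypes shuffled across nuclei relative to expression
        config = SimConfig(
            chromosome_lengths={"chr1": 10_000_000},
            n_nuclei=400,
            seed=41,
            n_genes=120,
        )
        truth = simulate_truth_haplotypes(config)
        adata = preprocess_expression(simulate_expression(truth, config))
        H = truth.haplotype[rng.permutation(truth.n_nuclei)].astype(float)
        pheno = adata.var["eqtl_phenotype"].to_numpy()
        Y = np.asarray(adata.layers["normalized"])[:, pheno]
        res = fit_bin_models(
            Y, list(adata.var_names[pheno]), H, grid=truth.grid,
            pcs=adata.obsm["X_pca"], n_pcs=2,
        )
        res = correct_multiple_testing(res, H)
        frac = (res.gene_fdr < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(res.genes))
        assert frac <= 0.05 + 3 * se


class TestPeaks:
    def lod_result(self, lod, grid, genes=("g0",)):
        lod = np.atleast_2d(lod)
        G, B = lod.shape
        res = EqtlResult(
            genes=list(genes),
            grid=grid,
            lrt=lod * TWO_LN10,
            lod=lod,
            p=np.full((G, B), 1e-9),
            df=np.ones(B, dtype=int),
            bin_mask=np.ones(B, bool),
        )
        res.meff = 1.0
        res.p_adj = res.p.copy()
        res.gene_fdr = np.zeros(G)
        return res

    def test_flat_profile_below_threshold_yields_nothing(self):
        grid = BinGrid({"chr1": 200 * 25_000}, 25_000)
        lod = np.full(200, 2.9)
        assert len(call_peaks(self.lod_result(lod, grid))) == 0

    def test_lod_drop_interval(self):
        grid = BinGrid({"chr1": 200 * 25_000}, 25_000)
        lod = np.zeros(200)
        lod[80:121] = 10 - 0.1 * np.abs(np.arange(80, 121) - 100)
        peaks = call_peaks(self.lod_result(lod, grid))
        assert len(peaks) == 1
        pk = peaks.iloc[0]
        assert pk["bin"] == 100
        # CI = bins with LOD >= 8.5: |b - 100| <= 15
        assert pk["ci_lo"] == 85 * 25_000
        assert pk["ci_hi"] == 116 * 25_000

    def test_close_secondary_peak_suppressed(self):
        grid = BinGrid({"chr1": 400 * 25_000}, 25_000)
        lod = np.zeros(400)
        lod[100] = 10.0
        lod[180] = 8.0  # 2 Mb away: inside the 3 Mb exclusion
        lod[350] = 8.0  # 6.25 Mb away: kept
        peaks = call_peaks(self.lod_result(lod, grid))
        assert sorted(peaks["bin"]) == [100, 350]

    def test_low_prominence_shoulder_not_called(self):
        grid = BinGrid({"chr1": 400 * 25_000}, 25_000)
        lod = np.zeros(400)
        lod[100] = 10.0
        lod[300] = 2.0  # below 25% of the top peak
        lod[301] = 1.0
        peaks = call_peaks(self.lod_result(lod, grid))
        assert peaks["bin"].tolist() == [100]

    @pytest.mark.parametrize(
        "peak_chrom,ci_lo,ci_hi,expected",
        [
            ("chr2", 0, 50_000, "trans"),  # different chromosome
            ("chr1", 3_000_000, 3_100_000, "cis"),  # exactly 2 Mb from gene edge
            ("chr1", 9_000_000, 9_500_000, "trans"),  # 8 Mb away
            ("chr1", 1_000_000, 1_030_000, "cis"),
        ],
    )
    def test_cis_trans_classification(self, peak_chrom, ci_lo, ci_hi, expected):
        peaks = pd.DataFrame(
            [
                {
                    "gene": "g0",
                    "chrom": peak_chrom,
                    "bin": 0,
                    "position": ci_lo,
                    "lod": 5.0,
                    "ci_lo": ci_lo,
                    "ci_hi": ci_hi,
                    "celltype": "all",
                }
            ]
        )
        coords = pd.DataFrame(
            [{"gene": "g0", "chrom": "chr1", "start": 1_000_000, "end": 1_005_000}]
        )
        out = classify_peaks(peaks, coords)
        assert out["class"].iloc[0] == expected

    def test_unknown_gene_coordinates_rejected(self):
        peaks = pd.DataFrame(
            [{"gene": "gX", "chrom": "chr1", "bin": 0, "position": 0.0,
              "lod": 5.0, "ci_lo": 0, "ci_hi": 1, "celltype": "all"}]
        )
        coords = pd.DataFrame([{"gene": "g0", "chrom": "chr1", "start": 0, "end": 1}])
        with pytest.raises(ValueError, match="unknown gene"):
            classify_peaks(peaks, coords)

    def test_peak_always_inside_its_ci_on_simulation(self):
        config = SimConfig(
            chromosome_lengths={"chr1": 20_000_000},
            n_nuclei=800,
            seed=43,
            n_genes=40,
            eqtl_effects=[
                EqtlEffect(gene="GENE0003", chrom="chr1", bin_index=300, effect_size=1.2)
            ],
        )
        truth = simulate_truth_haplotypes(config)
        adata = preprocess_expression(simulate_expression(truth, config))
        pheno = adata.var["eqtl_phenotype"].to_numpy()
        Y = np.asarray(adata.layers["normalized"])[:, pheno]
        res = fit_bin_models(
            Y, list(adata.var_names[pheno]), truth.haplotype.astype(float),
            grid=truth.grid, pcs=adata.obsm["X_pca"],
        )
        res = correct_multiple_testing(res, truth.haplotype.astype(float))
        peaks = call_peaks(res)
        assert len(peaks) >= 1
        for _, pk in peaks.iterrows():
            assert pk["ci_lo"] <= pk["position"] <= pk["ci_hi"]
        best = peaks.loc[peaks["gene"] == "GENE0003"].iloc[0]
        assert best["ci_lo"] <= 300 * 25_000 <= best["ci_hi"]


class TestCelltypeScan:
    def test_celltype_restricted_effect_detected_in_right_type(self):
        config = SimConfig(
            chromosome_lengths={"chr1": 15_000_000},
            n_nuclei=3_000,
            seed=47,
            n_genes=40,
            celltype_proportions={"sperm": 0.5, "vegetative": 0.5},
            eqtl_effects=[
                EqtlEffect(
                    gene="GENE0005", chrom="chr1", bin_index=200,
                    effect_size=1.0, celltype="sperm",
                )
            ],
        )
        truth = simulate_truth_haplotypes(config)
        adata = preprocess_expression(simulate_expression(truth, config))
        probs = assign_celltypes(adata)
        # orient columns to the true labels for the assertion
        sperm_col = int(
            probs[truth.celltype == "sperm", 1].mean()
            > probs[truth.celltype == "sperm", 0].mean()
        )
        pheno = adata.var["eqtl_phenotype"].to_numpy()
        Y = np.asarray(adata.layers["normalized"])[:, pheno]
        genes = list(adata.var_names[pheno])
        H = truth.haplotype.astype(float)
        from gametiq.rhmm import HaplotypeField

        field = HaplotypeField(
            posterior=H,
            viterbi=truth.haplotype,
            boundary_prob=np.zeros_like(H),
            expected_crossovers=np.zeros(len(H)),
            barcodes=truth.barcodes,
            grid=truth.grid,
        )
        res, peaks = celltype_scan(
            Y, genes, field, probs, celltype_names=["ct0", "ct1"],
            pcs=adata.obsm["X_pca"], n_pcs=2,
        )
        gi = genes.index("GENE0005")
        t_sperm = sperm_col
        t_veg = 1 - sperm_col
        assert res.coef_p[t_sperm, gi, 200] < 1e-6
        assert res.coef_p[t_veg, gi, 200] > 1e-3
        lab = f"ct{t_sperm}"
        called = peaks[(peaks["gene"] == "GENE0005") & (peaks["celltype"] == lab)]
        assert len(called) == 1

    def test_hard_celltype_probabilities_collapse_to_subset_model(self, rng):
        n, B = 400, 8
        grid = BinGrid({"chr1": B * 25_000}, 25_000)
        H = (rng.random((n, B)) < 0.5).astype(float)
        ct = np.zeros((n, 2))
        ct[:, 0] = 1.0  # every nucleus is type A
        y = 0.7 * H[:, 2] + rng.normal(0, 1, n)
        from gametiq.rhmm import HaplotypeField

        field = HaplotypeField(
            posterior=H, viterbi=H.astype(np.int8), boundary_prob=np.zeros_like(H),
            expected_crossovers=np.zeros(n), barcodes=[f"b{i}" for i in range(n)],
            grid=grid,
        )
        res, _ = celltype_scan(y[:, None], ["g"], field, ct)
        plain = fit_bin_models(y[:, None], ["g"], H, grid=grid)
        np.testing.assert_allclose(res.lrt[0], plain.lrt[0], atol=1e-8)


class TestFinemap:
    def test_hotspot_recovered_by_top_component(self):
        hotspot_bin = 400
        effects = [
            EqtlEffect(
                gene=f"GENE{j:04d}", chrom="chr1", bin_index=hotspot_bin,
                effect_size=0.8,
            )
            for j in range(30)
        ]
        config = SimConfig(
            chromosome_lengths={"chr1": 25_000_000},
            n_nuclei=900,
            seed=53,
            n_genes=80,
            eqtl_effects=effects,
        )
        truth = simulate_truth_haplotypes(config)
        adata = preprocess_expression(simulate_expression(truth, config))
        qc = pd.DataFrame(
            {
                "barcode": truth.barcodes,
                "classifier_prob": 1.0,
                "doublet_prob": 0.0,
                "log10_markers": 3.0,
            }
        )
        # feed peaks directly: all affected genes trans at the hotspot
        peaks = pd.DataFrame(
            [
                {
                    "gene": e.gene, "chrom": "chr1", "bin": hotspot_bin,
                    "position": (hotspot_bin + 0.5) * 25_000, "lod": 10.0,
                    "ci_lo": (hotspot_bin - 2) * 25_000,
                    "ci_hi": (hotspot_bin + 2) * 25_000,
                    "celltype": "all", "class": "trans",
                }
                for e in effects
            ]
        )
        from gametiq.rhmm import HaplotypeField

        H = truth.haplotype.astype(float)
        field = HaplotypeField(
            posterior=H, viterbi=truth.haplotype, boundary_prob=np.zeros_like(H),
            expected_crossovers=np.zeros(len(H)), barcodes=truth.barcodes,
            grid=truth.grid,
        )
        out = finemap_hotspot(
            adata, field, qc, peaks,
            hotspot=("chr1", (hotspot_bin + 0.5) * 25_000),
        )
        pk = out["peak"]
        assert pk["chrom"] == "chr1"
        assert pk["ci_lo"] <= (hotspot_bin + 0.5) * 25_000 <= pk["ci_hi"]
        assert pk["lod"] > 3

    def test_insufficient_nuclei_rejected(self):
        config = SimConfig(
            chromosome_lengths={"chr1": 5_000_000}, n_nuclei=60, seed=3, n_genes=20
        )
        truth = simulate_truth_haplotypes(config)
        adata = preprocess_expression(simulate_expression(truth, config))
        qc = pd.DataFrame(
            {
                "barcode": truth.barcodes,
                "classifier_prob": 0.0,  # nobody passes
                "doublet_prob": 0.0,
                "log10_markers": 3.0,
            }
        )
        from gametiq.rhmm import HaplotypeField

        H = truth.haplotype.astype(float)
        field = HaplotypeField(
            posterior=H, viterbi=truth.haplotype, boundary_prob=np.zeros_like(H),
            expected_crossovers=np.zeros(len(H)), barcodes=truth.barcodes,
            grid=truth.grid,
        )
        with pytest.raises(ValueError, match="nuclei"):
            finemap_hotspot(adata, field, qc, pd.DataFrame(columns=["gene", "chrom", "bin", "position", "lod", "ci_lo", "ci_hi", "celltype", "class"]), hotspot=("chr1", 1_000_000))
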