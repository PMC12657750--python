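import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dipaseq import (
    SimConfig,
    classify_volcano,
    filter_genes,
    make_design,
    normalize_log2,
    pca_summary,
    simulate_counts,
    size_factors,
    test_contrast,
)


def em_from(counts, samples=None):
    return normalize_log2(counts, size_factors(counts))


class TestFilterGenes:
    def test_zero_threshold_is_identity(self, random_counts):
        pd.testing.assert_frame_equal(filter_genes(random_counts, 0), random_counts)

    def test_threshold_boundary(self):
        counts = pd.DataFrame(
            [[0, 0], [4, 5], [5, 5]],
            index=pd.Index(["a", "b", "c"], name="gene_id"),
            columns=["s1", "s2"],
        )
        kept = filter_genes(counts, 10)
        assert list(kept.index) == ["c"]

    def test_matches_bruteforce_row_scan(self, random_counts):
        kept = filter_genes(random_counts, 300)
        expected = [g for g in random_counts.index if random_counts.loc[g].sum() >= 300]
        assert list(kept.index) == expected

    def test_empty_result_warns(self, random_counts):
        with pytest.warns(UserWarning):
            filter_genes(random_counts, 10**9)


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 5], "s2": [10, 20, 5]})
        np.testing.assert_allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_sample_forced_ratios(self):
        # gene rows (10, 20) and (20, 40): factors are 1/sqrt(2) and sqrt(2)
        counts = pd.DataFrame({"A": [10, 20], "B": [20, 40]})
        np.testing.assert_allclose(size_factors(counts), [2**-0.5, 2**0.5], rtol=1e-12)

    def test_matches_per_gene_loop_oracle(self, random_counts):
        mat = random_counts.to_numpy(dtype=float)
        ref_rows = [i for i in range(mat.shape[0]) if (mat[i] > 0).all()]
        expected = []
        for j in range(mat.shape[1]):
            ratios = []
            for i in ref_rows:
                geomean = np.exp(np.mean([np.log(v) for v in mat[i]]))
                ratios.append(mat[i, j] / geomean)
            expected.append(np.median(ratios))
        np.testing.assert_allclose(size_factors(random_counts), expected, rtol=1e-10)

    def test_fallback_to_totals_when_no_reference_gene(self):
        counts = pd.DataFrame({"s1": [0, 10], "s2": [10, 0]})
        with pytest.warns(UserWarning, match="total-count"):
            factors = size_factors(counts)
        np.testing.assert_allclose(factors, [1.0, 1.0])


class TestNormalizeLog2:
    def test_known_values(self):
        counts = pd.DataFrame({"s": [0, 7]})
        em = normalize_log2(counts, pd.Series([1.0], index=["s"]))
        np.testing.assert_allclose(em["s"], [0.0, 3.0])

    def test_doubling_counts_and_factors_is_invariant(self, random_counts):
        f = size_factors(random_counts)
        a = normalize_log2(random_counts, f)
        b = normalize_log2(random_counts * 2, f * 2)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_nonpositive_factor_or_pseudocount(self, random_counts):
        bad = pd.Series(0.0, index=random_counts.columns)
        with pytest.raises(ValueError):
            normalize_log2(random_counts, bad)
        with pytest.raises(ValueError):
            normalize_log2(random_counts, size_factors(random_counts), pseudocount=0)


class TestTestContrast:
    @pytest.fixture(scope="class")
    def stage1(self):
        design = make_design(["S1"], n_per_group=5)
        counts, _ = simulate_counts(design, SimConfig(n_genes=200, seed=21))
        em = normalize_log2(counts, size_factors(counts))
        return em, design

    def test_antisymmetry(self, stage1):
        em, design = stage1
        ab = test_contrast(em, design, "SHAM_VEH", "BDL_VEH")
        ba = test_contrast(em, design, "BDL_VEH", "SHAM_VEH")
        np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"])
        np.testing.assert_allclose(ab["p_raw"], ba["p_raw"])

    def test_bh_properties(self, stage1):
        em, design = stage1
        cr = test_contrast(em, design, "SHAM_VEH", "BDL_VEH")
        assert (cr["p_adj"] >= cr["p_raw"] - 1e-15).all()
        assert (cr["p_adj"] <= 1.0).all()
        ordered = cr.sort_values("p_raw")["p_adj"].to_numpy()
        assert (np.diff(ordered) >= -1e-12).all()

    def test_matches_per_gene_scipy_oracle(self, stage1):
        em, design = stage1
        cr = test_contrast(em, design, "SHAM_VEH", "BDL_VEH")
        ids_a = design.loc[design["arm"] == "SHAM_VEH", "sample_id"]
        ids_b = design.loc[design["arm"] == "BDL_VEH", "sample_id"]
        for gene in em.index[:40]:
            a = em.loc[gene, ids_a].to_numpy()
            b = em.loc[gene, ids_b].to_numpy()
            _, p = stats.ttest_ind(b, a, equal_var=False)
            assert cr.loc[gene, "p_raw"] == pytest.approx(p, rel=1e-10)
            assert cr.loc[gene, "log2fc"] == pytest.approx(b.mean() - a.mean(), rel=1e-10)

    def test_zero_variance_handling(self):
        design = make_design(["S1"], ["SHAM_VEH", "BDL_VEH"], n_per_group=2)
        ids = design["sample_id"].tolist()
        em = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0], [1.0, 1.0, 2.0, 2.0], [1.0, 1.2, 1.1, 1.4]],
            index=pd.Index(["flat", "shifted", "noisy"], name="gene_id"),
            columns=ids,
        )
        cr = test_contrast(em, design, "SHAM_VEH", "BDL_VEH")
        assert cr.loc["flat", "p_raw"] == 1.0
        assert cr.loc["shifted", "p_raw"] == np.finfo(float).tiny
        assert 0 < cr.loc["noisy", "p_raw"] <= 1

    def test_errors(self, stage1):
        em, design = stage1
        with pytest.raises(ValueError, match="unknown group"):
            test_contrast(em, design, "SHAM_VEH", "NOT_A_GROUP")
        with pytest.raises(ValueError, match=">= 2 samples"):
            test_contrast(em, design, "SHAM_VEH", "BDL_VEH", stage="S2")

    def test_power_on_strong_effects(self):
        """Genes with a true 3-log2 shift and low dispersion are detected
        (BH-adjusted p < 0.05) in >= 95% of simulations at n = 5."""
        design = make_design(["S1"], n_per_group=5)
        hits = total = 0
        for seed in range(100):
            cfg = SimConfig(
                n_genes=40,
                dispersion=0.01,
                archetype_fractions={"REFRACTORY": 0.5, "NULL": 0.5},
                bdl_effect_log2_range=(3.0, 3.0),
                seed=seed,
            )
            counts, truth = simulate_counts(design, cfg)
            em = normalize_log2(counts, size_factors(counts))
            cr = test_contrast(em, design, "SHAM_VEH", "BDL_VEH")
            strong = truth.set_index("gene_id").loc[cr.index]
            strong = strong[strong["archetype"] == "REFRACTORY"]
            hits += (cr.loc[strong.index, "p_adj"] < 0.05).sum()
            total += len(strong)
        assert hits / total >= 0.95


class TestClassifyVolcano:
    @pytest.mark.parametrize(
        "log2fc,p_adj,expected",
        [
            (0.5, 0.01, "ns"),  # inside the 1.5-fold band
            (1.0, 0.01, "up"),
            (-2.0, 0.2, "ns"),  # fails alpha
            (-1.0, 0.01, "down"),
            (np.log2(1.5), 0.04, "up"),  # threshold itself counts
        ],
    )
    def test_rule(self, log2fc, p_adj, expected):
        cr = pd.DataFrame({"log2fc": [log2fc], "p_raw": [p_adj], "p_adj": [p_adj]})
        labels, _ = classify_volcano(cr)
        assert labels.iloc[0] == expected

    def test_counts_partition_genes(self, random_counts):
        rng = np.random.default_rng(5)
        n = 200
        cr = pd.DataFrame(
            {"log2fc": rng.normal(0, 2, n), "p_raw": rng.random(n), "p_adj": rng.random(n)}
        )
        labels, summary = classify_volcano(cr)
        assert summary.n_up + summary.n_down + summary.n_ns == n
        assert set(labels.unique()) <= {"up", "down", "ns"}

    def test_invalid_thresholds(self):
        cr = pd.DataFrame({"log2fc": [0.0], "p_raw": [0.5], "p_adj": [0.5]})
        with pytest.raises(ValueError):
            classify_volcano(cr, tau=0)
        with pytest.raises(ValueError):
            classify_volcano(cr, alpha=1.5)


class TestPcaSummary:
    def test_duplicated_profiles_coincide(self):
        rng = np.random.default_rng(0)
        base = rng.normal(5, 1, size=(30, 3))
        em = pd.DataFrame(
            np.hstack([base, base[:, :1]]),
            columns=["s1", "s2", "s3", "s1_dup"],
        )
        coords, evr = pca_summary(em, n_top_variance_genes=30)
        np.testing.assert_allclose(coords.loc["s1"], coords.loc["s1_dup"], atol=1e-8)
        assert evr.sum() <= 1.0 + 1e-9
        assert (np.diff(evr) <= 1e-12).all()

    def test_clamps_n_top_with_warning(self):
        rng = np.random.default_rng(1)
        em = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        with pytest.warns(UserWarning, match="clamping"):
            pca_summary(em, n_top_variance_genes=100)

    def test_disease_separates_from_sham_on_pc1(self):
        from sklearn.metrics import silhouette_score

        design = make_design(["S1"], n_per_group=5)
        cfg = SimConfig(n_genes=400, bdl_effect_log2_range=(2.0, 4.0), seed=2)
        counts, _ = simulate_counts(design, cfg)
        em = normalize_log2(counts, size_factors(counts))
        coords, _ = pca_summary(em)
        sub = design[design["arm"].isin(["SHAM_VEH", "BDL_VEH"])]
        x = coords.loc[sub["sample_id"], ["PC1"]].to_numpy()
        assert silhouette_score(x, sub["arm"]) > 0
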