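import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gensem.screen import (
    ScreenConfig,
    bonferroni_threshold,
    collapse_rare,
    compute_maf,
    confusion_counts,
    full_design,
    identify_pigs,
    ols_regression,
    pca_genotypes,
    scan,
)
from gensem.simulate import GeneConfig, PopulationConfig, simulate_genotypes


class TestMaf:
    def test_monomorphic(self):
        assert compute_maf(np.array([0, 0, 0, 0])) == 0.0

    def test_four_minor_alleles_in_ten(self):
        assert compute_maf(np.array([0, 1, 2, 0, 1])) == pytest.approx(0.4)

    def test_common_rare_boundary(self):
        # a MAF of 0.0667 is common at the 0.05 threshold, 0.028 is rare
        n = 1500
        col = np.zeros(n, dtype=int)
        col[: int(0.0667 * 2 * n) // 1] = 0  # build via allele counts below
        carriers = round(0.0667 * 2 * n)
        col = np.array([1] * carriers + [0] * (2 * n - carriers))[:n]
        maf = compute_maf(col)
        assert (maf >= 0.05) == (col.mean() / 2 >= 0.05)

    @given(st.lists(st.integers(0, 2), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=100)
    def test_maf_always_in_range(self, values):
        maf = compute_maf(np.array(values))
        assert 0.0 <= maf <= 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_maf(np.array([]))


class TestPca:
    def test_identical_rows_give_constant_scores(self):
        X = np.tile(np.array([0, 1, 2, 1, 0]), (10, 1))
        scores = pca_genotypes(X, 2)
        assert np.allclose(scores, 0.0)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, size=(10, 5)).astype(float)
        scores = pca_genotypes(X, 3)
        Xc = X - X.mean(axis=0)
        w, V = np.linalg.eigh(np.cov(Xc, rowvar=False, ddof=1))
        order = np.argsort(w)[::-1]
        expected = Xc @ V[:, order[:3]]
        for j in range(3):
            e = expected[:, j]
            s = scores[:, j]
            assert np.allclose(s, e, atol=1e-8) or np.allclose(s, -e, atol=1e-8)

    def test_pc1_separates_two_populations(self):
        genes = [
            GeneConfig(f"G{k}", tuple(f"G{k}_s{i}" for i in range(10)),
                       tuple([0.3] * 10))
            for k in range(20)
        ]
        pops = PopulationConfig(sizes=(200, 200), differentiation=0.1)
        geno = simulate_genotypes(pops, genes, seed=17)
        pcs = pca_genotypes(geno, 2)
        corr = np.corrcoef(pcs[:, 0], geno.populations)[0, 1]
        assert abs(corr) > 0.9

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            pca_genotypes(np.zeros((5, 3)) + np.arange(3), 3)


class TestOls:
    def test_exact_fit_flagged_degenerate(self):
        g = np.array([0, 1, 2, 0, 1, 2, 1, 0], dtype=float)
        y = 2.0 * g + 3.0
        res = ols_regression(y, g)
        assert res.degenerate
        assert res.beta == pytest.approx(2.0, abs=1e-10)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, 8).astype(float)
        c = rng.standard_normal(8)
        y = 0.5 * g + 0.3 * c + rng.standard_normal(8)
        res = ols_regression(y, g, c[:, None])
        X = np.column_stack([np.ones(8), g, c])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (8 - 3)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.beta == pytest.approx(beta[1], abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)

    def test_collinear_design_named(self):
        g = np.array([0.0, 1, 2, 0, 1, 2])
        with pytest.raises(ValueError, match="collinear"):
            ols_regression(np.arange(6.0), g, np.column_stack([g, g * 2]))


class TestCollapse:
    def test_carrier_oracle(self, toy_genotypes):
        design = collapse_rare(toy_genotypes, rare_maf_threshold=0.2)
        mafs = toy_genotypes.mafs()
        rare = [s for s in toy_genotypes.snp_ids if mafs[s] < 0.2]
        assert rare == ["rareA", "rareB"]
        cid = "G1__rare"
        j = design.column_ids.index(cid)
        # brute-force per-individual scan
        for i in range(toy_genotypes.n_individuals):
            carrier = any(toy_genotypes.column(s)[i] > 0 for s in rare)
            assert design.columns[i, j] == (1.0 if carrier else 0.0)
        # common SNPs pass through unchanged
        for s in ("comA", "comB"):
            k = design.column_ids.index(s)
            assert np.array_equal(design.columns[:, k], toy_genotypes.column(s))
        # G2 has no rare SNPs -> no collapsed column for it
        assert "G2__rare" not in design.column_ids

    def test_homozygous_rare_is_carrier(self, toy_genotypes):
        design = collapse_rare(toy_genotypes, rare_maf_threshold=0.2)
        j = design.column_ids.index("G1__rare")
        assert design.columns[4, j] == 1.0  # individual 4 has rareA == 2

    def test_count_coding(self, toy_genotypes):
        design = collapse_rare(toy_genotypes, rare_maf_threshold=0.2, coding="count")
        j = design.column_ids.index("G1__rare")
        expected = toy_genotypes.column("rareA") + toy_genotypes.column("rareB")
        assert np.array_equal(design.columns[:, j], expected.astype(float))

    def test_indicator_is_binary(self, small_study):
        design = collapse_rare(small_study.genotypes, rare_maf_threshold=0.3)
        for cid in design.collapsed:
            col = design.columns[:, design.column_ids.index(cid)]
            assert set(np.unique(col)) <= {0.0, 1.0}


class TestBonferroni:
    def test_printed_thresholds(self):
        # 24,487 SNPs at alpha 0.05 and a 6,000-test configuration
        assert f"{bonferroni_threshold(24487, 0.05):.3g}" == "2.04e-06"
        assert f"{bonferroni_threshold(6000, 0.05):.3g}" == "8.33e-06"

    def test_single_test(self):
        assert bonferroni_threshold(1, 0.05) == 0.05

    @given(st.integers(1, 10**6), st.floats(1e-6, 0.999))
    @settings(deadline=None, max_examples=100)
    def test_exactly_alpha_over_n(self, n, alpha):
        assert bonferroni_threshold(n, alpha) == alpha / n

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0, 0.05)


class TestScan:
    def test_empty_input(self, small_study):
        geno = small_study.genotypes
        design = full_design(geno)
        design.columns = design.columns[:, :0]
        design.column_ids = []
        cfg = ScreenConfig(covariate_sets={"crude": ()})
        out = scan(design, small_study.phenotypes[0], cfg)
        assert out.empty

    def test_each_row_matches_standalone_regression(self, small_study):
        geno = small_study.genotypes
        ph = small_study.phenotypes[0]
        cfg = ScreenConfig(covariate_sets={"adj": ("Age", "Sex")}, collapse=False)
        out = scan(geno, ph, cfg)
        y = ph["Q1"].to_numpy()
        C = ph[["Age", "Sex"]].to_numpy(dtype=float)
        for _, row in out.iterrows():
            res = ols_regression(y, geno.column(row["snp_id"]).astype(float), C)
            assert row["beta"] == pytest.approx(res.beta, rel=1e-10)
            assert row["p"] == pytest.approx(res.p_value, rel=1e-10)

    def test_id_mismatch_reported(self, small_study):
        ph = small_study.phenotypes[0].copy()
        ph.loc[0, "IID"] = "WRONG"
        cfg = ScreenConfig(covariate_sets={"crude": ()})
        with pytest.raises(ValueError, match="mismatch"):
            scan(small_study.genotypes, ph, cfg)

    def test_collapsing_independent_of_covariate_sets(self, small_study):
        # PC adjustment must not leak into MAF or collapsing decisions
        geno = small_study.genotypes
        d1 = collapse_rare(geno, 0.05)
        d2 = collapse_rare(geno, 0.05)
        assert d1.column_ids == d2.column_ids
        assert np.array_equal(d1.columns, d2.columns)


class TestPigsAndConfusion:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["model_tag", "snp_id", "gene", "beta", "se", "p"])

    def test_no_hits_empty(self):
        res = self._results([("m", "s1", "G1", 1, 1, 0.5)])
        assert identify_pigs(res, 1e-6) == set()

    def test_single_qualifying_snp(self):
        res = self._results([("m", "s1", "G1", 1, 1, 1e-8), ("m", "s2", "G2", 1, 1, 0.2)])
        assert identify_pigs(res, 1e-6) == {"G1"}

    def test_matches_exhaustive_filter(self):
        rng = np.random.default_rng(0)
        rows = [("m", f"s{i}", f"G{i % 5}", 0, 1, rng.uniform()) for i in range(50)]
        res = self._results(rows)
        thr = 0.3
        expected = {g for _, _, g, _, _, p in rows if p <= thr}
        assert identify_pigs(res, thr) == expected

    def test_confusion_perfect_and_empty(self):
        causal = {"A", "B", "C"}
        cc = confusion_counts([causal, set()], causal)
        assert cc.per_replicate.loc[0].tolist() == [3, 0, 0]
        assert cc.per_replicate.loc[1].tolist() == [0, 0, 3]

    def test_summary_matches_hand_enumeration(self):
        causal = {"A", "B"}
        pigs = [{"A"}, {"A", "B"}, {"C"}, set(), {"A", "C", "D"}]
        cc = confusion_counts(pigs, causal)
        tp = [1, 2, 0, 0, 1]
        fp = [0, 0, 1, 0, 2]
        fn = [1, 0, 2, 2, 1]
        s = cc.summary()
        assert s.loc["mean", "TP"] == pytest.approx(np.mean(tp))
        assert s.loc["sd", "FP"] == pytest.approx(np.std(fp, ddof=1))
        assert s.loc["max", "FN"] == max(fn)

    def test_tp_plus_fn_equals_causal_count(self):
        causal = {"A", "B", "C", "D"}
        rng = np.random.default_rng(1)
        pigs = [set(rng.choice(list("ABCDEFG"), size=rng.integers(0, 6), replace=False))
                for _ in range(20)]
        cc = confusion_counts(pigs, causal)
        assert ((cc.per_replicate["TP"] + cc.per_replicate["FN"]) == 4).all()
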