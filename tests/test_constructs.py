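import numpy as np
import pandas as pd
import pytest

from gensem.constructs import (
    ConstructConfig,
    assemble_model,
    construct_report,
    cronbach_alpha,
    cronbach_alpha_from_cov,
    eigen_screen,
    ld_r2,
    ld_r2_table,
    select_snps,
)
from gensem.sem import parse_model_spec


class TestCronbach:
    def test_perfectly_correlated_items(self):
        x = np.arange(10.0)
        assert cronbach_alpha(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_uncorrelated_items_zero(self):
        cov = np.diag([1.0, 2.0, 0.5])
        assert cronbach_alpha_from_cov(cov) == pytest.approx(0.0)

    def test_three_item_hand_formula(self):
        cov = np.array([[1.0, 0.3, 0.2], [0.3, 1.5, 0.4], [0.2, 0.4, 0.8]])
        k = 3
        expected = (k / (k - 1)) * (1 - np.trace(cov) / cov.sum())
        assert cronbach_alpha_from_cov(cov) == pytest.approx(expected)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((10, 1)))
        with pytest.raises(ValueError):
            cronbach_alpha_from_cov(np.zeros((2, 2)))


class TestLd:
    def test_snp_with_itself(self):
        g = np.array([0, 1, 2, 1, 0, 2])
        assert ld_r2(g, g) == pytest.approx(1.0)

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(2)
        g1 = rng.binomial(2, 0.3, 10_000)
        g2 = rng.binomial(2, 0.3, 10_000)
        assert ld_r2(g1, g2) < 0.01

    def test_matches_direct_correlation(self):
        rng = np.random.default_rng(3)
        g1 = rng.binomial(2, 0.3, 200)
        g2 = g1.copy()
        g2[0] = 2 - g2[0]  # one flipped entry
        assert ld_r2(g1, g2) == pytest.approx(np.corrcoef(g1, g2)[0, 1] ** 2)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            ld_r2(np.zeros(10), np.ones(10))


class TestEigenScreen:
    def test_uncorrelated_pair(self):
        rng = np.random.default_rng(4)
        X = rng.binomial(2, 0.4, (20_000, 2))
        vals = eigen_screen(X)
        assert np.allclose(vals, [1.0, 1.0], atol=0.05)
        assert vals.sum() == pytest.approx(2.0)

    def test_perfectly_correlated_pair(self):
        x = np.array([0, 1, 2, 1, 0, 2, 1, 0])
        vals = eigen_screen(np.column_stack([x, x]))
        assert vals == pytest.approx([2.0, 0.0], abs=1e-10)

    def test_matches_dense_eigensolver(self):
        rng = np.random.default_rng(5)
        X = rng.binomial(2, 0.3, (100, 5)).astype(float)
        vals = eigen_screen(X)
        expected = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
        assert np.allclose(vals, expected, atol=1e-10)
        assert (np.diff(vals) <= 1e-12).all()  # non-increasing

    def test_monomorphic_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        X = np.column_stack([np.zeros(50), rng.binomial(2, 0.4, 50),
                             rng.binomial(2, 0.4, 50)])
        with pytest.warns(UserWarning, match="monomorphic"):
            vals = eigen_screen(X)
        assert vals.size == 2


def _assoc(rows):
    return pd.DataFrame(rows, columns=["model_tag", "snp_id", "gene", "beta", "se", "p"])


class TestSelectSnps:
    def test_single_snp_gene(self):
        res = _assoc([("m", "s1", "G", 1, 1, 0.5)])
        ld = pd.DataFrame([[1.0]], index=["s1"], columns=["s1"])
        assert select_snps("G", res, ld) == ["s1"]

    def test_perfectly_correlated_pair_pruned_to_smaller_p(self):
        res = _assoc([("m", "s1", "G", 1, 1, 0.2), ("m", "s2", "G", 1, 1, 0.01)])
        ld = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=["s1", "s2"], columns=["s1", "s2"])
        assert select_snps("G", res, ld) == ["s2"]

    def test_matches_exhaustive_greedy_enumeration(self):
        rng = np.random.default_rng(7)
        snps = [f"s{i}" for i in range(8)]
        ps = rng.uniform(size=8)
        R = rng.uniform(0, 1, (8, 8))
        R = (R + R.T) / 2
        np.fill_diagonal(R, 1.0)
        ld = pd.DataFrame(R, index=snps, columns=snps)
        res = _assoc([("m", s, "G", 1, 1, p) for s, p in zip(snps, ps)])
        cfg = ConstructConfig(max_indicators=4, r2_threshold=0.5)
        got = select_snps("G", res, ld, cfg)
        # brute-force greedy re-implementation
        order = [s for _, s in sorted(zip(ps, snps))]
        kept = []
        for s in order:
            if len(kept) == 4:
                break
            if all(ld.loc[s, k] <= 0.5 for k in kept):
                kept.append(s)
        assert got == kept

    def test_deterministic_under_permutation(self):
        snps = ["b", "a", "c"]
        res = _assoc([("m", s, "G", 1, 1, 0.5) for s in snps])  # all ties
        ld = pd.DataFrame(np.eye(3), index=snps, columns=snps)
        got1 = select_snps("G", res, ld)
        got2 = select_snps("G", res.iloc[::-1].reset_index(drop=True), ld)
        assert got1 == got2 == ["a", "b", "c"]  # tie-break by SNP id


class TestAssemble:
    def test_single_gene_template(self):
        text = assemble_model({"G": ["s1", "s2", "s3"]})
        assert text == "latent G = s1 + s2 + s3\npath G -> Q1\n"

    def test_parameter_count_with_inter_gene_paths(self):
        constructs = {f"G{i}": [f"g{i}s1", f"g{i}s2", f"g{i}s3"] for i in range(9)}
        text = assemble_model(constructs, covariates=("Age", "Sex"),
                              inter_gene_paths=[("G0", "G1")])
        spec = parse_model_spec(text)
        free = sum(p.free for p in spec.parameters())
        # loadings 18; theta 27; psi: 9 latent + Q1 = 10; exogenous latent
        # covariances C(8,2)=28 (G1 is endogenous); paths 9 + 2 + 1 = 12;
        # phi 2 var + 1 cov = 3
        assert free == 18 + 27 + 10 + 28 + 12 + 3

    def test_round_trip_fixed_point(self):
        text = assemble_model({"G1": ["a", "b"], "G2": ["c", "d"]},
                              covariates=("Age",))
        again = parse_model_spec(text).to_text()
        assert parse_model_spec(again).to_text() == again

    def test_name_collision_rejected(self):
        with pytest.raises(ValueError, match="collision"):
            assemble_model({"G": ["Age", "s2"]}, covariates=("Age",))

    def test_unknown_inter_gene_path_rejected(self):
        with pytest.raises(ValueError, match="unknown gene"):
            assemble_model({"G": ["a", "b"]}, inter_gene_paths=[("G", "NOPE")])


def test_construct_report_round_trip(small_study):
    geno = small_study.genotypes
    report = construct_report("CAUS", geno, ["c1", "c2", "c3"])
    assert report.eigenvalues.sum() == pytest.approx(3.0)
    assert 0 < report.cronbach_alpha <= 1.0
    assert report.ld_r2.shape == (3, 3)
    assert "cronbach_alpha" in report.to_text()
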