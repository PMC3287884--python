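import numpy as np
import pandas as pd
import pytest

from gensem.sem import (
    SemModel,
    classify_fit,
    fit_indices,
    fit_ml,
    parse_model_spec,
    simulate_data,
)
from gensem.sem.fit import _duplication, _vech, _vech_pairs

SATURATED = "path x1 -> Y\npath x2 -> Y\n"


class TestSaturated:
    def test_saturated_model_fits_perfectly(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((3, 6))
        S = A @ A.T / 6 + 0.5 * np.eye(3)
        fit = fit_ml(spec=SATURATED, sample_cov=S, n=200)
        assert fit.df == 0
        assert fit.T == pytest.approx(0.0, abs=1e-8)
        assert np.abs(fit.Sigma_hat - S).max() < 1e-8
        idx = fit.indices
        assert idx["cfi"] == 1.0
        assert idx["srmr"] == pytest.approx(0.0, abs=1e-8)
        assert np.isnan(idx["rmsea"])  # undefined at df = 0


class TestClosedFormCfa:
    def test_just_identified_three_indicator_solution(self, one_factor_data):
        S = np.cov(one_factor_data.to_numpy(), rowvar=False, ddof=1)
        fit = fit_ml(spec="latent F = y1 + y2 + y3", sample_cov=S, n=800)
        s12, s13, s23 = S[0, 1], S[0, 2], S[1, 2]
        phi = s12 * s13 / s23
        expected = {
            "F->y2": s23 / s13,
            "F->y3": s23 / s12,
            "var(F)": phi,
            "var(y1)": S[0, 0] - phi,
            "var(y2)": S[1, 1] - (s23 / s13) ** 2 * phi,
            "var(y3)": S[2, 2] - (s23 / s12) ** 2 * phi,
        }
        values = fit.param_values()
        for label, v in expected.items():
            assert values[label] == pytest.approx(v, abs=1e-8), label
        assert fit.df == 0 and fit.T == pytest.approx(0.0, abs=1e-8)

    def test_estimates_recover_generating_values(self, one_factor_data):
        fit = fit_ml(one_factor_data, "latent F = y1 + y2 + y3", robust=False)
        truth = {"F->y2": 0.8, "F->y3": 0.6, "var(F)": 1.0,
                 "var(y1)": 0.5, "var(y2)": 0.4, "var(y3)": 0.3}
        tab = fit.params.set_index("label")
        for label, v in truth.items():
            row = tab.loc[label]
            assert abs(row["estimate"] - v) < 4 * row["se"], label


class TestIndices:
    def test_rmsea_closed_form(self):
        idx = fit_indices(T=50.0, df=20, baseline_T=500.0, baseline_df=28, n=101)
        assert idx["rmsea"] == pytest.approx(np.sqrt(30 / 2000))

    def test_perfect_fit(self):
        idx = fit_indices(T=0.0, df=5, baseline_T=100.0, baseline_df=10, n=50)
        assert idx["cfi"] == 1.0 and idx["rmsea"] == 0.0

    def test_classification_thresholds(self):
        assert classify_fit({"cfi": 0.96, "rmsea": 0.02, "srmr": 0.05}) == {
            "cfi": "good", "rmsea": "good", "srmr": "good"}
        assert classify_fit({"cfi": 0.90})["cfi"] == "acceptable"
        assert classify_fit({"cfi": 0.50, "rmsea": 0.30, "srmr": 0.30}) == {
            "cfi": "poor", "rmsea": "poor", "srmr": "poor"}
        assert classify_fit({"rmsea": 0.10})["rmsea"] == "acceptable"
        assert classify_fit({"srmr": 0.09})["srmr"] == "acceptable"


class TestStandardized:
    def test_single_predictor_path_is_correlation(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(2000)
        y = 0.6 * x + rng.standard_normal(2000)
        data = pd.DataFrame({"X": x, "Y": y})
        fit = fit_ml(data, "path X -> Y", robust=False)
        r = np.corrcoef(x, y)[0, 1]
        std = fit.standardized()
        assert std["X->Y"] == pytest.approx(r, abs=1e-8)

    def test_r_squared_identity(self, one_factor_data):
        data = one_factor_data.copy()
        rng = np.random.default_rng(4)
        data["Q1"] = 0.4 * data["y1"] + rng.standard_normal(len(data))
        fit = fit_ml(data, "latent F = y1 + y2 + y3\npath F -> Q1", robust=False)
        std_dist = fit.params.set_index("label").loc["var(Q1)", "std_estimate"]
        assert fit.rsquare["Q1"] == pytest.approx(1 - std_dist, abs=1e-10)

    def test_permuting_data_columns_changes_nothing(self, one_factor_data):
        data = one_factor_data
        fit1 = fit_ml(data, "latent F = y1 + y2 + y3", robust=False)
        fit2 = fit_ml(data[["y3", "y1", "y2"]], "latent F = y1 + y2 + y3", robust=False)
        pd.testing.assert_frame_equal(fit1.params, fit2.params)
        assert fit1.indices["cfi"] == fit2.indices["cfi"]
        assert fit1.indices["srmr"] == fit2.indices["srmr"]


class TestDiagnostics:
    def test_overparameterized_model_rejected(self):
        S = np.eye(2) + 0.3 * (np.ones((2, 2)) - np.eye(2))
        with pytest.raises(ValueError, match="free parameters"):
            fit_ml(spec="latent F = y1 + y2", sample_cov=S, n=100)

    def test_heywood_case_flagged_inadmissible(self):
        # implied communality of y1 exceeds its variance: the residual
        # variance is driven to the boundary and the fit is flagged
        S = np.array([[1.0, 0.8, 0.8], [0.8, 1.0, 0.4], [0.8, 0.4, 1.0]])
        fit = fit_ml(spec="latent F = y1 + y2 + y3", sample_cov=S, n=200)
        assert not fit.admissible

    def test_non_pd_sample_cov_rejected_then_ridged(self):
        S = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError):
            fit_ml(spec="latent F = y1 + y2 + y3", sample_cov=S, n=50)
        fit = fit_ml(spec="latent F = y1 + y2 + y3", sample_cov=S, n=50, ridge=0.05)
        assert fit.df == 0


class TestRobust:
    def _skewed_data(self, n, seed):
        rng = np.random.default_rng(seed)
        eta = (rng.chisquare(3, n) - 3) / np.sqrt(6)
        lam = np.array([1.0, 0.8, 0.6])
        eps = (rng.chisquare(2, (n, 3)) - 2) / 2 * np.sqrt([0.5, 0.4, 0.3])
        return pd.DataFrame(eta[:, None] * lam + eps, columns=["y1", "y2", "y3"])

    def test_scaling_constant_near_one_under_normality(self):
        model = SemModel(parse_model_spec("latent F = y1 + y2 + y3 + y4"))
        vals = {"F->y2": 0.8, "F->y3": 0.7, "F->y4": 0.6, "var(F)": 1.0,
                "var(y1)": 0.5, "var(y2)": 0.5, "var(y3)": 0.5, "var(y4)": 0.5}
        data = simulate_data(model, vals, 10_000, rng=6)
        fit = fit_ml(data, model.spec, robust=True)
        assert 0.9 <= fit.scaling_c <= 1.1

    def test_scaled_statistic_matches_independent_dense_recomputation(self):
        data = self._skewed_data(1500, 7)
        spec = "latent F = y1 + y2 + y3"
        # over-identify by adding a fourth variable correlated with y1
        rng = np.random.default_rng(8)
        data["y4"] = 0.5 * data["y1"] + rng.standard_normal(1500) * 0.8
        fit = fit_ml(data, "latent F = y1 + y2 + y3 + y4", robust=True)
        assert fit.df > 0
        # independent recomputation: numerical Delta, explicit D and W
        model = fit.model
        p = model.pstar
        pairs = _vech_pairs(p)
        Z = data[model.observed_vars].to_numpy(float)
        Zc = Z - Z.mean(axis=0)
        B = np.column_stack([Zc[:, i] * Zc[:, j] for i, j in pairs])
        Gamma = np.cov(B, rowvar=False, ddof=1)
        Sinv = np.linalg.inv(fit.Sigma_hat)
        D = _duplication(p)
        W = 0.5 * D.T @ np.kron(Sinv, Sinv) @ D
        h = 1e-6
        cols = []
        for k in range(model.n_free):
            tp, tm = fit.theta.copy(), fit.theta.copy()
            tp[k] += h
            tm[k] -= h
            cols.append(_vech(
                (model.implied_covariance(tp) - model.implied_covariance(tm)) / (2 * h)
            ))
        Delta = np.column_stack(cols)
        bread = np.linalg.inv(Delta.T @ W @ Delta)
        U = W - W @ Delta @ bread @ Delta.T @ W
        c = np.trace(U @ Gamma) / fit.df
        assert fit.scaling_c == pytest.approx(c, rel=1e-4)
        assert fit.T_scaled == pytest.approx(fit.T / c, rel=1e-4)

    def test_robust_se_close_to_bootstrap(self):
        data = self._skewed_data(600, 9)
        spec = "latent F = y1 + y2 + y3"
        fit = fit_ml(data, spec, robust=True)
        rng = np.random.default_rng(10)
        labels = ["F->y2", "F->y3"]
        boot = {l: [] for l in labels}
        for _ in range(500):
            idx = rng.integers(0, len(data), len(data))
            bfit = fit_ml(data.iloc[idx], spec, robust=False)
            vals = bfit.param_values()
            for l in labels:
                boot[l].append(vals[l])
        tab = fit.params.set_index("label")
        for l in labels:
            bse = np.std(boot[l], ddof=1)
            assert abs(tab.loc[l, "robust_se"] - bse) / bse < 0.15, l
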