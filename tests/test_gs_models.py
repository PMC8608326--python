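"""Kinships, GBLUP REML, LASSO selection + refit, and model dispatch."""

import numpy as np
import pandas as pd
import pytest

from pgsihet.genotype_io import CodedMarkerMatrix, code_additive, code_dominance
from pgsihet.gs_models import (
    KinshipMatrix,
    ModelInputs,
    additive_kinship,
    build_model,
    dominance_kinship,
    fit_gblup,
    fit_lasso_refit,
    predict_gblup,
    predict_linear,
)

from conftest import make_genotypes


def coded(values, coding="additive"):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return CodedMarkerMatrix(
        values=values,
        coding=coding,
        chrom=np.array(["A01"] * m, dtype=object),
        pos=np.arange(1, m + 1) * 100,
        minor_allele=np.array(["G"] * m, dtype=object),
        samples=[f"I{i}" for i in range(n)],
    )


def window_frame(X, ids=None):
    n, m = X.shape
    cols = [f"A01:{i * 1000}-{(i + 1) * 1000}" for i in range(m)]
    idx = ids if ids is not None else [f"I{i}" for i in range(n)]
    return pd.DataFrame(X, index=idx, columns=cols)


class TestKinship:
    def test_single_marker_two_individuals(self):
        K = additive_kinship(coded([[1.0], [-1.0]]))
        np.testing.assert_allclose(K.values, [[1, -1], [-1, 1]])

    def test_identical_individuals_have_equal_rows(self):
        Z = np.array([[1.0, 0.0, -1.0], [1.0, 0.0, -1.0], [0.0, 1.0, 1.0]])
        K = additive_kinship(coded(Z))
        np.testing.assert_allclose(K.values[0], K.values[1])
        assert K.values[0, 0] == pytest.approx(K.values[0, 1])

    def test_matches_per_marker_loop_oracle(self):
        rng = np.random.default_rng(6)
        Z = rng.choice([-1.0, 0.0, 1.0], size=(6, 20))
        K = additive_kinship(coded(Z))
        expected = np.zeros((6, 6))
        for k in range(20):
            zk = Z[:, k : k + 1]
            expected += zk @ zk.T
        expected /= 20
        np.testing.assert_allclose(K.values, expected, atol=1e-12)

    def test_missing_codes_mean_imputed(self):
        Z = np.array([[1.0, np.nan], [-1.0, 0.5], [0.0, 0.5]])
        K = additive_kinship(coded(Z))
        Zi = Z.copy()
        Zi[0, 1] = 0.5
        np.testing.assert_allclose(K.values, Zi @ Zi.T / 2)

    def test_inbred_population_dominance_kinship_is_zero(self):
        rng = np.random.default_rng(2)
        pop = make_genotypes(rng, n_sites=30, n_samples=6, inbred=True)
        K = dominance_kinship(code_dominance(pop))
        np.testing.assert_allclose(K.values, 0.0, atol=1e-12)

    def test_dominance_loop_oracle(self):
        rng = np.random.default_rng(3)
        pop = make_genotypes(rng, n_sites=30, n_samples=6, inbred=False)
        codes = code_dominance(pop)
        K = dominance_kinship(codes)
        Z = codes.values
        expected = (Z @ Z.T) / Z.shape[1]
        np.testing.assert_allclose(K.values, expected, atol=1e-12)

    def test_coding_mismatch_rejected(self):
        with pytest.raises(ValueError, match="additive"):
            additive_kinship(coded([[0.0], [1.0]], coding="dominance"))


class TestGblup:
    def simulate_gblup(self, seed, n=200, phi2=2.0, sigma2=1.0, m=80):
        rng = np.random.default_rng(seed)
        Z = rng.choice([-1.0, 1.0], size=(n, m))
        K = KinshipMatrix((Z @ Z.T) / m, [f"I{i}" for i in range(n)], "additive", m)
        L = np.linalg.cholesky(K.values + 1e-10 * np.eye(n))
        g = L @ rng.standard_normal(n) * np.sqrt(phi2)
        e = rng.standard_normal(n) * np.sqrt(sigma2)
        return K, g + e

    def test_constant_phenotype_gives_no_genetic_variance(self):
        K, _ = self.simulate_gblup(0, n=40)
        y = np.full(40, 3.5)
        fit = fit_gblup(y, K)
        # with zero residual and genetic variance, phi^2 = lambda * sigma^2 -> 0
        assert fit.variance_components["additive"] == pytest.approx(0.0, abs=1e-10)
        pred = predict_gblup(fit, K.values)
        np.testing.assert_allclose(pred, 3.5, atol=1e-6)

    def test_variance_ratio_recovery_median_within_30pct(self):
        lams = []
        for seed in range(20):
            K, y = self.simulate_gblup(seed)
            fit = fit_gblup(y, K)
            lams.append(fit.lambdas["additive"])
        assert 1.4 <= float(np.median(lams)) <= 2.6

    def test_zero_dominance_variance_recovered_at_boundary(self):
        K, y = self.simulate_gblup(1, n=150)
        rng = np.random.default_rng(99)
        H = rng.random((150, 30)) < 0.5
        D = H - H.mean(axis=0)
        Kd = KinshipMatrix((D @ D.T) / 30, K.individual_ids, "dominance", 30)
        fit = fit_gblup(y, [K, Kd])
        assert fit.variance_components["dominance"] < 0.15 * fit.variance_components["additive"]

    def test_unrelated_test_individual_predicted_by_fixed_part(self):
        K, y = self.simulate_gblup(2, n=50)
        fit = fit_gblup(y, K)
        pred = predict_gblup(fit, np.zeros((1, 50)))
        assert pred[0] == pytest.approx(float(fit.beta[0]))

    def test_duplicate_of_training_individual_predicts_near_twin(self):
        # near-noiseless, high-signal data: a genomic twin's prediction
        # approaches the twin's phenotype
        rng = np.random.default_rng(8)
        n, m = 60, 40
        Z = rng.choice([-1.0, 1.0], size=(n, m))
        u = rng.standard_normal(m) * 0.5
        y = Z @ u + rng.standard_normal(n) * 0.01
        K = KinshipMatrix((Z @ Z.T) / m, [f"I{i}" for i in range(n)], "additive", m)
        fit = fit_gblup(y, K)
        cross = (Z[:1] @ Z.T) / m  # test = copy of individual 0
        pred = predict_gblup(fit, cross)
        assert pred[0] == pytest.approx(y[0], abs=0.05)

    def test_equivalent_to_matched_penalty_ridge(self):
        # RR-BLUP identity: g_hat = Z (Z'Z + (m/lambda) I)^-1 Z' V0^-1-residuals
        rng = np.random.default_rng(4)
        n, m = 30, 50
        Z = rng.choice([-1.0, 0.0, 1.0], size=(n, m))
        y = Z @ (rng.standard_normal(m) * 0.3) + rng.standard_normal(n)
        K = KinshipMatrix((Z @ Z.T) / m, [f"I{i}" for i in range(n)], "additive", m)
        fit = fit_gblup(y, K)
        lam = fit.lambdas["additive"]
        # ridge marker effects with penalty alpha = m / lambda
        alpha = m / lam
        resid = y - fit.beta[0]
        beta_r = np.linalg.solve(Z.T @ Z + alpha * np.eye(m), Z.T @ resid)
        pred_ridge = fit.beta[0] + Z @ beta_r
        pred_gblup = predict_gblup(fit, K.values)
        np.testing.assert_allclose(pred_gblup, pred_ridge, atol=1e-8)

    def test_shift_equivariance(self):
        K, y = self.simulate_gblup(5, n=60)
        f0 = fit_gblup(y, K)
        f1 = fit_gblup(y + 7.0, K)
        p0 = predict_gblup(f0, K.values)
        p1 = predict_gblup(f1, K.values)
        np.testing.assert_allclose(p1, p0 + 7.0, atol=1e-6)

    def test_non_psd_kinship_rejected(self):
        bad = np.array([[1.0, 2.0, 0], [2.0, 1.0, 0], [0, 0, 1.0]])
        bad = KinshipMatrix(np.kron(bad, np.eye(2)), [f"i{k}" for k in range(6)], "additive", 1)
        with pytest.raises(ValueError, match="semidefinite"):
            fit_gblup(np.zeros(6), bad)


class TestLassoRefit:
    def test_constant_y_gives_intercept_only(self):
        rng = np.random.default_rng(0)
        feats = window_frame(rng.normal(size=(20, 5)))
        fit = fit_lasso_refit(feats, np.full(20, 2.0), seed=1)
        assert fit.intercept_only
        assert fit.intercept == pytest.approx(2.0)
        np.testing.assert_allclose(predict_linear(fit, feats), 2.0)

    def test_orthonormal_design_soft_threshold_oracle(self):
        # centered orthogonal columns of unit norm: after the internal
        # standardization X~ = sqrt(n) Q, the lasso solution is
        # soft(Q'y / sqrt(n), alpha)
        rng = np.random.default_rng(3)
        n, p = 64, 8
        M = rng.standard_normal((n, p))
        M -= M.mean(axis=0)
        Q, _ = np.linalg.qr(M)
        Q -= Q.mean(axis=0)  # re-center (QR keeps columns near mean zero)
        Q, _ = np.linalg.qr(Q)
        beta = np.array([3.0, -2.5, 1.5, 0.0, 0.0, 0.0, 0.0, 0.0])
        y = Q @ beta + rng.standard_normal(n) * 0.05
        feats = window_frame(Q)
        fit = fit_lasso_refit(feats, y, seed=7)
        proj = Q.T @ (y - y.mean()) / np.sqrt(n)
        soft = np.sign(proj) * np.clip(np.abs(proj) - fit.alpha, 0.0, None)
        expected_sel = np.flatnonzero(soft != 0)
        np.testing.assert_array_equal(fit.selected, expected_sel)
        # refit equals unpenalized OLS on the selected columns
        A = np.column_stack([np.ones(n), Q[:, fit.selected]])
        ols, *_ = np.linalg.lstsq(A, y, rcond=None)
        refit_orig = fit.coefficients_original_scale().to_numpy()
        np.testing.assert_allclose(refit_orig, ols[1:], atol=1e-5)

    def test_true_support_recovered_with_strong_effects(self):
        hits, coef_ok = 0, 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n, p = 150, 50
            X = rng.standard_normal((n, p))
            y = 2.0 * X[:, 3] - 1.5 * X[:, 27] + rng.standard_normal(n) * 0.3
            fit = fit_lasso_refit(window_frame(X), y, seed=seed)
            sel = set(fit.selected.tolist())
            if {3, 27} <= sel:
                hits += 1
                c = fit.coefficients_original_scale()
                c3 = c[fit.feature_keys[3]]
                c27 = c[fit.feature_keys[27]]
                if abs(c3 - 2.0) < 0.2 and abs(c27 + 1.5) < 0.15:
                    coef_ok += 1
        assert hits >= 29  # >= 95% of seeds
        assert coef_ok >= 27

    def test_selection_invariant_to_positive_feature_rescaling(self):
        rng = np.random.default_rng(12)
        n, p = 60, 10
        X = rng.standard_normal((n, p))
        y = X[:, 1] - 0.8 * X[:, 6] + rng.standard_normal(n) * 0.2
        base = fit_lasso_refit(window_frame(X), y, seed=5)
        X2 = X.copy()
        X2[:, 1] *= 37.0
        X2[:, 6] *= 0.013
        scaled = fit_lasso_refit(window_frame(X2), y, seed=5)
        np.testing.assert_array_equal(base.selected, scaled.selected)

    def test_training_rows_repredict_to_fitted_values(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((40, 6))
        y = X[:, 0] + rng.standard_normal(40) * 0.1
        feats = window_frame(X)
        fit = fit_lasso_refit(feats, y, seed=2)
        Xs = (X - fit.col_means) / fit.col_stds
        fitted = fit.intercept + Xs[:, fit.selected] @ fit.coef
        np.testing.assert_allclose(predict_linear(fit, feats), fitted, atol=1e-12)

    def test_predict_two_feature_hand_arithmetic(self):
        fit_keys = ["A01:0-1000", "A01:1000-2000"]
        from pgsihet.gs_models import LassoFit

        fit = LassoFit(
            feature_keys=fit_keys,
            col_means=np.array([0.5, 0.2]),
            col_stds=np.array([2.0, 0.1]),
            alpha=0.1,
            selected=np.array([0, 1]),
            coef=np.array([3.0, -1.0]),
            intercept=10.0,
            seed=0,
        )
        feats = pd.DataFrame([[1.5, 0.3]], index=["x"], columns=fit_keys)
        # standardized: (1.5-0.5)/2 = 0.5; (0.3-0.2)/0.1 = 1.0
        assert predict_linear(fit, feats)[0] == pytest.approx(10 + 3 * 0.5 - 1.0)

    def test_all_missing_row_predicts_intercept(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 4))
        y = X[:, 0] + rng.standard_normal(30) * 0.1
        feats = window_frame(X)
        fit = fit_lasso_refit(feats, y, seed=3)
        blank = pd.DataFrame([[np.nan] * 4], index=["new"], columns=feats.columns)
        assert predict_linear(fit, blank)[0] == pytest.approx(fit.intercept)

    def test_unknown_feature_keys_rejected(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 4))
        feats = window_frame(X)
        fit = fit_lasso_refit(feats, X[:, 0], seed=3)
        bad = feats.rename(columns={feats.columns[0]: "Z99:0-10"})
        with pytest.raises(KeyError, match="unknown feature"):
            predict_linear(fit, bad)


class TestBuildModel:
    def test_window_lasso_dispatch_keys(self):
        rng = np.random.default_rng(0)
        ids = [f"I{i}" for i in range(30)]
        feats = window_frame(rng.normal(size=(30, 6)), ids=ids)
        y = feats.iloc[:, 0].to_numpy() + rng.normal(0, 0.1, 30)
        inputs = ModelInputs(ids=ids, pgsi_by_width={100_000: feats})
        fit = build_model("LASSO_100Kb", y, inputs, seed=1)
        assert fit.feature_keys == list(feats.columns)

    def test_gblup_ad_without_dominance_is_error(self):
        rng = np.random.default_rng(1)
        ids = [f"I{i}" for i in range(10)]
        codes = coded(rng.choice([-1.0, 1.0], size=(10, 2000)))
        inputs = ModelInputs(ids=codes.samples, marker_codes=codes,
                             snp_subsample_fraction=0.01)
        with pytest.raises(ValueError, match="dominance"):
            build_model("GBLUP_AD", rng.normal(size=10), inputs, seed=0)

    def test_lasso_snp_subsamples_half_permille(self):
        rng = np.random.default_rng(2)
        codes = coded(rng.choice([-1.0, 1.0], size=(20, 10_000)))
        inputs = ModelInputs(ids=codes.samples, marker_codes=codes)
        feats = inputs.snp_features(seed=3)
        assert feats.shape == (20, 5)

    def test_unknown_spec_listed(self):
        with pytest.raises(ValueError, match="GBLUP_A"):
            build_model("LASSO_10Kb", np.zeros(10), ModelInputs(ids=[]), seed=0)
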