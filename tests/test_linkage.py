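"""Tests of the SOC regression, LDA and random-forest linkage analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm as norm_dist

from thermonorm.linkage import (
    ARCHITECTURE_FEATURES,
    fit_soc_model,
    lda_classify,
    link_architecture,
    rf_classify,
)


def _make_tables(n, rng, tf_coef=-3e-3, mir_coef=1.8e-3, noise_sd=0.046, intercept=1.125):
    """SOC^(1/4) generated linearly from TF/miRNA counts (effect sizes and
    intercept on the scale of the fly analysis)."""
    arch = pd.DataFrame(
        {
            "n_tfs": rng.poisson(15.0, n),
            "n_mirnas": rng.poisson(9.5, n),
            "utr5_len": rng.lognormal(5.3, 0.8, n).round(),
            "utr3_len": rng.lognormal(6.1, 0.9, n).round(),
            "intron1_len": rng.lognormal(6.9, 1.2, n).round(),
        },
        index=[f"g{i}" for i in range(n)],
    )
    y4 = (
        intercept
        + tf_coef * arch["n_tfs"]
        + mir_coef * arch["n_mirnas"]
        + rng.normal(0.0, noise_sd, n)
    )
    y4 = np.maximum(y4, 0.0)
    profiles = pd.DataFrame(
        {
            "class_label": rng.choice(["increasing", "decreasing"], n),
            "curvature": rng.choice(["linear", "quadratic"], n),
            "soc": y4**4,
        },
        index=arch.index,
    )
    return profiles, arch


class TestSocModel:
    def test_sign_recovery_at_reported_effect_sizes(self):
        rng = np.random.default_rng(0)
        profiles, arch = _make_tables(5000, rng)
        res = fit_soc_model(profiles, arch)
        assert res.summary.loc["n_tfs", "coefficient"] < 0
        assert res.summary.loc["n_mirnas", "coefficient"] > 0
        assert res.summary.loc["n_tfs", "r2_share"] > res.summary.loc["n_mirnas", "r2_share"]

    def test_null_term_share_near_zero(self):
        rng = np.random.default_rng(1)
        profiles, arch = _make_tables(5000, rng, mir_coef=0.0)
        res = fit_soc_model(profiles, arch, select_aic=False)
        assert res.summary.loc["n_mirnas", "r2_share"] < 0.01

    def test_orthogonal_single_predictor_share_equals_full_r2(self):
        """When the response is exactly orthogonal to every other covariate,
        the TF share equals the full-model R²."""
        rng = np.random.default_rng(2)
        n = 2000
        profiles, arch = _make_tables(n, rng, mir_coef=0.0, noise_sd=0.03)
        y4 = profiles["soc"] ** 0.25
        yc = y4 - y4.mean()
        # orthogonalize the non-TF covariates against [1, y]
        for col in ("n_mirnas", "utr5_len", "utr3_len", "intron1_len"):
            v = arch[col].astype(float)
            arch[col] = v - (v @ yc) / (yc @ yc) * yc - 0.0
        res = fit_soc_model(profiles, arch, select_aic=False)
        assert res.summary.loc["n_tfs", "r2_share"] == pytest.approx(res.r2_full, abs=1e-6)

    def test_shares_nonnegative_and_bounded(self):
        rng = np.random.default_rng(3)
        profiles, arch = _make_tables(3000, rng)
        res = fit_soc_model(profiles, arch)
        shares = res.summary["r2_share"].dropna()
        assert (shares >= -1e-10).all()
        assert (shares <= res.r2_full + 1e-10).all()

    def test_too_few_genes_rejected(self):
        rng = np.random.default_rng(4)
        profiles, arch = _make_tables(8, rng)
        with pytest.raises(ValueError, match="complete-case"):
            fit_soc_model(profiles, arch)

    def test_singular_design_rejected(self):
        rng = np.random.default_rng(5)
        profiles, arch = _make_tables(500, rng)
        arch["utr3_len"] = 2 * arch["utr5_len"]  # exact collinearity
        with pytest.raises(ValueError, match="singular"):
            fit_soc_model(profiles, arch, select_aic=False)

    def test_ub_genes_excluded(self):
        rng = np.random.default_rng(6)
        profiles, arch = _make_tables(1000, rng)
        profiles.iloc[:200, profiles.columns.get_loc("class_label")] = "U"
        res = fit_soc_model(profiles, arch)
        assert res.n_genes == 800


def _two_class_features(rng, n, sep_feature="n_tfs", means=(11.7, 18.2)):
    labels = pd.Series(
        np.where(np.arange(n) % 2 == 0, "decreasing", "increasing"),
        index=[f"g{i}" for i in range(n)],
    )
    arch = pd.DataFrame(
        {
            "n_tfs": rng.poisson(15.0, n).astype(float),
            "n_mirnas": rng.poisson(9.5, n).astype(float),
            "utr5_len": rng.lognormal(5.3, 0.8, n).round(),
            "utr3_len": rng.lognormal(6.1, 0.9, n).round(),
            "intron1_len": rng.lognormal(6.9, 1.2, n).round(),
        },
        index=labels.index,
    )
    if sep_feature:
        arch[sep_feature] = np.where(
            labels == "decreasing", rng.poisson(means[0], n), rng.poisson(means[1], n)
        ).astype(float)
    return labels, arch


class TestLda:
    def test_tf_gap_dominates_discriminant(self):
        """With class-conditional TF means 11.7 vs 18.2 and all other
        features matched, TFs carry the largest standardized coefficient
        and accuracy clearly beats the majority baseline."""
        rng = np.random.default_rng(7)
        labels, arch = _two_class_features(rng, 4000)
        res = lda_classify(labels, arch, seed=1)
        std = res.coefficients_standardized.abs()
        assert std.idxmax() == "n_tfs"
        assert res.holdout_accuracy >= res.baseline_accuracy + 0.10
        assert abs(res.class_means.loc["increasing", "n_tfs"] - 18.2) < 0.5

    def test_identical_classes_at_chance(self):
        rng = np.random.default_rng(8)
        labels, arch = _two_class_features(rng, 2000, sep_feature=None)
        res = lda_classify(labels, arch, seed=2)
        se = np.sqrt(0.25 / res.n_test)
        assert abs(res.holdout_accuracy - res.baseline_accuracy) < 3 * se + 0.02

    def test_separated_gaussians_high_accuracy(self):
        """Mahalanobis distance 4 → Bayes error Φ(−2) ≈ 2.3%."""
        rng = np.random.default_rng(9)
        n = 2000
        labels = pd.Series(
            np.r_[["a"] * (n // 2), ["b"] * (n // 2)], index=[f"g{i}" for i in range(n)]
        )
        X = pd.DataFrame(
            rng.normal(size=(n, 5)), index=labels.index, columns=ARCHITECTURE_FEATURES
        )
        X.loc[labels == "b", "n_tfs"] += 4.0
        res = lda_classify(labels, X, seed=3)
        assert res.holdout_accuracy > 0.95
        assert res.holdout_accuracy <= 1.0 - norm_dist.cdf(-2) / 4

    def test_agreement_with_closed_form_discriminant(self):
        """LDA assignments match the two-Gaussian discriminant
        w = Σ⁻¹(μ₁ − μ₀) on homoscedastic data (>99%)."""
        rng = np.random.default_rng(10)
        n = 3000
        labels = pd.Series(
            rng.choice(["a", "b"], n), index=[f"g{i}" for i in range(n)]
        )
        X = pd.DataFrame(
            rng.normal(size=(n, 5)), index=labels.index, columns=ARCHITECTURE_FEATURES
        )
        X.loc[labels == "b"] += 1.0
        res = lda_classify(labels, X, seed=4)
        mu0 = X[labels == "a"].mean().to_numpy()
        mu1 = X[labels == "b"].mean().to_numpy()
        pooled = np.cov(X[labels == "a"].T) * 0.5 + np.cov(X[labels == "b"].T) * 0.5
        w = np.linalg.solve(pooled, mu1 - mu0)
        thresh = w @ (mu0 + mu1) / 2 + np.log((labels == "a").mean() / (labels == "b").mean())
        closed = np.where(X.to_numpy() @ w > thresh, "b", "a")
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        lda = LinearDiscriminantAnalysis().fit(X.to_numpy(), labels.to_numpy())
        assert (lda.predict(X.to_numpy()) == closed).mean() > 0.99

    def test_single_class_rejected(self):
        rng = np.random.default_rng(11)
        labels, arch = _two_class_features(rng, 200)
        with pytest.raises(ValueError, match="two classes"):
            lda_classify(pd.Series("increasing", index=labels.index), arch)

    def test_zero_variance_feature_dropped_with_warning(self):
        rng = np.random.default_rng(12)
        labels, arch = _two_class_features(rng, 500)
        arch["intron1_len"] = 100.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = lda_classify(labels, arch, seed=5)
        assert "intron1_len" in res.dropped_features
        assert "intron1_len" not in res.coefficients.index

    def test_split_disjoint_exhaustive(self):
        rng = np.random.default_rng(13)
        labels, arch = _two_class_features(rng, 997)
        res = lda_classify(labels, arch, seed=6)
        assert res.n_train + res.n_test == 997
        assert res.n_train == round(0.6 * 997)


class TestRandomForest:
    def test_permuted_labels_at_chance(self):
        rng = np.random.default_rng(14)
        labels, arch = _two_class_features(rng, 1500)
        permuted = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        res = rf_classify(permuted, arch, n_trees=200, seed=7)
        se = np.sqrt(0.25 / res.n_test)
        assert abs(res.holdout_accuracy - res.baseline_accuracy) < 3 * se + 0.02

    def test_importances_positive_when_all_features_inform(self):
        """Labels generated from all five covariates → every permutation
        importance positive."""
        rng = np.random.default_rng(15)
        n = 3000
        arch = pd.DataFrame(
            rng.normal(size=(n, 5)), columns=ARCHITECTURE_FEATURES,
            index=[f"g{i}" for i in range(n)],
        )
        score = arch.to_numpy() @ np.array([1.0, -1.0, 0.8, -0.8, 0.9])
        labels = pd.Series(np.where(score > 0, "up", "down"), index=arch.index)
        res = rf_classify(labels, arch, seed=8)
        assert (res.importances > 0).all()

    def test_seeded_determinism(self):
        rng = np.random.default_rng(16)
        labels, arch = _two_class_features(rng, 800)
        r1 = rf_classify(labels, arch, n_trees=100, seed=9)
        r2 = rf_classify(labels, arch, n_trees=100, seed=9)
        assert r1.holdout_accuracy == r2.holdout_accuracy
        pd.testing.assert_series_equal(r1.importances, r2.importances)

    def test_rf_beats_lda_on_nonlinear_boundary(self):
        """XOR-style class structure: RF captures it, LDA cannot
        (directional comparison over seeds)."""
        rng = np.random.default_rng(17)
        n = 2000
        wins = 0
        for seed in range(5):
            arch = pd.DataFrame(
                rng.normal(size=(n, 5)), columns=ARCHITECTURE_FEATURES,
                index=[f"g{i}" for i in range(n)],
            )
            xor = (arch["n_tfs"] > 0) ^ (arch["n_mirnas"] > 0)
            labels = pd.Series(np.where(xor, "a", "b"), index=arch.index)
            acc_rf = rf_classify(labels, arch, n_trees=200, seed=seed).holdout_accuracy
            acc_lda = lda_classify(labels, arch, seed=seed).holdout_accuracy
            wins += acc_rf > acc_lda
        assert wins >= 4


def test_link_architecture_bundles_all_analyses(linked_run):
    res = linked_run["linkage"]
    assert res.soc_model.n_genes >= 10
    assert 0.0 <= res.direction_lda.holdout_accuracy <= 1.0
    assert res.direction_rf.holdout_accuracy >= res.direction_rf.baseline_accuracy - 0.05
    # generator couples TFs negatively and miRNAs positively to SOC
    assert res.soc_model.summary.loc["n_tfs", "coefficient"] < 0
    assert res.soc_model.summary.loc["n_mirnas", "coefficient"] > 0
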