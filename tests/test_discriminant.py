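"""Fisher discriminant fitting, scoring, confusion counts, separation."""

import numpy as np
import pandas as pd
import pytest

from hrvdx.discriminant import (
    DiscriminantModel,
    classify_cohort,
    d_score,
    fit_lda,
    mahalanobis_separation,
    sensitivity_specificity,
)
from hrvdx.paradigm import FEATURE_NAMES


def gaussian_cohort(mu_a, mu_b, n_a, n_b, seed, labels=("A", "B"), cov=None):
    rng = np.random.default_rng(seed)
    p = len(mu_a)
    L = np.linalg.cholesky(cov) if cov is not None else np.eye(p)
    Xa = np.asarray(mu_a) + rng.normal(size=(n_a, p)) @ L.T
    Xb = np.asarray(mu_b) + rng.normal(size=(n_b, p)) @ L.T
    df = pd.DataFrame(np.vstack([Xa, Xb]), columns=list(FEATURE_NAMES))
    df.insert(0, "group", [labels[0]] * n_a + [labels[1]] * n_b)
    return df


def mean_row(mu, label="A"):
    s = pd.Series(dict(zip(FEATURE_NAMES, mu)))
    s["group"] = label
    return s


class TestFitLda:
    def test_midpoint_cut_on_separated_gaussians(self):
        mu_a = np.zeros(9)
        mu_b = np.zeros(9)
        mu_a[0] = 2.0
        cohort = gaussian_cohort(mu_a, mu_b, 400, 400, seed=0)
        model = fit_lda(cohort, "A", "B")
        # the two true means score symmetrically about the cut
        da = d_score(model, pd.Series(dict(zip(FEATURE_NAMES, mu_a))))
        db = d_score(model, pd.Series(dict(zip(FEATURE_NAMES, mu_b))))
        assert da > 0 > db

    def test_label_swap_negates_scores(self):
        cohort = gaussian_cohort(np.ones(9), np.zeros(9), 50, 60, seed=1)
        m1 = fit_lda(cohort, "A", "B")
        m2 = fit_lda(cohort, "B", "A")
        s1 = d_score(m1, cohort)
        s2 = d_score(m2, cohort)
        np.testing.assert_allclose(s1, -s2, atol=1e-8)

    def test_recovery_at_known_mahalanobis_distance(self):
        # identity covariance, shift 2/3 per feature: Delta = sqrt(9*(2/3)^2) = 2;
        # averaged over replicates to beat the ~1.6% binomial noise of one draw
        mu_a = np.full(9, 2.0 / 3.0)
        rates = []
        for seed in range(5):
            cohort = gaussian_cohort(mu_a, np.zeros(9), 500, 500, seed=seed)
            model = fit_lda(cohort, "A", "B")
            counts = classify_cohort(model, cohort)
            rates.append(sensitivity_specificity(counts, "A", "B"))
        from scipy.stats import norm

        target = 100 * norm.cdf(1.0)  # Phi(Delta/2)
        sens, spec = np.mean(rates, axis=0)
        assert sens == pytest.approx(target, abs=3.0)
        assert spec == pytest.approx(target, abs=3.0)

    def test_direction_recovery_cosine(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(9, 9))
        cov = A @ A.T + 9 * np.eye(9)
        diff = rng.normal(size=9)
        # scale shift so true Mahalanobis distance is 2
        d0 = np.sqrt(diff @ np.linalg.solve(cov, diff))
        diff *= 2.0 / d0
        cohort = gaussian_cohort(diff, np.zeros(9), 2000, 2000, seed=4, cov=cov)
        model = fit_lda(cohort, "A", "B")
        w_true = np.linalg.solve(cov, diff)
        w_hat = model.coefficients.to_numpy()
        cos = w_hat @ w_true / (np.linalg.norm(w_hat) * np.linalg.norm(w_true))
        assert cos > 0.95

    def test_tiny_group_rejected(self):
        cohort = gaussian_cohort(np.zeros(9), np.zeros(9), 1, 5, seed=5)
        with pytest.raises(ValueError, match="at least 2"):
            fit_lda(cohort, "A", "B")


class TestDScore:
    def test_zero_model_scores_zero(self):
        model = DiscriminantModel(
            coefficients=pd.Series(0.0, index=list(FEATURE_NAMES)),
            discriminant_point=0.0, positive_label="A", negative_label="B",
        )
        assert d_score(model, pd.Series(1.0, index=list(FEATURE_NAMES))) == 0.0

    def test_single_coefficient_linear_form(self):
        coef = pd.Series(0.0, index=list(FEATURE_NAMES))
        coef["hf_rest"] = 1.0
        model = DiscriminantModel(coefficients=coef, discriminant_point=50.0,
                                  positive_label="A", negative_label="B")
        fv = pd.Series(0.0, index=list(FEATURE_NAMES))
        fv["hf_rest"] = 100.0
        assert d_score(model, fv) == 50.0

    def test_group_means_score_opposite_and_equal(self):
        cohort = gaussian_cohort(np.ones(9) * 3, np.zeros(9), 100, 100, seed=6)
        model = fit_lda(cohort, "A", "B")
        mu_a = cohort[cohort["group"] == "A"][list(FEATURE_NAMES)].mean()
        mu_b = cohort[cohort["group"] == "B"][list(FEATURE_NAMES)].mean()
        assert d_score(model, mu_a) == pytest.approx(-d_score(model, mu_b), abs=1e-9)

    def test_json_roundtrip(self, tmp_path):
        cohort = gaussian_cohort(np.ones(9), np.zeros(9), 30, 30, seed=7)
        model = fit_lda(cohort, "A", "B")
        model.to_json(tmp_path / "m.json")
        back = DiscriminantModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(back.coefficients, model.coefficients)
        assert back.discriminant_point == pytest.approx(model.discriminant_point)


class TestClassifyAndRates:
    def test_training_means_classify_to_their_sides(self):
        cohort = gaussian_cohort(np.ones(9) * 2, np.zeros(9), 50, 50, seed=8)
        model = fit_lda(cohort, "A", "B")
        means = pd.DataFrame([
            mean_row(cohort[cohort["group"] == "A"][list(FEATURE_NAMES)].mean(), "A"),
            mean_row(cohort[cohort["group"] == "B"][list(FEATURE_NAMES)].mean(), "B"),
        ])
        counts = classify_cohort(model, means)
        assert counts.table.loc["A", "positive"] == 1
        assert counts.table.loc["B", "negative"] == 1

    def test_separable_cohort_nearly_perfect(self):
        mu_a = np.full(9, 2.0)  # Delta = 6
        cohort = gaussian_cohort(mu_a, np.zeros(9), 100, 100, seed=9)
        model = fit_lda(cohort, "A", "B")
        sens, spec = sensitivity_specificity(classify_cohort(model, cohort), "A", "B")
        assert sens >= 99.0 and spec >= 99.0

    def test_huge_intercept_all_positive(self):
        cohort = gaussian_cohort(np.ones(9), np.zeros(9), 20, 20, seed=10)
        model = fit_lda(cohort, "A", "B")
        shifted = DiscriminantModel(
            coefficients=model.coefficients, discriminant_point=-1e9,
            positive_label="A", negative_label="B",
        )
        counts = classify_cohort(shifted, cohort)
        assert counts.table["positive"].sum() == 40

    def test_published_confusion_counts_reproduce_printed_rates(self):
        table = pd.DataFrame(
            {"positive": [45, 0], "negative": [4, 44], "total": [49, 44]},
            index=["MDD", "CFS"],
        )
        from hrvdx.discriminant import ConfusionCounts

        sens, spec = sensitivity_specificity(ConfusionCounts(table), "MDD", "CFS")
        assert (sens, spec) == (91.8, 100.0)

    def test_all_positives_missed(self):
        from hrvdx.discriminant import ConfusionCounts

        table = pd.DataFrame(
            {"positive": [0, 0], "negative": [10, 10], "total": [10, 10]},
            index=["A", "B"],
        )
        sens, spec = sensitivity_specificity(ConfusionCounts(table), "A", "B")
        assert sens == 0.0 and spec == 100.0


class TestMahalanobis:
    def test_identical_means_zero_distance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(100, 9))
        df = pd.DataFrame(np.vstack([X, X]), columns=list(FEATURE_NAMES))
        df.insert(0, "group", ["A"] * 100 + ["B"] * 100)
        d, _ = mahalanobis_separation(df, "A", "B")
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_single_feature_reduces_to_standardised_difference(self):
        rng = np.random.default_rng(12)
        xa, xb = rng.normal(5, 2, 300), rng.normal(2, 2, 300)
        df = pd.DataFrame({"x": np.concatenate([xa, xb]),
                           "group": ["A"] * 300 + ["B"] * 300})
        d, _ = mahalanobis_separation(df, "A", "B", feature_names=("x",))
        sp = np.sqrt(((299 * xa.var(ddof=1)) + (299 * xb.var(ddof=1))) / 598)
        assert d == pytest.approx(abs(xa.mean() - xb.mean()) / sp, abs=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(13)
        cohort = gaussian_cohort(np.ones(9), np.zeros(9), 200, 200, seed=14)
        d0, _ = mahalanobis_separation(cohort, "A", "B")
        M = rng.normal(size=(9, 9)) + 3 * np.eye(9)
        shift = rng.normal(size=9)
        X = cohort[list(FEATURE_NAMES)].to_numpy() @ M.T + shift
        transformed = pd.DataFrame(X, columns=list(FEATURE_NAMES))
        transformed.insert(0, "group", cohort["group"].to_numpy())
        d1, _ = mahalanobis_separation(transformed, "A", "B")
        assert d1 == pytest.approx(d0, abs=1e-8)

    def test_cross_check_against_sklearn_lda(self):
        # independent route: sklearn's LDA decision function agrees in rates
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        cohort = gaussian_cohort(np.full(9, 0.5), np.zeros(9), 300, 300, seed=15)
        model = fit_lda(cohort, "A", "B")
        ours = np.asarray(d_score(model, cohort)) >= 0
        X = cohort[list(FEATURE_NAMES)].to_numpy()
        y = (cohort["group"] == "A").astype(int).to_numpy()
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        theirs = sk.predict(X) == 1
        assert np.mean(ours == theirs) > 0.99
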