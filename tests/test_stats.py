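"""Statistical layer against closed-form, brute-force and printed-cell oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mesfmon.stats import (
    ContingencyTable,
    GroupSummary,
    anova_oneway_from_summary,
    chi_square_test,
    logistic_fit,
    lsd_pairwise_from_summary,
    roc_analysis,
    t_test_from_summary,
)


def _g(label, n, mean, sd):
    return GroupSummary(label, n, mean, sd)


class TestAnovaFromSummary:
    def test_pathogen_subgroup_ncd64_cell(self):
        """Neutrophil CD64 across bacterial/viral/fungal subgroups: p = 0.03."""
        groups = [
            _g("bacterial", 26, 11361.46, 9428.95),
            _g("viral", 13, 4099.15, 5347.64),
            _g("fungal", 11, 11137.91, 7337.20),
        ]
        _, p = anova_oneway_from_summary(groups)
        assert p == pytest.approx(0.030, abs=0.0005)

    def test_pathogen_subgroup_si_cell(self):
        groups = [
            _g("bacterial", 26, 504.29, 376.84),
            _g("viral", 13, 170.73, 262.07),
            _g("fungal", 11, 827.91, 1071.35),
        ]
        _, p = anova_oneway_from_summary(groups)
        assert p == pytest.approx(0.029, abs=0.0005)

    def test_equal_groups_give_f_zero_p_one(self):
        groups = [_g("a", 10, 5.0, 2.0), _g("b", 12, 5.0, 2.0)]
        F, p = anova_oneway_from_summary(groups)
        assert F == 0.0 and p == 1.0

    def test_matches_raw_data_anova(self, rng):
        """Summary-statistic F equals scipy.f_oneway on the raw samples."""
        samples = [rng.normal(loc, 2.0, size=n) for loc, n in [(0, 15), (1, 20), (0.5, 12)]]
        groups = [
            _g(str(i), len(s), float(s.mean()), float(s.std(ddof=1)))
            for i, s in enumerate(samples)
        ]
        F, p = anova_oneway_from_summary(groups)
        ref = sps.f_oneway(*samples)
        assert F == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_two_groups_equal_pooled_t_squared(self, rng):
        """On two groups, F = t^2 and the p-values coincide."""
        g1 = _g("a", 14, float(rng.normal()), 1.7)
        g2 = _g("b", 9, float(rng.normal()), 2.4)
        F, p_f = anova_oneway_from_summary([g1, g2])
        t, _, p_t = t_test_from_summary(g1, g2, variant="pooled")
        assert F == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)


class TestLsdFromSummary:
    SEPSIS = [
        _g("stable", 65, 2728.62, 854.87),
        _g("sepsis", 19, 1803.47, 1192.66),
        _g("non-sepsis", 31, 3021.52, 1260.32),
    ]
    NCD64 = [
        _g("stable", 65, 1697.89, 1056.32),
        _g("sepsis", 19, 10265.47, 8293.09),
        _g("non-sepsis", 31, 8908.39, 8837.41),
    ]

    def test_mhladr_sepsis_vs_non_sepsis_below_001(self):
        _, p = lsd_pairwise_from_summary(self.SEPSIS, 1, 2)
        assert p < 0.001

    def test_ncd64_sepsis_vs_non_sepsis_cell(self):
        _, p = lsd_pairwise_from_summary(self.NCD64, 1, 2)
        assert p == pytest.approx(0.416, abs=0.0005)

    def test_identical_groups_give_t_zero(self):
        groups = [_g("a", 10, 5.0, 2.0), _g("b", 10, 5.0, 2.0), _g("c", 10, 7.0, 2.0)]
        t, p = lsd_pairwise_from_summary(groups, 0, 1)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_pooling_uses_all_groups(self):
        """Dropping the third group changes the pooled MSW and hence p."""
        _, p_all = lsd_pairwise_from_summary(self.NCD64, 1, 2)
        _, p_pair = lsd_pairwise_from_summary(self.NCD64[1:], 0, 1)
        assert p_all != pytest.approx(p_pair, rel=1e-3)


class TestTTestFromSummary:
    @pytest.mark.parametrize(
        "g1, g2, printed",
        [
            ((3, 701.67, 857.79), (18, -383.17, 458.87), 0.003),  # ΔSI
            ((3, -1273.33, 2049.93), (18, 811.06, 1461.78), 0.042),  # ΔmHLA-DR
            ((3, 143.67, 5631.89), (18, -6309.61, 9163.02), 0.26),  # ΔnCD64
            ((3, 0.33, 70.29), (18, -52.67, 69.44), 0.24),  # ΔCD64 index
        ],
    )
    def test_longitudinal_cells_pooled(self, g1, g2, printed):
        """The exacerbation vs non-exacerbation Δ comparisons reproduce the
        printed p-values under the pooled (Student) variant."""
        _, df, p = t_test_from_summary(_g("e", *g1), _g("n", *g2), "pooled")
        assert df == g1[0] + g2[0] - 2
        decimals = len(str(printed).split(".")[1])
        assert round(p, decimals) == printed

    def test_identical_groups(self):
        g = _g("a", 10, 3.0, 1.0)
        t, _, p = t_test_from_summary(g, g)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_welch_df_smaller_with_unequal_variances(self):
        g1, g2 = _g("a", 10, 0.0, 1.0), _g("b", 10, 1.0, 5.0)
        _, df_w, _ = t_test_from_summary(g1, g2, "welch")
        _, df_p, _ = t_test_from_summary(g1, g2, "pooled")
        assert df_w < df_p

    def test_welch_matches_scipy_raw(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 3, 20)
        g1 = _g("a", 12, float(a.mean()), float(a.std(ddof=1)))
        g2 = _g("b", 20, float(b.mean()), float(b.std(ddof=1)))
        t, _, p = t_test_from_summary(g1, g2, "welch")
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)


class TestChiSquare:
    def test_sex_distribution_cell(self):
        """Male/female split, stable vs infection recipients: p = 0.036."""
        table = ContingencyTable(((45, 20), (25, 25)))
        _, p = chi_square_test(table, "pearson")
        assert p == pytest.approx(0.036, abs=0.0005)

    def test_proportional_table_gives_zero(self):
        chi2, p = chi_square_test(ContingencyTable(((10, 20), (20, 40))))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_fisher_exact_enumeration(self):
        """2x2 {3,1;1,3}: two-sided hypergeometric enumeration gives
        p = 34/70."""
        _, p = chi_square_test(ContingencyTable(((3, 1), (1, 3))), "fisher")
        assert p == pytest.approx(34 / 70, rel=1e-12)

    def test_permutation_invariance(self):
        t1 = ContingencyTable(((45, 20), (25, 25)))
        t2 = ContingencyTable(((25, 25), (45, 20)))  # rows swapped
        t3 = ContingencyTable(((20, 45), (25, 25)))  # columns swapped
        assert chi_square_test(t1)[0] == pytest.approx(chi_square_test(t2)[0])
        assert chi_square_test(t1)[0] == pytest.approx(chi_square_test(t3)[0])

    def test_zero_margin_is_error(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_test(ContingencyTable(((0, 5), (0, 3))))


def brute_force_auc(scores, labels):
    """Pairwise comparison oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.youden_j == pytest.approx(1.0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_small_example_brute_force(self):
        assert roc_analysis([1, 3, 2, 4], [0, 0, 1, 1]).auc == pytest.approx(0.75)

    def test_matches_brute_force_on_random_instances(self, rng):
        """Rank-formula AUC equals the all-pairs oracle, ties included."""
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = rng.integers(0, 15, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            res = roc_analysis(scores, labels)
            assert res.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=500)
        labels = rng.integers(0, 2, 500)
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_binormal_closed_form(self, rng):
        """N(0,1) vs N(1,1) at n = 1e5/class: AUC within 0.005 of
        Phi(1/sqrt(2)) ~ 0.7602."""
        neg = rng.normal(0, 1, 100_000)
        pos = rng.normal(1, 1, 100_000)
        scores = np.concatenate([neg, pos])
        labels = np.r_[np.zeros(100_000, int), np.ones(100_000, int)]
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(sps.norm.cdf(1 / np.sqrt(2)), abs=0.005)

    def test_auc_complement_under_sign_flip(self, rng):
        scores = rng.normal(size=101)  # continuous, no ties
        labels = rng.integers(0, 2, 101)
        a = roc_analysis(scores, labels).auc
        b = roc_analysis(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_direction_less_recovers_low_marker(self):
        res = roc_analysis([1, 2, 9, 10], [1, 1, 0, 0], direction="less")
        assert res.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis([1, 2, 3], [1, 1, 1])


def newton_raphson_logistic(X, y, tol=1e-12, max_iter=100):
    """Independent MLE oracle: explicit Newton iterations on the score."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = (X * W[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    cov = np.linalg.inv(hess)
    return beta, np.sqrt(np.diag(cov))


class TestLogistic:
    FIXTURE_X = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
    FIXTURE_Y = [0, 1, 0, 1, 0, 1, 1, 1]

    def test_matches_newton_raphson_oracle(self):
        """8-row worked dataset: IRLS coefficients and SEs agree with the
        independent Newton-Raphson oracle to 1e-6."""
        design = pd.DataFrame({"x": self.FIXTURE_X})
        [fit] = logistic_fit(design, self.FIXTURE_Y, mode="univariate")
        Xo = np.column_stack([np.ones(8), self.FIXTURE_X])
        beta, se = newton_raphson_logistic(Xo, self.FIXTURE_Y)
        assert fit.coefficients[0] == pytest.approx(beta[1], abs=1e-6)
        assert fit.standard_errors[0] == pytest.approx(se[1], abs=1e-6)
        assert fit.odds_ratios[0] == pytest.approx(np.exp(beta[1]), rel=1e-6)

    def test_ci_brackets_or(self):
        design = pd.DataFrame({"x": self.FIXTURE_X})
        [fit] = logistic_fit(design, self.FIXTURE_Y, mode="univariate")
        assert fit.ci_lower[0] < fit.odds_ratios[0] < fit.ci_upper[0]

    def test_null_covariate_sanity_band(self, rng):
        """Outcome independent of a balanced binary covariate (n=400):
        OR near 1 and p > 0.05."""
        x = np.r_[np.zeros(200), np.ones(200)]
        y = rng.integers(0, 2, 400)
        [fit] = logistic_fit(pd.DataFrame({"x": x}), y, mode="univariate")
        assert 0.7 <= fit.odds_ratios[0] <= 1.4
        assert fit.p_values[0] > 0.05

    def test_multivariate_screens_on_univariate_p(self, rng):
        n = 300
        x1 = rng.normal(size=n)
        eta = -0.5 + 1.5 * x1
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        noise = rng.normal(size=n)  # unrelated covariate
        design = pd.DataFrame({"signal": x1, "noise": noise})
        [multi] = logistic_fit(design, y, mode="multivariate")
        assert "signal" in multi.terms
        assert multi.model_type == "multivariate"

    def test_separation_flagged_not_raised(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.astype(int)  # perfect separation
        [fit] = logistic_fit(pd.DataFrame({"x": x}), y, mode="univariate")
        assert fit.converged is False
        assert len(fit.warnings_) > 0

    def test_ci_coverage_of_true_or(self, rng):
        """True per-unit OR 2.0, n = 500, 200 replicates: the 95% Wald CI
        covers the truth in >= 93% of replicates."""
        beta_true = np.log(2.0)
        covered = 0
        for _ in range(200):
            x = rng.normal(size=500)
            p = 1 / (1 + np.exp(-(-0.3 + beta_true * x)))
            y = (rng.random(500) < p).astype(int)
            [fit] = logistic_fit(pd.DataFrame({"x": x}), y, mode="univariate")
            if fit.ci_lower[0] <= 2.0 <= fit.ci_upper[0]:
                covered += 1
        assert covered / 200 >= 0.93

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            logistic_fit(pd.DataFrame({"x": [1.0, 2.0]}), [1, 1])
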