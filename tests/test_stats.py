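import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from octaquant import (PairedMatrix, analyze_cohort, bonferroni,
                       friedman_test, normality_check,
                       pearson_with_regression, rm_anova,
                       wilcoxon_signed_rank)

from oracles import (friedman_permutation_p, friedman_statistic,
                     rm_anova_direct, wilcoxon_enumeration)


class TestNormality:
    def test_large_gaussian_sample_flagged_normal(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=200)
            if normality_check(x).is_normal:
                hits += 1
        assert hits >= 18  # >= 90% of seeds

    def test_extreme_bimodal_sample_flagged_non_normal(self):
        x = np.tile([0.0, 1000.0], 30)
        res = normality_check(x)
        assert not res.is_normal

    def test_constant_sample_degenerate(self):
        res = normality_check(np.full(10, 3.3))
        assert not res.is_normal
        assert "constant" in res.note

    def test_returns_both_p_values(self):
        res = normality_check(np.random.default_rng(0).normal(size=50))
        assert 0 <= res.shapiro_p <= 1
        assert 0 <= res.ks_p <= 1


class TestFriedman:
    def test_identical_columns_give_null_result(self):
        m = PairedMatrix(np.tile([[3.0, 3.0, 3.0]], (6, 1)))
        res = friedman_test(m)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_strictly_increasing_rows(self):
        # every subject ranks the conditions 1 < 2 < 3: Q = 6 for n = 3
        m = PairedMatrix(np.array([[1.0, 2, 3], [4, 5, 6], [7, 8, 9]]))
        res = friedman_test(m)
        assert res.statistic == pytest.approx(6.0)
        assert res.p_value == pytest.approx(sps.chi2.sf(6.0, 2))

    def test_matches_scipy_with_and_without_ties(self, rng):
        for _ in range(20):
            v = rng.integers(0, 5, size=(8, 3)).astype(float)
            res = friedman_test(PairedMatrix(v))
            ref = sps.friedmanchisquare(*(v[:, j] for j in range(3)))
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_chi2_p_close_to_permutation_p_in_decision_region(self):
        """The chi-squared p tracks the exact (3!)^5-arrangement permutation
        p within 0.02 wherever the test decides (exact p <= 0.05).

        At n = 5, k = 3 the permutation null is discrete with atoms of up
        to ~0.17, so no continuous approximation can match it uniformly in
        the middle of the distribution; calibration is asserted in the
        significance region.
        """
        checked = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            v = rng.normal(size=(5, 3)) + np.array([0.0, 0.9, 1.8])
            p_exact = friedman_permutation_p(v)
            if p_exact > 0.05:
                continue
            p_chi2 = friedman_test(PairedMatrix(v)).p_value
            assert abs(p_chi2 - p_exact) <= 0.02
            checked += 1
        assert checked >= 3


class TestWilcoxon:
    def test_identical_samples_degenerate(self):
        x = np.arange(8.0)
        res = wilcoxon_signed_rank(x, x)
        assert res.p_value == 1.0
        assert "zero" in res.note

    def test_six_concordant_pairs(self):
        # all differences positive and distinct: W = 0, p = 2/2^6
        res = wilcoxon_signed_rank(np.arange(5.0, 11), np.zeros(6))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 64)

    def test_exact_p_equals_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 11))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res = wilcoxon_signed_rank(x, y)
            w, p = wilcoxon_enumeration(x, y)
            assert res.statistic == pytest.approx(w)
            assert res.p_value == pytest.approx(p)

    def test_exact_p_with_tied_magnitudes(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 10))
            x = rng.integers(0, 4, size=n).astype(float)
            y = rng.integers(0, 4, size=n).astype(float)
            if (x == y).all():
                continue
            res = wilcoxon_signed_rank(x, y)
            _, p = wilcoxon_enumeration(x, y)
            assert res.p_value == pytest.approx(p)

    def test_large_sample_normal_approximation(self, rng):
        x = rng.normal(size=60)
        y = x + rng.normal(0.3, 1.0, size=60)
        res = wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(x, y, correction=True, method="approx")
        assert res.p_value == pytest.approx(ref.pvalue, rel=0.02)


class TestRMAnova:
    def test_identical_conditions_give_null_result(self, rng):
        col = rng.normal(size=6)
        m = PairedMatrix(np.column_stack([col, col, col]))
        res = rm_anova(m)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_two_conditions_reduce_to_paired_t(self, rng):
        v = rng.normal(size=(6, 2))
        res = rm_anova(PairedMatrix(v))
        t = sps.ttest_rel(v[:, 0], v[:, 1])
        assert res.statistic == pytest.approx(t.statistic ** 2)
        assert res.p_value == pytest.approx(t.pvalue)

    def test_matches_textbook_sums_of_squares(self, rng):
        v = rng.normal(size=(6, 3))
        res = rm_anova(PairedMatrix(v))
        f, p = rm_anova_direct(v)
        assert res.statistic == pytest.approx(f)
        assert res.p_value == pytest.approx(p)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.anova import AnovaRM
        v = rng.normal(size=(8, 3))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 3),
            "cond": np.tile(np.arange(3), 8),
            "y": v.ravel()})
        ref = AnovaRM(long, "y", "subject", within=["cond"]).fit()
        res = rm_anova(PairedMatrix(v))
        assert res.statistic == pytest.approx(
            float(ref.anova_table["F Value"].iloc[0]))

    def test_zero_error_variance_noted(self):
        v = np.array([[0.0, 1.0, 2.0]] * 4) + np.arange(4)[:, None]
        res = rm_anova(PairedMatrix(v))
        assert np.isinf(res.statistic)
        assert res.p_value == 0.0

    def test_pairwise_bonferroni_attached(self, rng):
        res = rm_anova(PairedMatrix(rng.normal(size=(6, 3))))
        assert len(res.pairwise) == 3
        for _, raw, adj in res.pairwise:
            assert adj == pytest.approx(min(1.0, raw * 3))
            assert adj >= raw


class TestBonferroni:
    def test_examples_and_capping(self):
        assert bonferroni([0.01], 3) == [pytest.approx(0.03)]
        assert bonferroni([0.5], 3) == [1.0]

    def test_order_preserved(self, rng):
        ps = sorted(rng.random(5))
        adj = bonferroni(ps, 5)
        assert adj == sorted(adj)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bonferroni([1.5], 3)
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], 1)


class TestPearson:
    def test_perfect_line(self):
        ss = np.array([1.0, 2, 3, 4, 5])
        r, p, slope, intercept = pearson_with_regression(ss, 2 * ss + 1)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        ss = np.array([1.0, 2, 3, 4])
        r, *_ = pearson_with_regression(ss, -ss)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        r, *_ = pearson_with_regression(x, y)
        want = (np.mean((x - x.mean()) * (y - y.mean()))
                / (x.std() * y.std()))
        assert r == pytest.approx(want, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_regression(np.ones(5), np.arange(5.0))


def _toy_cohort(effect: float, seed: int = 0, n: int = 12) -> pd.DataFrame:
    """Cohort-mean table with a linear OD effect on every metric."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n):
        subj = rng.normal(0, 0.5)
        for dev in ("SD", "SS"):
            for j, od in enumerate((0.0, 0.3, 0.6)):
                ss = 10 - 3 * j * effect + rng.normal(0, 0.2)
                for slab in ("SCP", "DCP", "CC"):
                    rows.append({
                        "subject": s, "device_model": dev, "od": od,
                        "slab": slab,
                        "vd_pct": 35 + subj - 2 * j * effect + rng.normal(0, 0.4),
                        "vld_pct": 11 + subj - j * effect + rng.normal(0, 0.2),
                        "ccfd_pct": 25 + subj + 8 * j * effect + rng.normal(0, 1.0),
                        "signal_strength": ss,
                    })
    return pd.DataFrame(rows)


class TestAnalyzeCohort:
    def test_constant_metric_gives_unit_p_everywhere(self):
        df = _toy_cohort(effect=0.0, seed=1)
        for col in ("vd_pct", "vld_pct", "ccfd_pct"):
            df[col] = 42.0
        analysis = analyze_cohort(df)
        flow = analysis.table1[analysis.table1.slab != "SS"]
        for _, row in flow.iterrows():
            if row["metric"] in ("vd_pct", "vld_pct", "ccfd_pct"):
                assert row["omnibus_p"] == 1.0

    def test_strong_effect_detected(self):
        analysis = analyze_cohort(_toy_cohort(effect=1.0, seed=2, n=20))
        ccfd = analysis.table1[analysis.table1.metric == "ccfd_pct"]
        assert (ccfd["omnibus_p"] < 0.05).all()
        t2 = analysis.table2
        assert len(t2) == 10  # 2 devices x (2+2+1) metrics
        assert (t2[t2.metric == "ccfd_pct"]["r"] < 0).all()

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            analyze_cohort(pd.DataFrame({"subject": [1]}))
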