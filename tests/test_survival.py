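import numpy as np
import pandas as pd
import pytest

from regnomics.survival import (
    SurvivalRecord,
    composite_myc,
    cox_ph,
    dichotomize,
    kaplan_scan,
    km_estimate,
    loglog_diagnostic,
    logrank_test,
    pearson,
)


def rec(time, event=True):
    return SurvivalRecord(time, event)


class TestKmEstimate:
    def test_single_event(self):
        curve = km_estimate([rec(5)])
        assert curve.survival_at(4.9) == 1.0
        assert curve.survival_at(5) == 0.0

    def test_two_events(self):
        curve = km_estimate([rec(1), rec(2)])
        assert curve.survival_at(1) == 0.5
        assert curve.survival_at(2) == 0.0

    def test_mixed_censoring_matches_hand_product_limit(self):
        # 8 subjects; events at 2, 4, 4, 7; censored at 3, 5, 8, 9
        records = [rec(2), rec(3, False), rec(4), rec(4), rec(5, False),
                   rec(7), rec(8, False), rec(9, False)]
        curve = km_estimate(records)
        # hand product-limit: t=2 (8 at risk, 1 event) -> 7/8
        #                     t=4 (6 at risk, 2 events) -> 7/8 * 4/6
        #                     t=7 (3 at risk, 1 event)  -> ... * 2/3
        assert curve.survival_at(2) == pytest.approx(7 / 8)
        assert curve.survival_at(4) == pytest.approx(7 / 8 * 4 / 6)
        assert curve.survival_at(7) == pytest.approx(7 / 8 * 4 / 6 * 2 / 3)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(5)
        t = rng.exponential(10, size=40)
        e = rng.random(40) < 0.7
        records = [rec(ti, ei) for ti, ei in zip(t, e)]
        curve = km_estimate(records)
        kmf = KaplanMeierFitter().fit(t, e)
        for et, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(et).iloc[0]))

    def test_monotone_nonincreasing_and_exhausts(self):
        records = [rec(t) for t in (3, 1, 4, 1, 5)]
        curve = km_estimate(records)
        assert np.all(np.diff(curve.survival) <= 0)
        assert curve.survival[-1] == 0.0  # no censoring: S hits zero

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([])


class TestLogrank:
    def test_identical_groups(self):
        g = [rec(1), rec(2), rec(3, False)]
        res = logrank_test(g, list(g))
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_matches_hand_oe_accumulation(self):
        # 10 subjects, no ties across groups, all events
        ga = [rec(t) for t in (1, 3, 5, 7, 9)]
        gb = [rec(t) for t in (2, 4, 6, 8, 10)]
        times = sorted([(t, 0) for t in (1, 3, 5, 7, 9)]
                       + [(t, 1) for t in (2, 4, 6, 8, 10)])
        na, nb = 5, 5
        o_minus_e = 0.0
        var = 0.0
        for t, grp in times:
            n = na + nb
            e_a = na / n
            o_a = 1 if grp == 0 else 0
            o_minus_e += o_a - e_a
            if n > 1:
                var += na * nb * (n - 1) / (n ** 2 * (n - 1))  # d=1: na*nb/n^2
            if grp == 0:
                na -= 1
            else:
                nb -= 1
        expected_chi2 = o_minus_e ** 2 / var
        res = logrank_test(ga, gb)
        assert res["chi2"] == pytest.approx(expected_chi2)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(9)
        ga = [rec(float(t)) for t in rng.uniform(0.1, 2, 50)]
        gb = [rec(float(t)) for t in rng.uniform(5, 10, 50)]
        assert logrank_test(ga, gb)["chi2"] > 3.84

    def test_relabel_invariance(self):
        ga = [rec(1), rec(4), rec(6, False)]
        gb = [rec(2), rec(3), rec(5)]
        assert (logrank_test(ga, gb)["chi2"]
                == pytest.approx(logrank_test(gb, ga)["chi2"]))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([rec(1, False)], [rec(2, False)])


class TestKaplanScan:
    def test_constant_values_rejected(self):
        with pytest.raises(ValueError):
            kaplan_scan([1.0] * 5, [rec(t) for t in range(1, 6)])

    def test_recovers_planted_hazard_step(self):
        rng = np.random.default_rng(21)
        n = 120
        biomarker = rng.normal(0, 1, n)
        lam = np.where(biomarker > 0, 1.0, 0.2)
        records = [rec(float(t)) for t in rng.exponential(1 / lam)]
        res = kaplan_scan(biomarker, records)
        sorted_b = np.sort(biomarker)
        idx = np.searchsorted(sorted_b, res.cutoff)
        zero_idx = np.searchsorted(sorted_b, 0.0)
        assert abs(idx - zero_idx) <= 1  # within one order statistic of 0

    def test_equals_exhaustive_scan(self):
        rng = np.random.default_rng(13)
        n = 60
        v = rng.normal(size=n)
        records = [rec(float(t), bool(c)) for t, c in
                   zip(rng.exponential(2, n), rng.random(n) < 0.8)]
        res = kaplan_scan(v, records)
        lo, hi = np.quantile(v, [0.1, 0.9])
        best_p = np.inf
        for c in np.unique(v[(v >= lo) & (v <= hi)]):
            high = v > c
            if 0 < high.sum() < n:
                p = logrank_test([r for r, h in zip(records, high) if h],
                                 [r for r, h in zip(records, high) if not h])["p"]
                best_p = min(best_p, p)
        assert res.min_p == pytest.approx(best_p)

    def test_min_p_beats_median_split(self):
        rng = np.random.default_rng(17)
        n = 80
        v = rng.normal(size=n)
        records = [rec(float(t)) for t in rng.exponential(2, n)]
        res = kaplan_scan(v, records)
        high = dichotomize(v, "median")
        p_med = logrank_test([r for r, h in zip(records, high) if h],
                             [r for r, h in zip(records, high) if not h])["p"]
        assert res.min_p <= p_med


class TestDichotomize:
    def test_median_half_high(self):
        labels = dichotomize(np.arange(1, 101), "median")
        assert labels.sum() == 50

    def test_upper_quartile(self):
        labels = dichotomize(np.arange(1, 101), "upper_quartile")
        assert labels.sum() == 25

    def test_all_equal_all_low(self):
        assert not dichotomize([2.0] * 10, "median").any()


class TestCoxPh:
    def test_zero_variance_covariate_rejected(self):
        records = [rec(t) for t in (1, 2, 3, 4)]
        with pytest.raises(ValueError, match="zero-variance"):
            cox_ph(pd.DataFrame({"x": [1.0] * 4}), records)

    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(31)
        n = 500
        x = (rng.random(n) < 0.5).astype(float)
        lam = 0.05 * 2.0 ** x
        t_event = rng.exponential(1 / lam)
        t_cens = rng.uniform(0, 45, n)  # ~30% censoring
        records = [rec(float(min(a, b)), bool(a <= b))
                   for a, b in zip(t_event, t_cens)]
        fit = cox_ph(pd.DataFrame({"x": x}), records)
        assert 1.6 <= fit.hazard_ratio[0] <= 2.5
        assert fit.ci95[0, 0] < fit.hazard_ratio[0] < fit.ci95[0, 1]

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(41)
        n = 120
        x1 = rng.normal(size=n)
        x2 = (rng.random(n) < 0.4).astype(float)
        lam = 0.1 * np.exp(0.5 * x1 + 0.8 * x2)
        t_event = rng.exponential(1 / lam)
        cens = rng.uniform(0, 20, n)
        t = np.minimum(t_event, cens)
        e = t_event <= cens
        records = [rec(float(ti), bool(ei)) for ti, ei in zip(t, e)]
        fit = cox_ph(pd.DataFrame({"x1": x1, "x2": x2}), records)
        df = pd.DataFrame({"T": t, "E": e, "x1": x1, "x2": x2})
        ll = CoxPHFitter().fit(df, duration_col="T", event_col="E")
        assert fit.coef == pytest.approx(ll.params_.to_numpy(), rel=1e-4)

    def test_breslow_ties_available(self):
        records = [rec(t) for t in (1, 1, 2, 2, 3, 4)]
        x = pd.DataFrame({"x": [1.0, 0, 1, 0, 1, 0]})
        fit_e = cox_ph(x, records, ties="efron")
        fit_b = cox_ph(x, records, ties="breslow")
        assert fit_e.coef[0] != fit_b.coef[0]  # tie correction matters here


class TestCompositeMyc:
    @pytest.mark.parametrize("a,b,expected", [
        ([3.0], [5.0], [5.0]),
        ([4.0], [4.0], [4.0]),
        ([1, 9, 4], [2, 3, 4], [2, 9, 4]),
    ])
    def test_elementwise_max(self, a, b, expected):
        assert composite_myc(a, b).tolist() == expected

    def test_dominates_both_inputs(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=50), rng.normal(size=50)
        m = composite_myc(a, b)
        assert np.all(m >= a) and np.all(m >= b)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            composite_myc([1, 2], [1])


class TestPearson:
    def test_perfect_correlation(self):
        x = [1.0, 2, 3, 4]
        assert pearson(x, x).r == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]).r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        res = pearson(x, y)
        expected = (np.cov(x, y, ddof=1)[0, 1]
                    / (np.std(x, ddof=1) * np.std(y, ddof=1)))
        assert res.r == pytest.approx(expected)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLoglogDiagnostic:
    def test_drops_degenerate_survival(self):
        curve = km_estimate([rec(1), rec(2), rec(3)])  # S: 2/3, 1/3, 0
        series = loglog_diagnostic({"g": curve})["g"]
        assert series.shape[0] == 2  # S=0 step excluded

    def test_direct_substitution(self):
        curve = km_estimate([rec(float(np.e)), rec(4.0, False)])  # S(e)=0.5
        pt = loglog_diagnostic({"g": curve})["g"][0]
        assert pt[0] == pytest.approx(1.0)
        assert pt[1] == pytest.approx(np.log(np.log(2)))

    def test_empty_group_warns(self):
        curve = km_estimate([rec(2.0)])  # only S=0
        with pytest.warns(UserWarning):
            series = loglog_diagnostic({"g": curve})["g"]
        assert series.shape == (0, 2)
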