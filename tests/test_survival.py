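"""Survival estimators and association tests: hand-worked oracles, symmetry
properties, cross-checks against an independent fitter."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import comb

from tnbclayers.survival import (
    chi2_contingency,
    compare_groups,
    cox_binary_hr,
    dunn_posthoc,
    fisher_2x2,
    km_curve,
    kruskal_wallis,
    logrank_test,
    percent_report,
)


class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self):
        out = km_curve([3.0, 5.0, 8.0], [0, 0, 0])
        assert (out["survival"] == 1.0).all()

    def test_hand_product_limit_with_interleaved_censoring(self):
        # times 1 (event), 2 (censored), 3 (event):
        # S(1) = 2/3; the censored time drops the risk set to 1;
        # S(3) = 2/3 * (1 - 1/1) = 0
        out = km_curve([1.0, 2.0, 3.0], [1, 0, 1]).set_index("time")
        assert out.loc[1.0, "survival"] == pytest.approx(2 / 3)
        assert out.loc[2.0, "survival"] == pytest.approx(2 / 3)
        assert out.loc[3.0, "survival"] == pytest.approx(0.0)
        assert out.loc[1.0, "at_risk"] == 3
        assert out.loc[3.0, "at_risk"] == 1

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        times = rng.exponential(10, size=40)
        out = km_curve(times, np.ones(40, dtype=int))
        for _, row in out.iterrows():
            ecdf = (times <= row["time"]).mean()
            assert row["survival"] == pytest.approx(1 - ecdf, abs=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_curve([-1.0], [1])


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        t = [2.0, 4.0, 6.0, 8.0]
        e = [1, 0, 1, 1]
        chi2, df, p = logrank_test({"a": (t, e), "b": (t, e)})
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 1
        assert p == pytest.approx(1.0, abs=1e-8)

    def test_hand_computed_two_group_table(self):
        # group A: events at 1, 2; group B: events at 3, 4.
        # Mantel-Cox by hand: O_A - E_A = 2 - (4/4 + 3/3... ) computed below
        ta, ea = [1.0, 2.0], [1, 1]
        tb, eb = [3.0, 4.0], [1, 1]
        # distinct event times 1,2,3,4; at-risk (A,B): (2,2),(1,2),(0,2),(0,1)
        e_a = 2 / 4 + 1 / 3 + 0 / 2 + 0 / 1
        v = (2 * 2) / (4 * 4 * 3 / 3) + (1 * 2) / (3 * 3 * 2 / 2)  # hypergeom var, d=1
        expected_chi2 = (2 - e_a) ** 2 / v
        chi2, df, p = logrank_test({"A": (ta, ea), "B": (tb, eb)})
        assert chi2 == pytest.approx(expected_chi2, rel=1e-6)

    def test_three_groups_have_two_degrees_of_freedom(self, rng):
        groups = {
            g: (rng.exponential(10, 20), np.ones(20, dtype=int)) for g in "abc"
        }
        _, df, _ = logrank_test(groups)
        assert df == 2


class TestCox:
    def test_recovers_true_hazard_ratio(self, rng):
        n = 1000
        x = np.repeat([0, 1], n // 2)
        rates = np.where(x == 1, 0.01, 0.02)  # HR(group1 vs 0) = 0.5
        t = rng.exponential(1 / rates)
        res = cox_binary_hr(t, np.ones(n, dtype=int), x)
        assert res.converged
        assert 0.4 <= res.hr <= 0.62
        assert res.ci_low < res.hr < res.ci_high

    def test_sign_symmetry_inverts_hazard_ratio(self, rng):
        n = 200
        x = rng.integers(0, 2, n)
        t = rng.exponential(np.where(x == 1, 50, 25))
        e = np.ones(n, dtype=int)
        a = cox_binary_hr(t, e, x)
        b = cox_binary_hr(t, e, 1 - x)
        assert a.hr == pytest.approx(1 / b.hr, rel=1e-6)

    def test_agrees_with_lifelines_without_ties(self, rng):
        from lifelines import CoxPHFitter
        import pandas as pd

        n = 120
        x = rng.integers(0, 2, n)
        t = rng.exponential(np.where(x == 1, 30, 15))
        e = rng.integers(0, 2, n) | (np.arange(n) % 3 == 0)
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        ours = cox_binary_hr(t, e, x, ties="efron")
        assert ours.beta == pytest.approx(cph.params_["x"], rel=1e-4)
        assert ours.se == pytest.approx(cph.standard_errors_["x"], rel=1e-3)
        # without tied event times breslow and efron coincide
        breslow = cox_binary_hr(t, e, x, ties="breslow")
        assert breslow.beta == pytest.approx(ours.beta, rel=1e-8)

    def test_no_events_in_a_group_reported_not_estimated(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 0]
        x = [0, 0, 1, 1]
        res = cox_binary_hr(t, e, x)
        assert not res.converged
        assert "no events" in res.message
        assert math.isnan(res.hr)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_binary_hr([1.0, 2.0], [1, 1], [1, 1])


class TestRankTests:
    def test_identical_groups_no_signal(self):
        h, p = kruskal_wallis([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert p > 0.9

    def test_hand_computed_h_with_ties(self):
        # groups {1,2,2} {2,3,4}: pooled ranks of 1,2,2,2,3,4 are
        # 1, 3, 3, 3, 5, 6 (ties share rank 3); N=6
        a, b = [1, 2, 2], [2, 3, 4]
        r_a, r_b = 1 + 3 + 3, 3 + 5 + 6
        n = 6
        h_raw = 12 / (n * (n + 1)) * (r_a**2 / 3 + r_b**2 / 3) - 3 * (n + 1)
        tie = 1 - (3**3 - 3) / (n**3 - n)
        h, _ = kruskal_wallis([a, b])
        assert h == pytest.approx(h_raw / tie, rel=1e-10)

    def test_dunn_adjusted_never_below_raw(self, rng):
        groups = [rng.standard_normal(15) + shift for shift in (0.0, 0.5, 1.0)]
        out = dunn_posthoc(groups, labels=["a", "b", "c"])
        assert (out["p_adj"] >= out["p"] - 1e-12).all()
        assert len(out) == 3

    def test_dunn_z_matches_direct_formula_two_groups(self, rng):
        a = rng.standard_normal(12)
        b = rng.standard_normal(10) + 1.0
        out = dunn_posthoc([a, b], adjust="none")
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        z_expected = (ranks[:12].mean() - ranks[12:].mean()) / math.sqrt(
            n * (n + 1) / 12 * (1 / 12 + 1 / 10)
        )
        assert out["z"].iloc[0] == pytest.approx(z_expected, rel=1e-10)


class TestContingency:
    def test_fisher_matches_exhaustive_enumeration(self):
        a, b, c, d = 1, 9, 9, 1
        # enumerate all tables with the same margins, sum P(table) <= P(obs)
        row1, col1, n = a + b, a + c, a + b + c + d

        def table_p(x):
            return (
                comb(row1, x, exact=True)
                * comb(n - row1, col1 - x, exact=True)
                / comb(n, col1, exact=True)
            )

        p_obs = table_p(a)
        expected = sum(
            table_p(x)
            for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1)
            if table_p(x) <= p_obs * (1 + 1e-9)
        )
        assert fisher_2x2([[a, b], [c, d]]) == pytest.approx(expected, rel=1e-9)

    def test_zero_margin_p_one(self):
        assert fisher_2x2([[0, 0], [5, 7]]) == 1.0

    def test_symmetric_table_p_one(self):
        assert fisher_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_chi2_zero_for_proportional_rows(self):
        chi2, df, p = chi2_contingency([[10, 20, 30], [20, 40, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 2

    def test_chi2_hand_formula_2x2(self):
        table = np.array([[10, 20], [30, 10]], dtype=float)
        n = table.sum()
        row, col = table.sum(axis=1), table.sum(axis=0)
        expected = np.outer(row, col) / n
        chi2_hand = ((table - expected) ** 2 / expected).sum()
        chi2, df, _ = chi2_contingency(table)
        assert chi2 == pytest.approx(chi2_hand)
        assert df == 1

    def test_chi2_invariant_to_permutation(self, rng):
        table = rng.integers(5, 50, size=(3, 4))
        chi2_a, _, _ = chi2_contingency(table)
        chi2_b, _, _ = chi2_contingency(table[::-1, ::-1])
        assert chi2_a == pytest.approx(chi2_b)


class TestPercentReport:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(91, 494, 18), (44, 53, 83), (0, 10, 0), (310, 494, 63), (1, 8, 13)],
    )
    def test_table_style_percentages(self, num, den, expected):
        assert percent_report(num, den) == expected

    def test_half_rounds_away_from_zero(self):
        assert percent_report(1, 8) == 13  # 12.5 -> 13
        assert percent_report(-1, 8) == -13

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_report(1, 0)


class TestCompareGroups:
    def test_bundle_consistent(self, rng):
        n = 300
        labels = np.array(["x"] * (n // 2) + ["y"] * (n // 2))
        t = rng.exponential(np.where(labels == "y", 40, 20))
        e = (t < 60).astype(int)
        t = np.minimum(t, 60)
        res = compare_groups(t, e, labels, reference="x", comparison="y")
        assert res.n_per_group == {"x": 150, "y": 150}
        assert res.cox.hr < 1  # y has longer survival
        assert res.logrank_p < 0.05
        for curve in res.curves.values():
            s = curve["survival"].to_numpy()
            assert np.all(np.diff(s) <= 1e-12)
            assert np.all((s >= 0) & (s <= 1))
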