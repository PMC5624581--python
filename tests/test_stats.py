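"""Nonparametric battery against independent enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from uvcover import (
    CohortModel,
    canthus_change_test,
    compare_groups,
    compare_paired,
    correlate,
    draw_cohort_fractions,
    full_report,
    normality_test,
    summarize,
)
from uvcover.stats import BOX_PERCENTILES, _box_stats, pearson_correlate


def mw_oracle(x, y):
    """Exhaustive Mann-Whitney oracle built directly on pairwise comparisons:
    relabel the pooled values in every possible way and count tail masses."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(sample_x, sample_y):
        return sum(
            (a > b) + 0.5 * (a == b) for a in sample_x for b in sample_y
        )

    u_obs = u_stat(x, y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(xs, ys))
    lo = sum(u <= u_obs + 1e-9 for u in us) / len(us)
    hi = sum(u >= u_obs - 1e-9 for u in us) / len(us)
    return min(1.0, 2.0 * min(lo, hi))


def wilcoxon_oracle(diffs):
    """Exhaustive signed-rank oracle: every sign assignment of |d| ranks."""
    d = [v for v in diffs if v != 0]
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[np.asarray(d) > 0].sum())
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    lo = sum(w <= w_obs + 1e-9 for w in ws) / len(ws)
    hi = sum(w >= w_obs - 1e-9 for w in ws) / len(ws)
    return min(1.0, 2.0 * min(lo, hi))


class TestNormalityGate:
    def test_gaussian_samples_pass(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(100)
            hits += normality_test(x).pvalue > 0.05
        assert hits >= 95

    def test_two_point_samples_fail(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).choice([0.0, 100.0], size=100)
            hits += normality_test(x).pvalue < 0.05
        assert hits >= 95

    def test_constant_sample_not_applicable(self):
        res = normality_test([5.0] * 10)
        assert math.isnan(res.pvalue) and "not applicable" in res.method

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_test([1.0, 2.0])


class TestMannWhitney:
    def test_textbook_example(self):
        res = compare_groups([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1 / 3)
        assert "exact" in res.method

    def test_identical_samples_p_one(self):
        assert compare_groups([1, 2, 3], [1, 2, 3]).pvalue == 1.0

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n1, n2 = rng.integers(2, 7, size=2)
            x = rng.integers(0, 6, size=n1).astype(float)  # ties likely
            y = rng.integers(0, 6, size=n2).astype(float)
            res = compare_groups(x, y)
            assert "exact" in res.method
            assert res.pvalue == pytest.approx(mw_oracle(x, y), abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x, y = rng.normal(size=6), rng.normal(size=6)
            exact = compare_groups(x, y, method="exact").pvalue
            approx = compare_groups(x, y, method="approx").pvalue
            assert abs(exact - approx) <= 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])


class TestWilcoxon:
    def test_all_positive_differences(self):
        res = compare_paired([0, 0, 0], [1, 2, 3])
        assert res.pvalue == pytest.approx(0.25)
        assert "exact" in res.method

    def test_no_change_reports_p_one(self):
        res = compare_paired([1.0, 2.0], [1.0, 2.0])
        assert res.pvalue == 1.0 and "not applicable" in res.method

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(3, 11))
            before = rng.integers(0, 8, size=n).astype(float)
            after = before + rng.integers(-3, 4, size=n)
            if np.all(after == before):
                continue
            res = compare_paired(before, after)
            assert "exact" in res.method
            assert res.pvalue == pytest.approx(wilcoxon_oracle(after - before), abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            before = rng.normal(size=12)
            after = before + rng.normal(size=12)
            exact = compare_paired(before, after, method="exact").pvalue
            approx = compare_paired(before, after, method="approx").pvalue
            assert abs(exact - approx) <= 0.03

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_paired([1, 2], [1, 2, 3])


class TestCorrelation:
    def test_monotone_sequences(self):
        assert correlate([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)
        assert correlate([1, 2, 3, 4], [9, 7, 5, 3]).statistic == pytest.approx(-1.0)

    def test_rank_formula_example(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (1,1,1,1) -> 1 - 24/60 = 0.6
        res = correlate([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.statistic == pytest.approx(0.6)

    def test_constant_input_not_applicable(self):
        res = correlate([1.0, 1.0, 1.0], [1, 2, 3])
        assert math.isnan(res.statistic)


class TestCanthusChange:
    def test_printed_counts_consistency(self):
        """44/57 then 37/57 canthal failures: chi-square stays short of 0.05."""
        res = canthus_change_test([[44, 13], [37, 20]])
        oracle = 0.0
        obs = np.array([[44, 13], [37, 20]], float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        oracle = ((obs - exp) ** 2 / exp).sum()
        assert res.statistic == pytest.approx(oracle)
        assert res.statistic == pytest.approx(2.09, abs=0.01)
        assert res.pvalue == pytest.approx(0.148, abs=0.002)
        assert not res.significant

    def test_identical_rows_give_zero(self):
        res = canthus_change_test([[30, 10], [30, 10]])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_row_swap_symmetry(self):
        a = canthus_change_test([[44, 13], [37, 20]]).statistic
        b = canthus_change_test([[37, 20], [44, 13]]).statistic
        assert a == pytest.approx(b)

    def test_zero_expected_count_rejected(self):
        with pytest.raises(ValueError):
            canthus_change_test([[0, 0], [5, 5]])

    def test_yates_correction_shrinks_statistic(self):
        plain = canthus_change_test([[44, 13], [37, 20]]).statistic
        yates = canthus_change_test([[44, 13], [37, 20]], yates=True).statistic
        assert yates < plain


class TestPercentiles:
    def test_box_stats_match_sort_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 100, size=57)
        stats = _box_stats(x)
        xs = np.sort(x)
        for q in BOX_PERCENTILES:
            h = (len(xs) - 1) * q / 100.0
            lo = int(np.floor(h))
            expected = xs[lo] + (h - lo) * (xs[min(lo + 1, len(xs) - 1)] - xs[lo])
            assert stats[f"p{q}"] == pytest.approx(expected)


def _fractions_as_cohort(df: pd.DataFrame) -> pd.DataFrame:
    out = df.rename(
        columns={
            "target_missed_letterbox": "pct_letterbox",
            "target_missed_rest": "pct_rest",
        }
    ).copy()
    out["pct_letterbox"] *= 100
    out["pct_rest"] *= 100
    out["pct_face"] = 0.18 * out["pct_letterbox"] + 0.82 * out["pct_rest"]
    out["canthus_covered"] = ~out.pop("canthus_missed")
    return out


class TestSummarize:
    def test_region_panel_recovers_effect(self):
        cohort = _fractions_as_cohort(draw_cohort_fractions(CohortModel(seed=3)))
        panel = summarize(cohort, "region").panels["region"]
        assert panel["letterbox"]["median"] == pytest.approx(14.0, abs=2.0)
        assert panel["rest"]["median"] == pytest.approx(7.0, abs=2.0)
        assert panel["letterbox vs rest"]["p"] < 0.01

    def test_formulation_null_is_controlled(self):
        """No formulation effect is simulated, so the comparison should stay
        non-significant in at least 90 of 100 seeded cohorts (type-I control)."""
        hits = 0
        for seed in range(100):
            cohort = _fractions_as_cohort(draw_cohort_fractions(CohortModel(seed=seed)))
            panel = summarize(cohort, "formulation").panels["formulation"]
            hits += panel["letterbox test"]["p"] > 0.05
        assert hits >= 90

    def test_visit_panel_contents(self):
        cohort = _fractions_as_cohort(draw_cohort_fractions(CohortModel(seed=4)))
        panel = summarize(cohort, "visit").panels["visit"]
        assert panel["letterbox paired test"]["p"] < 0.001
        assert "canthus change" in panel
        assert set(panel["eyelid banding visit 1"]) == {"0-10%", "10-20%", ">20%"}
        assert sum(panel["eyelid banding visit 1"].values()) == 57
        assert "eyelid change vs initial (pearson)" in panel

    def test_single_visit_cohort_warns_and_skips(self):
        cohort = _fractions_as_cohort(draw_cohort_fractions(CohortModel(seed=5)))
        report = summarize(cohort[cohort.visit == 1], "visit")
        assert report.warnings
        assert "letterbox paired test" not in report.panels["visit"]

    def test_full_report_covers_all_groupings(self):
        cohort = _fractions_as_cohort(draw_cohort_fractions(CohortModel(seed=6)))
        report = full_report(cohort)
        assert set(report.panels) == {"region", "gender", "skin_group",
                                      "formulation", "visit"}
        js = report.to_json()
        assert "letterbox vs rest" in js
        assert report.to_markdown().startswith("# Coverage cohort report")

    def test_unknown_grouping_rejected(self):
        cohort = _fractions_as_cohort(draw_cohort_fractions(CohortModel(seed=7)))
        with pytest.raises(ValueError):
            summarize(cohort, "starsign")


class TestPearsonLabel:
    def test_improvement_vs_initial_reports_both_coefficients(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(size=30)
        y = 0.5 * x + 0.1 * rng.uniform(size=30)
        assert pearson_correlate(x, y).statistic == pytest.approx(
            np.corrcoef(x, y)[0, 1]
        )
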