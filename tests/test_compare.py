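"""Group comparisons: twin engines, post hoc tests, gates, exact tests."""

import itertools

import numpy as np
import pytest
from scipy import stats

from cartizone.compare import (
    GroupSummary,
    anova_from_summary,
    anova_raw,
    fisher_exact_rxc,
    format_p,
    kruskal_wallis_posthoc,
    mann_whitney,
    normality_gate,
    t_between,
    tukey_hsd,
    variance_homogeneity,
)
from cartizone.normative import (
    AGE_SEX_COUNTS,
    THICKNESS_BY_AGE_ALL,
    THICKNESS_BY_AGE_MALE,
    age_summary,
    sex_summary,
)
from cartizone.synth import make_group_samples


def _summary_to_dict(summ):
    return {lab: (int(n), float(m), float(s))
            for lab, n, m, s in zip(summ.labels, summ.ns, summ.means,
                                    summ.sds)}


class TestAnovaEngines:
    def test_two_identical_groups_f_zero(self):
        summ = GroupSummary(["a", "b"], [10, 10], [3.0, 3.0], [0.2, 0.2])
        table = anova_from_summary(summ)
        assert table.f == pytest.approx(0.0)
        assert table.p == pytest.approx(1.0)

    @pytest.mark.parametrize("site,printed_f", [
        ("right_lateral", 4.924), ("right_medial", 3.393),
        ("left_medial", 4.061),
    ])
    def test_normative_all_participants_f(self, site, printed_f):
        table = anova_from_summary(age_summary(THICKNESS_BY_AGE_ALL, site))
        assert table.f == pytest.approx(printed_f, abs=0.05)

    @pytest.mark.parametrize("site,printed_f", [
        ("right_lateral", 3.627), ("right_medial", 4.206),
        ("left_medial", 4.614),
    ])
    def test_normative_male_f(self, site, printed_f):
        table = anova_from_summary(age_summary(THICKNESS_BY_AGE_MALE, site))
        assert table.f == pytest.approx(printed_f, abs=0.05)

    def test_summary_engine_equals_raw_engine_on_exact_moments(self):
        summ = age_summary(THICKNESS_BY_AGE_ALL, "right_lateral")
        groups = make_group_samples(_summary_to_dict(summ), seed=2)
        t_sum = anova_from_summary(summ)
        t_raw = anova_raw(groups)
        assert t_raw.f == pytest.approx(t_sum.f, rel=1e-9)
        assert t_raw.ssb == pytest.approx(t_sum.ssb, rel=1e-9)
        assert t_raw.ssw == pytest.approx(t_sum.ssw, rel=1e-9)
        # and against scipy's raw-data ANOVA as an outside oracle
        f_sp, p_sp = stats.f_oneway(*groups.values())
        assert t_raw.f == pytest.approx(float(f_sp), rel=1e-9)
        assert t_raw.p == pytest.approx(float(p_sp), rel=1e-9)

    def test_zero_within_variance_flagged_infinite(self):
        summ = GroupSummary(["a", "b"], [5, 5], [1.0, 2.0], [0.0, 0.0])
        table = anova_from_summary(summ)
        assert np.isinf(table.f) and table.degenerate

    def test_affine_invariance_of_f(self, rng):
        groups = {str(i): rng.normal(3 + 0.1 * i, 0.3, 20) for i in range(3)}
        f0 = anova_raw(groups).f
        f1 = anova_raw({k: 2.5 * v + 7 for k, v in groups.items()}).f
        assert f1 == pytest.approx(f0, rel=1e-9)


class TestTukey:
    def test_identical_groups_q_zero_p_one(self):
        summ = GroupSummary(["a", "b", "c"], [10, 10, 10],
                            [3.0, 3.0, 3.1], [0.2, 0.2, 0.2])
        res = tukey_hsd(summary=summ)
        pair_ab = next(p for p in res.pairs
                       if {p.group_a, p.group_b} == {"a", "b"})
        assert pair_ab.statistic == pytest.approx(0.0)
        assert pair_ab.p == pytest.approx(1.0)

    def test_male_right_medial_significant_pairs(self):
        res = tukey_hsd(summary=age_summary(THICKNESS_BY_AGE_MALE,
                                            "right_medial"))
        assert set(res.significant_pairs(0.05)) == {"4 > 1", "4 > 2"}

    def test_direction_matches_sign_of_mean_difference(self, rng):
        groups = {str(i + 1): rng.normal(3 + 0.2 * i, 0.3, 25)
                  for i in range(4)}
        res = tukey_hsd(groups=groups)
        for pr in res.pairs:
            hi, lo = pr.direction.split(" > ")
            assert np.mean(groups[hi]) >= np.mean(groups[lo])

    def test_matches_scipy_tukey_on_raw_data(self, rng):
        groups = {str(i): rng.normal(3 + 0.1 * i, 0.3, 30) for i in range(4)}
        mine = tukey_hsd(groups=groups)
        ref = stats.tukey_hsd(*groups.values())
        got = {frozenset((a, b)): p.p for a, b, p in
               ((pr.group_a, pr.group_b, pr) for pr in mine.pairs)}
        for i, j in itertools.combinations(range(4), 2):
            assert got[frozenset((str(i), str(j)))] == pytest.approx(
                float(ref.pvalue[i, j]), rel=1e-6)

    def test_p_matches_studentized_range_monte_carlo(self):
        # MC oracle for the null distribution of the pairwise q statistic:
        # range of k group means over sqrt(MSW/n), equal n
        rng = np.random.default_rng(12)
        k, n, sims = 4, 10, 100_000
        x = rng.normal(size=(sims, k, n))
        means = x.mean(axis=2)
        msw = x.var(axis=2, ddof=1).mean(axis=1)
        q_null = (means.max(axis=1) - means.min(axis=1)) / np.sqrt(msw / n)
        for q_obs in (2.5, 3.5, 4.5):
            p_mc = float((q_null > q_obs).mean())
            p_dist = float(stats.studentized_range.sf(q_obs, k, k * (n - 1)))
            se = np.sqrt(p_mc * (1 - p_mc) / sims) + 1e-5
            assert abs(p_mc - p_dist) < 5 * se


class TestTwoSample:
    def test_equal_groups_t_zero(self):
        summ = GroupSummary(["a", "b"], [20, 20], [3.0, 3.0], [0.2, 0.2])
        res = t_between(summary=summ)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_normative_right_middle_sex_p(self):
        res = t_between(summary=sex_summary("right_middle"))
        assert abs(res.statistic) == pytest.approx(1.65, abs=0.01)
        assert res.p == pytest.approx(0.096, abs=0.01)

    def test_summary_equals_raw_engine_exact_moments(self):
        summ = sex_summary("right_middle")
        groups = make_group_samples(_summary_to_dict(summ), seed=3)
        res_sum = t_between(summary=summ)
        res_raw = t_between(groups=groups)
        assert res_raw.statistic == pytest.approx(res_sum.statistic,
                                                  rel=1e-12)
        t_sp, p_sp = stats.ttest_ind(*groups.values())
        assert res_raw.statistic == pytest.approx(float(t_sp), rel=1e-9)

    def test_welch_variant(self):
        summ = GroupSummary(["a", "b"], [10, 40], [3.0, 3.4], [0.5, 0.1])
        pooled = t_between(summary=summ, variant="pooled")
        welch = t_between(summary=summ, variant="welch")
        assert pooled.p != welch.p
        a = np.repeat([2.5, 3.5], 5)
        rng = np.random.default_rng(1)
        b = rng.normal(3.4, 0.1, 40)
        ref = stats.ttest_ind(a, b, equal_var=False)
        got = t_between(groups={"a": a, "b": b}, variant="welch")
        assert got.statistic == pytest.approx(float(ref.statistic), rel=1e-9)
        assert got.p == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_degenerate_zero_variance(self):
        summ = GroupSummary(["a", "b"], [5, 5], [2.0, 2.0], [0.0, 0.0])
        res = t_between(summary=summ)
        assert res.p == 1.0 and res.degenerate

    def test_mann_whitney_separated_groups_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1)  # 2/20 orderings as extreme

    def test_mann_whitney_adjacent_transposition(self):
        res = mann_whitney([1, 2, 4], [3, 5, 6])
        assert res.statistic == 1.0

    def test_mann_whitney_all_tied_degenerate(self):
        res = mann_whitney([2.0, 2.0], [2.0, 2.0])
        assert res.p == 1.0 and res.degenerate

    def test_mann_whitney_type_one_error_calibrated(self):
        rng = np.random.default_rng(21)
        rej = sum(
            mann_whitney(rng.normal(size=40), rng.normal(size=40)).p < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rej / 1000 <= 0.07


class TestKruskalDunn:
    def test_identical_groups_h_zero(self):
        res = kruskal_wallis_posthoc({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert res.statistic == 0.0 and res.p == 1.0 and res.degenerate

    def test_h_matches_brute_force_rank_formula(self):
        groups = {"a": [1.2, 3.4, 2.2], "b": [5.1, 4.4, 6.0],
                  "c": [2.9, 3.3, 4.1]}
        res = kruskal_wallis_posthoc(groups)
        pooled = np.concatenate(list(groups.values()))
        ranks = stats.rankdata(pooled)
        N = len(pooled)
        idx = 0
        h = 0.0
        for g in groups.values():
            r = ranks[idx:idx + len(g)]
            idx += len(g)
            h += r.sum() ** 2 / len(g)
        h = 12 / (N * (N + 1)) * h - 3 * (N + 1)
        assert res.statistic == pytest.approx(h, rel=1e-9)

    def test_power_increases_with_shift(self):
        rng = np.random.default_rng(8)
        powers = []
        for shift in (0.0, 0.5, 1.0):
            rej = sum(
                kruskal_wallis_posthoc({
                    "a": rng.normal(0, 1, 25),
                    "b": rng.normal(0, 1, 25),
                    "c": rng.normal(shift, 1, 25),
                }).p < 0.05
                for _ in range(200)
            )
            powers.append(rej / 200)
        assert powers[0] < powers[1] < powers[2]

    def test_dunn_bonferroni_upper_bounds_unadjusted(self, rng):
        groups = {str(i): rng.normal(3 + 0.3 * i, 0.4, 20) for i in range(3)}
        res = kruskal_wallis_posthoc(groups)
        for pr in res.pairs:
            raw = 2 * stats.norm.sf(abs(pr.statistic))
            assert pr.p >= raw - 1e-12
            assert pr.p <= 1.0


class TestGates:
    def test_levene_gate_calibration_under_homogeneity(self):
        rng = np.random.default_rng(31)
        passes = sum(
            "homogeneous" in variance_homogeneity({
                "a": rng.normal(0, 1, 50), "b": rng.normal(0, 1, 50),
                "c": rng.normal(0, 1, 50),
            }).notes
            for _ in range(400)
        )
        assert 0.90 <= passes / 400 <= 0.98

    def test_levene_gate_detects_tenfold_sd(self):
        rng = np.random.default_rng(32)
        fails = sum(
            "heterogeneous" in variance_homogeneity({
                "a": rng.normal(0, 1, 50), "b": rng.normal(0, 10, 50),
            }).notes
            for _ in range(200)
        )
        assert fails / 200 > 0.99

    def test_levene_constant_groups_pass(self):
        res = variance_homogeneity({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0]})
        assert res.statistic == 0.0 and "homogeneous" in res.notes

    def test_shapiro_normal_quantiles_w_near_one(self):
        x = stats.norm.ppf((np.arange(1, 101) - 0.5) / 100)
        res = normality_gate(x)
        assert res.statistic > 0.995 and "normal" in res.notes

    def test_shapiro_rejects_heavy_tails_and_uniform(self):
        rng = np.random.default_rng(41)
        heavy = sum(normality_gate(rng.standard_t(2, 100)).p < 0.05
                    for _ in range(100))
        assert heavy / 100 > 0.5
        unif = sum(normality_gate(rng.uniform(size=500)).p < 0.05
                   for _ in range(50))
        assert unif / 50 > 0.9

    def test_shapiro_n_out_of_range(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])


class TestFisherExact:
    def test_two_by_two_matches_scipy_and_enumeration(self):
        res = fisher_exact_rxc([[1, 9], [11, 3]])
        assert res.p == pytest.approx(0.00276, abs=5e-5)
        assert res.p == pytest.approx(
            float(stats.fisher_exact([[1, 9], [11, 3]])[1]), rel=1e-9)

    def test_proportional_rows_give_p_one(self):
        assert fisher_exact_rxc([[10, 20], [20, 40]]).p == pytest.approx(1.0)

    def test_normative_age_sex_counts(self):
        res = fisher_exact_rxc(AGE_SEX_COUNTS)
        assert res.p == pytest.approx(0.710, abs=0.02)

    def test_monte_carlo_agrees_with_enumeration(self, monkeypatch):
        import cartizone.compare as cmp
        table = [[8, 12], [15, 5], [10, 10]]
        exact = fisher_exact_rxc(table).p
        monkeypatch.setattr(cmp, "_ENUM_CAP", 1)
        mc = fisher_exact_rxc(table, n_mc=100_000, seed=9)
        assert "monte-carlo" in mc.notes[0]
        assert mc.p == pytest.approx(exact, abs=0.01)

    def test_empty_row_dropped_with_warning(self):
        res = fisher_exact_rxc([[0, 0], [5, 3], [2, 6]])
        assert "empty rows/columns dropped" in res.notes


def test_p_formatting_table_style():
    assert format_p(0.0004) == "<0.001"
    assert format_p(0.096123) == "0.096"
    assert format_p(0.5) == "0.500"
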