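import numpy as np
import pytest

from dopacircuit.stats import (
    MetricSample,
    average_same_type,
    dunn_test,
    regression_vs_dopamine,
    select_and_run_tests,
    significance_stars,
    summarize,
)


class TestAveraging:
    def test_singleton_identity(self):
        s = average_same_type([3.7], metric="e", level="Low", replicate=0)
        assert s.value == 3.7 and s.members_averaged == 1

    def test_mean_of_constants(self):
        assert average_same_type([2.0] * 20).value == 2.0

    def test_arithmetic_mean(self):
        assert average_same_type([1.0, 2.0, 3.0]).value == 2.0

    def test_missing_members_excluded_with_count(self):
        s = average_same_type([1.0, np.nan, 3.0])
        assert s.value == 2.0 and s.members_averaged == 2

    def test_all_missing(self):
        s = average_same_type([np.nan, np.nan])
        assert np.isnan(s.value) and s.members_averaged == 0


class TestSummarize:
    def test_constant_values(self):
        mean, sem, n = summarize([2.0, 2.0, 2.0])
        assert (mean, sem, n) == (2.0, 0.0, 3)

    def test_two_points(self):
        mean, sem, n = summarize([0.0, 2.0])
        assert mean == 1.0 and sem == pytest.approx(1.0) and n == 2

    def test_single_point_sem_missing(self):
        mean, sem, n = summarize([5.0])
        assert mean == 5.0 and np.isnan(sem) and n == 1

    def test_unit_variance_sem_near_one_third(self):
        """SEM of 9 standard-normal draws concentrates near 1/3."""
        rng = np.random.default_rng(42)
        sems = [summarize(rng.normal(size=9))[1] for _ in range(2000)]
        assert np.mean(sems) == pytest.approx(1 / 3, abs=0.03)


class TestDecisionTree:
    def _groups(self, rng, shift=0.0, scale=(1, 1, 1, 1)):
        return {
            name: rng.normal(loc=shift if i == 3 else 0.0, scale=scale[i], size=9)
            for i, name in enumerate(["Low", "Medium", "High", "Full"])
        }

    def test_normal_equal_variance_selects_anova_tukey(self):
        rng = np.random.default_rng(7)
        res = select_and_run_tests(self._groups(rng), metric="m")
        assert res.omnibus == "anova" and res.posthoc == "tukey"
        assert len(res.pairwise_p) == 6
        assert set(res.summary) == {"Low", "Medium", "High", "Full"}

    def test_unequal_variance_selects_welch_games_howell(self):
        rng = np.random.default_rng(4)
        groups = self._groups(rng, scale=(1, 1, 1, 40))
        res = select_and_run_tests(groups, metric="m")
        assert res.omnibus == "welch-anova" and res.posthoc == "games-howell"

    def test_skewed_data_selects_kruskal_dunn(self):
        rng = np.random.default_rng(11)
        groups = {name: rng.exponential(size=40) ** 2 for name in
                  ["Low", "Medium", "High", "Full"]}
        res = select_and_run_tests(groups, metric="m")
        assert res.omnibus == "kruskal-wallis" and res.posthoc == "dunn"

    def test_degenerate_zero_variance_reports_without_p(self):
        groups = {"Low": [1.0, 1.0, 1.0], "Full": [2.0, 2.1, 1.9]}
        res = select_and_run_tests(groups, metric="m")
        assert res.omnibus == "none" and np.isnan(res.omnibus_p)
        assert res.summary["Low"][0] == 1.0

    def test_insufficient_design_rejected(self):
        with pytest.raises(ValueError):
            select_and_run_tests({"Low": [1.0, 2.0]}, metric="m")

    def test_accepts_metric_samples(self):
        rng = np.random.default_rng(5)
        samples = [MetricSample("m", lv, r, float(rng.normal()))
                   for lv in ("Low", "Full") for r in range(9)]
        res = select_and_run_tests(samples)
        assert res.metric == "m" and np.isfinite(res.omnibus_p)


class TestDunn:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=9)
        p = dunn_test({"a": x, "b": x + 1e-9, "c": x - 1e-9})
        assert all(v > 0.9 for v in p.values())

    def test_separated_group_detected_and_bonferroni_ordering(self):
        rng = np.random.default_rng(2)
        groups = {"a": rng.normal(size=12), "b": rng.normal(size=12),
                  "c": rng.normal(loc=8.0, size=12)}
        p = dunn_test(groups)
        assert p[("a", "c")] < 0.01 and p[("b", "c")] < 0.01
        assert p[("a", "b")] > 0.05
        assert all(0.0 <= v <= 1.0 for v in p.values())


class TestReporting:
    def test_star_thresholds(self):
        assert significance_stars(0.5) == "ns"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.005) == "**"
        assert significance_stars(5e-4) == "***"
        assert significance_stars(5e-5) == "****"
        assert significance_stars(float("nan")) == "na"

    def test_regression_recovers_linear_trend(self):
        samples = [MetricSample("m", lv, r, {"Low": 0.125, "Medium": 0.375,
                                             "High": 0.625, "Full": 0.875}[lv] * 2.0 + 1.0)
                   for lv in ("Low", "Medium", "High", "Full") for r in range(3)]
        slope, intercept, r, p = regression_vs_dopamine(samples)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r == pytest.approx(1.0)
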