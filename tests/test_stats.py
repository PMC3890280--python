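"""Pearson, ANOVA, Scheffé and Shapiro-Wilk against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from myoviability.stats import (
    one_way_anova,
    pearson,
    run_study_stats,
    scheffe_posthoc,
    shapiro_wilk,
    two_way_anova,
)


def naive_pearson(x, y):
    """Two-pass textbook formula, independent of numpy.corrcoef."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        assert pearson([1, 2, 3], [1, 2, 3]).r == pytest.approx(1.0)
        assert pearson([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0)

    def test_duration_vs_group_means(self):
        # ischemia hours against the study's normalized total-viability means
        res = pearson([0, 4, 6, 8, 9], [100.0, 60.5, 43.8, 24.3, 12.1])
        assert res.r == pytest.approx(-0.99930, abs=1e-4)
        assert res.r_squared == pytest.approx(0.99860, abs=2e-4)
        assert res.p_value < 0.001
        assert res.n_pairs == 5

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(4, 40))
    def test_matches_two_pass_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.5 * x
        assert pearson(x, y).r == pytest.approx(naive_pearson(x, y), abs=1e-12)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2])


class TestTwoWayAnova:
    def table(self, cells):
        rows = []
        for (a, b), values in cells.items():
            rows += [{"condition": a, "measurement": b, "value": v} for v in values]
        return pd.DataFrame(rows)

    def test_hand_computed_2x2(self):
        # cell means 11,21,31,41; additive design, within-cell deviations +-1
        cells = {
            ("a1", "b1"): (10, 12), ("a1", "b2"): (20, 22),
            ("a2", "b1"): (30, 32), ("a2", "b2"): (40, 42),
        }
        res = two_way_anova(self.table(cells))
        assert res["condition"].ss == pytest.approx(800.0)
        assert res["measurement"].ss == pytest.approx(200.0)
        assert res["condition:measurement"].ss == pytest.approx(0.0, abs=1e-12)
        assert res["residual"].ss == pytest.approx(8.0)
        assert res["residual"].df == 4
        assert res["condition"].f == pytest.approx(400.0)
        assert res["measurement"].f == pytest.approx(100.0)

    def test_all_equal_observations_zero_effect_ss(self):
        cells = {(a, b): (5.0, 5.0) for a in "xy" for b in "uv"}
        res = two_way_anova(self.table(cells))
        for eff in ("condition", "measurement", "condition:measurement"):
            assert res[eff].ss == pytest.approx(0.0, abs=1e-12)

    def test_scale_equivariance(self, rng):
        cells = {(a, b): tuple(rng.normal(size=3)) for a in "xyz" for b in "uv"}
        base = two_way_anova(self.table(cells))
        doubled = two_way_anova(
            self.table({k: tuple(2 * np.asarray(v)) for k, v in cells.items()})
        )
        for eff in ("condition", "measurement", "condition:measurement", "residual"):
            assert doubled[eff].ss == pytest.approx(4 * base[eff].ss, rel=1e-9)
        assert doubled["condition"].f == pytest.approx(base["condition"].f, rel=1e-9)

    def test_ss_decomposition(self, rng):
        cells = {(a, b): tuple(rng.normal(size=4)) for a in "pqr" for b in "uvw"}
        df = self.table(cells)
        res = two_way_anova(df)
        ss_total = float(((df.value - df.value.mean()) ** 2).sum())
        assert res.ss_total == pytest.approx(ss_total, rel=1e-9)

    def test_matches_statsmodels_reference(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        cells = {(a, b): tuple(rng.normal(loc=i, size=4)) for i, a in enumerate("pqr") for b in "uv"}
        df = self.table(cells)
        ours = two_way_anova(df)
        fit = ols("value ~ C(condition) * C(measurement)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        assert ours["condition"].ss == pytest.approx(ref.loc["C(condition)", "sum_sq"], rel=1e-8)
        assert ours["measurement"].ss == pytest.approx(ref.loc["C(measurement)", "sum_sq"], rel=1e-8)
        assert ours["condition:measurement"].ss == pytest.approx(
            ref.loc["C(condition):C(measurement)", "sum_sq"], rel=1e-8
        )
        assert ours["residual"].ss == pytest.approx(ref.loc["Residual", "sum_sq"], rel=1e-8)
        assert ours["condition"].p == pytest.approx(ref.loc["C(condition)", "PR(>F)"], rel=1e-6)

    def test_unbalanced_design_rejected(self):
        cells = {
            ("a1", "b1"): (10, 12, 13), ("a1", "b2"): (20, 22),
            ("a2", "b1"): (30, 32), ("a2", "b2"): (40, 42),
        }
        with pytest.raises(ValueError, match="balanced"):
            two_way_anova(self.table(cells))


class TestScheffe:
    def test_identical_means_not_significant(self):
        res = scheffe_posthoc({"a": 5.0, "b": 5.0}, {"a": 4, "b": 4}, 1.0, 6)
        assert res[0].statistic == 0.0 and not res[0].significant

    def test_separated_mean_detected(self):
        # k=3, n=5 each, means (0, 0, 5), MS_res=1: pair (a, c) stands out
        res = scheffe_posthoc({"a": 0.0, "b": 0.0, "c": 5.0}, dict.fromkeys("abc", 5), 1.0, 12)
        by_pair = {(r.group_i, r.group_j): r for r in res}
        ac = by_pair[("a", "c")]
        # statistic = 25 / (1 * 2/5) = 62.5; critical = 2 * F_crit(2, 12, .05)
        assert ac.statistic == pytest.approx(62.5)
        assert ac.critical_value == pytest.approx(2 * sps.f.isf(0.05, 2, 12))
        assert ac.significant and ac.p_value < 0.05
        assert not by_pair[("a", "b")].significant

    def test_all_pairs_reported(self):
        res = scheffe_posthoc(dict(enumerate(range(5))), dict.fromkeys(range(5), 3), 1.0, 10)
        assert len(res) == 5 * 4 // 2

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            scheffe_posthoc({"a": 1.0, "b": 2.0}, {"a": 3, "b": 3}, 1.0, 0)
        with pytest.raises(ValueError):
            scheffe_posthoc({"a": 1.0}, {"a": 3}, 1.0, 5)


class TestShapiroWilk:
    def test_normal_quantile_sample_high_w(self):
        x = sps.norm.ppf((np.arange(1, 21) - 0.5) / 20)
        res = shapiro_wilk(x)
        assert res.w > 0.95 and res.n == 20

    def test_bimodal_sample_rejected(self):
        x = np.concatenate([np.full(10, -10.0), np.full(10, 10.0)])
        x += np.linspace(-0.1, 0.1, 20)
        assert shapiro_wilk(x).p_value < 0.05

    def test_tiny_sample_is_an_error(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


def make_animal_table(group_means, n=6, sd=4.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for cond, mean in group_means.items():
        for a in range(n):
            shift = rng.normal(0, sd)
            for m in ("total", "type1", "type2b"):
                rows.append(
                    {
                        "animal_id": f"{cond}_{a}",
                        "condition": cond,
                        "measurement": m,
                        "normalized_pct": mean + shift + rng.normal(0, sd / 2),
                    }
                )
    return pd.DataFrame(rows)


class TestRunStudyStats:
    means = {"Control": 100.0, "4I": 60.5, "6I": 43.8, "8I": 24.3, "9I": 12.1}
    durations = {"Control": 0.0, "4I": 4.0, "6I": 6.0, "8I": 8.0, "9I": 9.0}

    def test_full_report_on_strong_effects(self):
        report = run_study_stats(make_animal_table(self.means), durations_h=self.durations)
        assert report.anova_kind == "two-way"
        assert report.anova["condition"].p < 0.001
        sig = {
            frozenset((r.group_i, r.group_j)) for r in report.posthoc if r.significant
        }
        for pair in [("Control", "4I"), ("4I", "6I"), ("6I", "8I"), ("8I", "9I")]:
            assert frozenset(pair) in sig
        assert report.correlation_per_animal.r < -0.9
        assert report.correlation_group_means.r < -0.97
        assert len(report.normality) == 15  # 5 groups x 3 measurements

    def test_single_measurement_uses_one_way(self):
        table = make_animal_table(self.means)
        table = table[table.measurement == "total"]
        report = run_study_stats(table, durations_h=self.durations)
        assert report.anova_kind == "one-way"

    def test_report_is_seed_reproducible_and_serializable(self):
        t = make_animal_table(self.means, seed=3)
        r1 = run_study_stats(t, durations_h=self.durations).to_dict()
        r2 = run_study_stats(t, durations_h=self.durations).to_dict()
        assert r1 == r2
        import json

        json.dumps(r1)  # schema must be JSON-stable

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            run_study_stats(pd.DataFrame())


def test_one_way_anova_matches_scipy():
    rng = np.random.default_rng(8)
    groups = [rng.normal(loc=i, size=6) for i in range(4)]
    values = np.concatenate(groups)
    labels = np.repeat(list("abcd"), 6)
    res = one_way_anova(pd.Series(values), pd.Series(labels))
    f, p = sps.f_oneway(*groups)
    assert res["condition"].f == pytest.approx(f, rel=1e-10)
    assert res["condition"].p == pytest.approx(p, rel=1e-8)
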