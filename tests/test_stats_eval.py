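"""Descriptives, one-way ANOVA, Bonferroni post hoc, fits, correlation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from rootquant.errors import ValidationError
from rootquant.stats_eval import (
    GroupSummary,
    anova_from_summaries,
    anova_raw,
    bonferroni_pairwise,
    descriptives,
    fit_polynomial,
    model_report,
    pearson,
    summarize_groups,
)

group_strategy = st.lists(
    st.lists(st.floats(-50, 50, allow_nan=False, width=32), min_size=3, max_size=12),
    min_size=2, max_size=6,
)


class TestDescriptives:
    def test_constant_group(self):
        rows = descriptives({1: [5, 5, 5]})
        assert rows[0].mean == 5 and rows[0].sd == 0 and rows[0].value_range == 0

    def test_two_point_group_hand_formula(self):
        s = descriptives({1: [1, 3]})[0]
        assert s.mean == 2
        assert s.sd == pytest.approx(math.sqrt(2))
        assert s.value_range == 2

    def test_pooled_total_row(self):
        groups = {c: list(range(30)) for c in range(1, 7)}
        rows = descriptives(groups)
        total = rows[-1]
        assert total.group == "Total"
        assert total.n == 180

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            descriptives({1: []})


class TestAnovaRaw:
    def test_identical_means_give_zero_between(self):
        table = anova_raw([[1, 2, 3], [1, 2, 3]])
        assert table.ss_between == pytest.approx(0, abs=1e-12)
        assert table.F == pytest.approx(0, abs=1e-12)

    def test_hand_computed_decomposition(self):
        table = anova_raw([[1, 2, 3], [4, 5, 6]])
        assert table.ss_between == pytest.approx(13.5)
        assert table.ss_within == pytest.approx(4.0)
        assert table.df_between == 1 and table.df_within == 4
        assert table.F == pytest.approx(13.5)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        groups = [list(rng.normal(m, 2, 12)) for m in (0, 1, 3)]
        table = anova_raw(groups)
        ref = sps.f_oneway(*groups)
        assert table.F == pytest.approx(ref.statistic, rel=1e-12)
        assert table.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_all_identical_values_flagged_infinite_or_zero_f(self):
        assert anova_raw([[1, 1], [1, 1]]).F == 0.0
        assert anova_raw([[1, 1], [2, 2]]).F == math.inf


class TestAnovaFromSummaries:
    def test_equivalent_to_raw_on_seeded_data(self):
        rng = np.random.default_rng(99)
        groups = [list(rng.normal(m, s, n)) for m, s, n in
                  ((0, 1, 8), (2, 2, 15), (5, 1.5, 11), (1, 3, 9))]
        raw = anova_raw(groups)
        summ = anova_from_summaries(
            summarize_groups({i: g for i, g in enumerate(groups)}))
        assert summ.ss_between == pytest.approx(raw.ss_between, rel=1e-9)
        assert summ.ss_within == pytest.approx(raw.ss_within, rel=1e-9)
        assert summ.F == pytest.approx(raw.F, rel=1e-9)
        assert (summ.df_between, summ.df_within) == (raw.df_between, raw.df_within)

    def test_identical_summaries_give_zero_f(self):
        s = GroupSummary(group=1, n=10, mean=4.0, sd=1.0)
        t = GroupSummary(group=2, n=10, mean=4.0, sd=1.0)
        assert anova_from_summaries([s, t]).F == pytest.approx(0, abs=1e-12)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValidationError):
            GroupSummary(group=1, n=1, mean=0.0, sd=0.0)

    @settings(deadline=None, max_examples=40)
    @given(groups=group_strategy)
    def test_summary_route_always_matches_raw_route(self, groups):
        raw = anova_raw(groups)
        summ = anova_from_summaries(
            summarize_groups({i: g for i, g in enumerate(groups)}))
        if math.isfinite(raw.F):
            assert summ.F == pytest.approx(raw.F, rel=1e-9, abs=1e-9)
        assert summ.ss_total == pytest.approx(raw.ss_total, rel=1e-9, abs=1e-9)


class TestBonferroniPairwise:
    def test_identical_groups_nothing_significant(self):
        groups = {i: [1.0, 2.0, 3.0] for i in range(4)}
        assert bonferroni_pairwise(groups).n_significant == 0

    def test_six_groups_give_15_comparisons(self):
        summaries = [GroupSummary(group=i, n=30, mean=float(i), sd=1.0)
                     for i in range(1, 7)]
        table = bonferroni_pairwise(summaries)
        assert table.n_comparisons == 15
        assert table.method == "Bonferroni"

    def test_mean_difference_antisymmetric_relabeling_invariant(self):
        rng = np.random.default_rng(3)
        groups = {i: list(rng.normal(i, 1, 10)) for i in range(4)}
        fwd = bonferroni_pairwise(groups)
        rev = bonferroni_pairwise(dict(reversed(list(groups.items()))))
        assert fwd.n_significant == rev.n_significant
        diffs = {frozenset((c.group_i, c.group_j)): abs(c.mean_difference)
                 for c in fwd.comparisons}
        for c in rev.comparisons:
            assert diffs[frozenset((c.group_i, c.group_j))] == pytest.approx(
                abs(c.mean_difference))

    def test_flags_match_brute_force_pooled_t(self):
        rng = np.random.default_rng(17)
        groups = {i: list(rng.normal(2 * i, 3, 10)) for i in range(4)}
        table = bonferroni_pairwise(groups)
        # independent recomputation: pooled-variance t for each pair with
        # the pooled within-group df, p times the number of comparisons
        arrays = {i: np.asarray(v) for i, v in groups.items()}
        n_total = sum(a.size for a in arrays.values())
        df_w = n_total - len(arrays)
        ms_w = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_w
        m = len(arrays) * (len(arrays) - 1) // 2
        for comp in table.comparisons:
            ai, aj = arrays[comp.group_i], arrays[comp.group_j]
            tstat = (ai.mean() - aj.mean()) / math.sqrt(
                ms_w * (1 / ai.size + 1 / aj.size))
            p_adj = min(1.0, 2 * sps.t.sf(abs(tstat), df_w) * m)
            assert comp.significant == (p_adj < 0.05)
            assert comp.t_statistic == pytest.approx(tstat, rel=1e-12)

    def test_zero_variance_nonzero_differences_significant(self):
        groups = {1: [1.0, 1.0], 2: [2.0, 2.0]}
        table = bonferroni_pairwise(groups)
        (comp,) = table.comparisons
        assert comp.significant and comp.p_adjusted == 0.0


class TestFitPolynomial:
    def test_exact_cubic_recovered(self):
        x = np.linspace(0, 10, 20)
        y = 1 + 2 * x - 0.3 * x**2 + 0.05 * x**3
        fit = fit_polynomial(x, y, 3)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.coefficients == pytest.approx((1, 2, -0.3, 0.05), abs=1e-8)

    def test_constant_y_gives_zero_r_squared(self):
        fit = fit_polynomial([1, 2, 3, 4, 5], [7, 7, 7, 7, 7], 1)
        assert fit.r_squared == 0.0

    def test_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 30, 40)
        y = 2 + 0.5 * x - 0.01 * x**2 + 0.0005 * x**3 + rng.normal(0, 0.5, 40)
        fit = fit_polynomial(x, y, 3)
        design = np.vander(x, 4, increasing=True)
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert fit.coefficients == pytest.approx(tuple(beta), abs=1e-8)

    def test_r_squared_non_decreasing_in_degree(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(0, 50, 60)
        y = 1 + 0.1 * x + rng.normal(0, 1, 60)
        r2 = [fit_polynomial(x, y, d).r_squared for d in (1, 2, 3)]
        assert r2[0] <= r2[1] + 1e-12 and r2[1] <= r2[2] + 1e-12

    def test_constant_x_rejected(self):
        with pytest.raises(ValidationError):
            fit_polynomial([2, 2, 2, 2, 2], [1, 2, 3, 4, 5], 1)


class TestPearson:
    def test_perfect_linear(self):
        x = [1, 2, 3, 4]
        assert pearson(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_matches_hand_formula(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(0, 1, 25), rng.normal(0, 1, 25)
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert pearson(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            pearson([1, 1, 1], [1, 2, 3])


class TestModelReport:
    def _inputs(self, seed_a=0, seed_b=0):
        out_fits, out_pw = {}, {}
        for name, seed in (("thresholding", seed_a), ("machine_learning", seed_b)):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 50, 60)
            y = np.clip(np.round(x / 10) + rng.integers(0, 2, 60), 1, 6)
            out_fits[name] = {d: fit_polynomial(x, y, d) for d in (1, 2, 3)}
            groups = {c: list(rng.normal(5 * c, 2, 10)) for c in range(1, 5)}
            out_pw[name] = bonferroni_pairwise(groups)
        return out_fits, out_pw

    def test_identical_inputs_give_identical_columns(self):
        fits, pw = self._inputs(seed_a=4, seed_b=4)
        table = model_report(fits, pw)
        assert (table["thresholding"] == table["machine_learning"]).all()

    def test_exactly_four_performance_rows(self):
        fits, pw = self._inputs()
        table = model_report(fits, pw)
        assert list(table.index) == ["R2 linear", "R2 quadratic", "R2 cubic",
                                     "Significant"]
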