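"""Evaluation statistics for colonization indices.

Implements the statistical layer used to compare an automated index
(t or ml) against visual class scoring over a six-class study design:

* per-class descriptives (n, mean, sample SD, range);
* classical one-way ANOVA, either from raw per-image values or
  reconstructed from printed group summaries (n, mean, SD), since
  ``SS_within = sum (n_i - 1) s_i^2`` and
  ``SS_between = sum n_i (m_i - grand_mean)^2`` need no raw data;
* Bonferroni-adjusted pairwise post-hoc comparisons using the pooled
  within-group mean square;
* polynomial regression (degrees 1–3) of visual class score on index
  value, with R^2; and Pearson correlation;
* a model-comparison report juxtaposing both methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "GroupSummary",
    "AnovaTable",
    "PairwiseComparison",
    "PairwiseTable",
    "PolynomialFit",
    "descriptives",
    "summarize_groups",
    "anova_raw",
    "anova_from_summaries",
    "bonferroni_pairwise",
    "fit_polynomial",
    "pearson",
    "model_report",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-class summary: n, mean, sample SD (n-1 denominator), range."""

    group: int | str
    n: int
    mean: float
    sd: float
    value_range: float | None = None

    def __post_init__(self):
        if self.n < 2:
            raise ValidationError(f"group {self.group}: need n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValidationError(f"group {self.group}: negative SD")


@dataclass(frozen=True)
class AnovaTable:
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    F: float
    p: float

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within

    @property
    def df_total(self) -> int:
        return self.df_between + self.df_within

    @property
    def ms_between(self) -> float:
        return self.ss_between / self.df_between

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within if self.df_within else math.nan

    def as_text(self) -> str:
        rows = [
            ("Between groups", self.ss_between, self.df_between, self.ms_between),
            ("Within groups", self.ss_within, self.df_within, self.ms_within),
            ("Total", self.ss_total, self.df_total, None),
        ]
        lines = [f"{'Variance':<16}{'SS':>12}{'df':>6}{'MS':>12}{'F':>10}{'p':>10}"]
        for i, (name, ss, df, ms) in enumerate(rows):
            ms_s = f"{ms:12.2f}" if ms is not None else " " * 12
            tail = f"{self.F:10.2f}{self.p:10.4g}" if i == 0 else ""
            lines.append(f"{name:<16}{ss:12.2f}{df:6d}{ms_s}{tail}")
        return "\n".join(lines)


@dataclass(frozen=True)
class PairwiseComparison:
    group_i: int | str
    group_j: int | str
    mean_difference: float
    t_statistic: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class PairwiseTable:
    comparisons: tuple
    method: str = "Bonferroni"
    alpha: float = 0.05

    @property
    def n_significant(self) -> int:
        return sum(c.significant for c in self.comparisons)

    @property
    def n_comparisons(self) -> int:
        return len(self.comparisons)


@dataclass(frozen=True)
class PolynomialFit:
    """y = a + b1 x + ... up to the given degree; coefficients ascending."""

    degree: int
    coefficients: tuple
    r_squared: float

    def __post_init__(self):
        if len(self.coefficients) != self.degree + 1:
            raise ValidationError("coefficient count must be degree + 1")

    def predict(self, x) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, float),
                                                self.coefficients)


def descriptives(groups: dict) -> list[GroupSummary]:
    """Per-group n/mean/SD/range plus a pooled 'Total' row.

    ``groups`` maps group id to a sequence of values; every group must be
    non-empty (and have n >= 2 for a defined sample SD).
    """
    out = []
    pooled = []
    for gid, values in groups.items():
        values = np.asarray(list(values), dtype=float)
        if values.size == 0:
            raise ValidationError(f"group {gid} is empty")
        out.append(GroupSummary(
            group=gid,
            n=int(values.size),
            mean=float(values.mean()),
            sd=float(values.std(ddof=1)),
            value_range=float(values.max() - values.min()),
        ))
        pooled.extend(values)
    pooled = np.asarray(pooled)
    out.append(GroupSummary(
        group="Total",
        n=int(pooled.size),
        mean=float(pooled.mean()),
        sd=float(pooled.std(ddof=1)),
        value_range=float(pooled.max() - pooled.min()),
    ))
    return out


def summarize_groups(groups: dict) -> list[GroupSummary]:
    """Per-group summaries only (no pooled row), for ANOVA reconstruction."""
    return [s for s in descriptives(groups) if s.group != "Total"]


def _finish_table(ss_b: float, ss_w: float, df_b: int, df_w: int) -> AnovaTable:
    ms_b = ss_b / df_b
    if ss_w == 0.0:
        # all values identical within groups: infinite F unless means equal too
        F = math.inf if ss_b > 0 else 0.0
        p = 0.0 if ss_b > 0 else 1.0
    else:
        ms_w = ss_w / df_w
        F = ms_b / ms_w
        p = float(sps.f.sf(F, df_b, df_w))
    return AnovaTable(ss_between=ss_b, ss_within=ss_w,
                      df_between=df_b, df_within=df_w, F=F, p=p)


def anova_raw(groups) -> AnovaTable:
    """Classical one-way ANOVA from raw per-group value lists."""
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("need >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValidationError("each group needs n >= 2")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_b = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ss_w = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_b = len(arrays) - 1
    df_w = int(all_vals.size) - len(arrays)
    return _finish_table(ss_b, ss_w, df_b, df_w)


def anova_from_summaries(summaries) -> AnovaTable:
    """One-way ANOVA reconstructed from (n, mean, SD) group summaries.

    Exact when the summaries are exact; with summaries printed to 2
    decimals the reconstructed table agrees with the raw-data table to
    within the propagation of that rounding (about 1 % relative).
    """
    summaries = list(summaries)
    if len(summaries) < 2:
        raise ValidationError("need >= 2 group summaries")
    N = sum(s.n for s in summaries)
    grand = sum(s.n * s.mean for s in summaries) / N
    ss_b = float(sum(s.n * (s.mean - grand) ** 2 for s in summaries))
    ss_w = float(sum((s.n - 1) * s.sd ** 2 for s in summaries))
    df_b = len(summaries) - 1
    df_w = N - len(summaries)
    return _finish_table(ss_b, ss_w, df_b, df_w)


def bonferroni_pairwise(groups_or_summaries, alpha: float = 0.05) -> PairwiseTable:
    """All-pairs post hoc with Bonferroni family-wise correction.

    Accepts either raw value lists (dict id -> values) or a list of
    :class:`GroupSummary`.  Each pair is tested with
    ``t = (m_i - m_j) / sqrt(MS_within (1/n_i + 1/n_j))`` on the pooled
    within-group df; the two-sided p is multiplied by the number of
    comparisons and capped at 1.  If MS_within is exactly 0, any nonzero
    mean difference is flagged significant with p = 0.
    """
    if isinstance(groups_or_summaries, dict):
        summaries = summarize_groups(groups_or_summaries)
        table = anova_raw(list(groups_or_summaries.values()))
    else:
        summaries = list(groups_or_summaries)
        table = anova_from_summaries(summaries)
    m = len(summaries) * (len(summaries) - 1) // 2
    ms_w = table.ms_within
    comps = []
    for si, sj in combinations(summaries, 2):
        diff = si.mean - sj.mean
        if table.ss_within == 0.0:
            tstat = math.inf if diff != 0 else 0.0
            p_adj = 0.0 if diff != 0 else 1.0
        else:
            se = math.sqrt(ms_w * (1.0 / si.n + 1.0 / sj.n))
            tstat = diff / se
            p_raw = 2.0 * float(sps.t.sf(abs(tstat), table.df_within))
            p_adj = min(1.0, p_raw * m)
        comps.append(PairwiseComparison(
            group_i=si.group, group_j=sj.group,
            mean_difference=diff, t_statistic=tstat,
            p_adjusted=p_adj, significant=p_adj < alpha,
        ))
    return PairwiseTable(comparisons=tuple(comps), alpha=alpha)


def fit_polynomial(x, y, degree: int) -> PolynomialFit:
    """Least-squares polynomial fit of class score y on index value x.

    R^2 = 1 - SS_res / SS_tot with SS_tot about the mean of y; a constant
    y yields R^2 = 0 by convention.
    """
    if degree not in (1, 2, 3):
        raise ValidationError("degree must be 1, 2, or 3")
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size <= degree + 1:
        raise ValidationError(f"need n > degree + 1 = {degree + 1} points")
    if np.ptp(x) == 0:
        raise ValidationError("all x values identical: rank-deficient design")
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    resid = y - np.polynomial.polynomial.polyval(x, coeffs)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return PolynomialFit(degree=degree, coefficients=tuple(coeffs), r_squared=r2)


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equally sized samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant input has undefined correlation")
    return float(sps.pearsonr(x, y).statistic)


def model_report(fits_by_method: dict, pairwise_by_method: dict) -> "pd.DataFrame":
    """Side-by-side performance table for the two methods.

    ``fits_by_method`` maps method name -> {degree: PolynomialFit} (degrees
    1–3); ``pairwise_by_method`` maps method name -> PairwiseTable.  Rows:
    R^2 linear / quadratic / cubic and the significant-pair count "k/m".
    """
    import pandas as pd

    methods = list(fits_by_method)
    if set(pairwise_by_method) != set(methods):
        raise ValidationError("fits and pairwise tables must cover the same methods")
    rows = {}
    for label, degree in (("R2 linear", 1), ("R2 quadratic", 2), ("R2 cubic", 3)):
        rows[label] = [round(fits_by_method[m][degree].r_squared, 3) for m in methods]
    rows["Significant"] = [
        f"{pairwise_by_method[m].n_significant}/{pairwise_by_method[m].n_comparisons}"
        for m in methods
    ]
    return pd.DataFrame(rows, index=methods).T
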