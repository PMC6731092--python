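"""Inferential tests for group comparisons.

Three tests cover the population comparisons in the loop-mapping analyses:

* pooled two-proportion z-test for responsive-neuron percentages (no
  continuity correction; ``z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2))`` with
  the pooled ``p``),
* unpaired Student's t-test with pooled variance, computable either from raw
  per-neuron values or directly from printed ``mean +/- SEM, n`` summaries,
* two-way fixed-effects ANOVA with interaction, Type III sums of squares by
  default (matching the GraphPad Prism convention on unbalanced designs),
  delegated to a statsmodels OLS fit with sum-coded factors.

Test statistics are reported as absolute values with two-sided p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ProportionPair",
    "GroupSummary",
    "StatTestResult",
    "two_proportion_z",
    "pooled_t_from_summary",
    "pooled_t_from_raw",
    "two_way_anova",
]


@dataclass(frozen=True)
class ProportionPair:
    """Responsive counts ``x`` out of totals ``n`` for two groups."""

    x1: int
    n1: int
    x2: int
    n2: int

    def __post_init__(self) -> None:
        for x, n in ((self.x1, self.n1), (self.x2, self.n2)):
            if n < 1:
                raise ValueError("group total must be >= 1")
            if not 0 <= x <= n:
                raise ValueError("count must satisfy 0 <= x <= n")


@dataclass(frozen=True)
class GroupSummary:
    """Printed-figure group summary: mean, SEM and n."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be non-negative")
        if self.n < 2:
            raise ValueError("need n >= 2")

    @staticmethod
    def from_values(values) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        return GroupSummary(mean=float(arr.mean()),
                            sem=float(arr.std(ddof=1) / np.sqrt(arr.size)),
                            n=int(arr.size))


@dataclass(frozen=True)
class StatTestResult:
    """A named test with its statistic, degrees of freedom, and two-sided p."""

    name: str
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def two_proportion_z(pair: ProportionPair) -> StatTestResult:
    """Pooled two-proportion z-test without continuity correction."""
    p_hat = (pair.x1 + pair.x2) / (pair.n1 + pair.n2)
    if p_hat in (0.0, 1.0):
        raise ValueError("pooled proportion is degenerate (0 or 1); z undefined")
    se = np.sqrt(p_hat * (1.0 - p_hat) * (1.0 / pair.n1 + 1.0 / pair.n2))
    z = abs(pair.x1 / pair.n1 - pair.x2 / pair.n2) / se
    return StatTestResult("two-proportion z-test", float(z), None,
                          float(2.0 * sps.norm.sf(z)))


def pooled_t_from_summary(g1: GroupSummary, g2: GroupSummary) -> StatTestResult:
    """Unpaired Student's t-test reconstructed from (mean, SEM, n) summaries.

    SD is recovered as ``SEM * sqrt(n)``; the pooled variance uses the usual
    ``(n-1)``-weighted average.  The statistic is reported as ``|t|`` with
    ``df = n1 + n2 - 2``.
    """
    if g1.n + g2.n < 3:
        raise ValueError("need at least 3 observations in total")
    sd1 = g1.sem * np.sqrt(g1.n)
    sd2 = g2.sem * np.sqrt(g2.n)
    df = g1.n + g2.n - 2
    pooled_var = ((g1.n - 1) * sd1**2 + (g2.n - 1) * sd2**2) / df
    denom = np.sqrt(pooled_var * (1.0 / g1.n + 1.0 / g2.n))
    if denom == 0:
        if g1.mean == g2.mean:
            return StatTestResult("unpaired t-test (pooled)", 0.0, df, 1.0)
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t = abs(g1.mean - g2.mean) / denom
    return StatTestResult("unpaired t-test (pooled)", float(t), df,
                          float(2.0 * sps.t.sf(t, df)))


def pooled_t_from_raw(x1, x2) -> StatTestResult:
    """Unpaired Student's t-test from raw per-observation values."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each group needs at least two observations")
    return pooled_t_from_summary(GroupSummary.from_values(x1),
                                 GroupSummary.from_values(x2))


def two_way_anova(
    data: pd.DataFrame,
    a: str,
    b: str,
    value: str,
    ss_type: int = 3,
) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA with interaction.

    ``data`` holds one observation per row with factor columns ``a`` and
    ``b``.  Returns the ANOVA table with rows (A, B, A:B, Residual) and
    columns ``sum_sq, df, mean_sq, F, p``.  Type III sums of squares (on
    sum-coded contrasts) are the default, matching common GUI statistics
    packages on unbalanced designs; Type I and II are available via
    ``ss_type``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if ss_type not in (1, 2, 3):
        raise ValueError("ss_type must be 1, 2 or 3")
    df = data[[a, b, value]].rename(columns={a: "_A", b: "_B", value: "_y"}).copy()
    cells = df.groupby(["_A", "_B"], observed=True).size()
    n_a = df["_A"].nunique()
    n_b = df["_B"].nunique()
    if len(cells) < n_a * n_b or (cells < 1).any():
        raise ValueError("every factor-level combination needs at least one observation")
    resid_df = len(df) - n_a * n_b
    if resid_df <= 0:
        raise ValueError("residual degrees of freedom is zero; no error term")
    model = smf.ols("_y ~ C(_A, Sum) * C(_B, Sum)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=ss_type)
    table = table.rename(
        index={
            "C(_A, Sum)": "A",
            "C(_B, Sum)": "B",
            "C(_A, Sum):C(_B, Sum)": "A:B",
        },
        columns={"PR(>F)": "p"},
    )
    if "Intercept" in table.index:
        table = table.drop(index="Intercept")
    table = table.loc[["A", "B", "A:B", "Residual"], ["sum_sq", "df", "F", "p"]]
    table.insert(2, "mean_sq", table["sum_sq"] / table["df"])
    return table
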