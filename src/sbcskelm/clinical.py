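"""Cohort-level statistics: 2x2 chi-square tests and two-sample t-tests.

Categorical features are compared between the two risk groups with the
Pearson chi-square on a 2x2 table; following common clinical-software
reporting practice, the Yates continuity correction is applied
automatically when the smallest expected cell count is below 5 (an
override flag is provided). Continuous features are compared with the
independent two-sample t-test, either pooled-variance (Student) or
unpooled (Welch, the default), computable from raw data or from printed
group summaries (n, mean, sample SD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "GroupSummary",
    "TestResult",
    "chi_square_2x2",
    "t_test_from_summary",
    "cohort_report",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts laid out (group1-No, group1-Yes; group2-No, group2-Yes)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and sample standard deviation of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    corrected: bool = False  # chi-square: Yates applied
    variant: str = ""  # t-test: 'pooled' or 'welch'


def chi_square_2x2(table: ContingencyTable2x2, auto_correct: bool = True) -> TestResult:
    """Pearson chi-square on a 2x2 table, df = 1.

    With ``auto_correct`` the Yates correction sum((|O-E| - 0.5)^2 / E)
    replaces the plain Pearson statistic when the minimum expected cell
    count is below 5.
    """
    obs = table.as_array()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal total")
    expected = np.outer(row, col) / n
    corrected = bool(auto_correct and expected.min() < 5)
    dev = np.abs(obs - expected)
    if corrected:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float(np.sum(dev**2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return TestResult(statistic=chi2, df=1.0, p=p, corrected=corrected)


def t_test_from_summary(
    g1: GroupSummary, g2: GroupSummary, variant: str = "welch"
) -> TestResult:
    """Two-sided independent t-test from group summaries.

    ``pooled`` is the classic Student test with df n1+n2-2; ``welch``
    uses unpooled variances and Welch-Satterthwaite df. Two groups with
    zero spread and equal means return t = 0, p = 1 by convention.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if g1.sd == 0 and g2.sd == 0:
        if g1.mean == g2.mean:
            return TestResult(0.0, float(g1.n + g2.n - 2), 1.0, variant=variant)
        return TestResult(np.inf, float(g1.n + g2.n - 2), 0.0, variant=variant)
    res = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=(variant == "pooled")
    )
    df = float(res.df) if hasattr(res, "df") else float(g1.n + g2.n - 2)
    return TestResult(
        statistic=float(res.statistic), df=df, p=float(res.pvalue), variant=variant
    )


def _is_binary(series: pd.Series) -> bool:
    vals = pd.unique(series.dropna())
    return set(np.asarray(vals).tolist()) <= {0, 1, 0.0, 1.0}


def cohort_report(
    data: pd.DataFrame,
    group_column: str = "risk_group",
    t_variant: str = "welch",
    auto_correct: bool = True,
) -> pd.DataFrame:
    """Per-feature between-group tests for a two-group cohort table.

    Binary {0,1} columns get the chi-square (with the auto correction
    rule), other numeric columns the t-test; per-group summaries are
    emitted alongside. Constant columns are flagged and skipped.
    """
    if group_column not in data.columns:
        raise ValueError(f"missing group column {group_column!r}")
    groups = np.sort(data[group_column].unique())
    if groups.shape[0] != 2:
        raise ValueError("group column must have exactly 2 levels")
    # Clinical convention: the lower-risk stratum is the reference group.
    order = (
        ["low", "high"] if set(groups) == {"low", "high"} else list(groups)
    )
    g1 = data[data[group_column] == order[0]]
    g2 = data[data[group_column] == order[1]]

    rows = []
    for col in data.columns:
        if col == group_column:
            continue
        x1, x2 = g1[col], g2[col]
        if data[col].nunique() < 2:
            rows.append(
                {"feature": col, "test": "skipped", "statistic": np.nan,
                 "p": np.nan, "detail": "constant feature"}
            )
            continue
        if _is_binary(data[col]):
            table = ContingencyTable2x2(
                a=int((x1 == 0).sum()), b=int((x1 == 1).sum()),
                c=int((x2 == 0).sum()), d=int((x2 == 1).sum()),
            )
            res = chi_square_2x2(table, auto_correct=auto_correct)
            rows.append(
                {
                    "feature": col,
                    "test": "chi-square" + (" (Yates)" if res.corrected else ""),
                    "statistic": res.statistic,
                    "p": res.p,
                    "detail": f"{table.a}/{table.b} vs {table.c}/{table.d}",
                }
            )
        else:
            s1 = GroupSummary(len(x1), float(x1.mean()), float(x1.std(ddof=1)))
            s2 = GroupSummary(len(x2), float(x2.mean()), float(x2.std(ddof=1)))
            res = t_test_from_summary(s1, s2, variant=t_variant)
            rows.append(
                {
                    "feature": col,
                    "test": f"t-test ({t_variant})",
                    "statistic": res.statistic,
                    "p": res.p,
                    "detail": (
                        f"{s1.mean:.2f} ± {s1.sd:.3f} vs {s2.mean:.2f} ± {s2.sd:.3f}"
                    ),
                }
            )
    return pd.DataFrame(rows)
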