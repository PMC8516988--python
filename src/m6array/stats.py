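"""Correlation and cohort-characteristics statistics.

Covers the small-sample association analyses around the array study:
Pearson correlation between a transcript's methylation level and a
regulator's expression (with an exact t-distribution p-value, appropriate at
n of ten per group), a two-sample t-test computable from printed summary
statistics (mean +/- SD and n per group), and a 2x2 Pearson chi-square for
categorical cohort contrasts such as the sex ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class CohortSummary:
    """One group's printed characteristics: n, age mean +/- SD, sex counts."""

    n: int
    age_mean: float
    age_sd: float
    n_female: int
    n_male: int

    def __post_init__(self) -> None:
        if self.n_female + self.n_male != self.n:
            raise ValueError("n_female + n_male must equal n")


def pearson_correlation(x, y) -> CorrelationResult:
    """Sample Pearson r with a two-sided p from the t-transform on n-2 df.

    The p-value uses ``t = r * sqrt((n-2) / (1-r^2))`` against Student's t —
    exact under bivariate normality and preferable to a normal approximation
    at the sample sizes involved here. Zero variance in either argument is an
    error (the correlation is undefined), as is n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least three paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    xd, yd = x - x.mean(), y - y.mean()
    sxx, syy = float(xd @ xd), float(yd @ yd)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("correlation undefined: zero variance in an argument")
    r = float(xd @ yd / np.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return CorrelationResult(r=r, p=0.0, n=n)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, p=p, n=n)


def t_test_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "student",
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test from summary statistics; returns (t, df, p).

    Lets published group summaries (mean +/- SD, n) be re-tested without raw
    data. Pooled-variance by default; ``variant='welch'`` for the
    unequal-variance form. Two identical degenerate summaries (both SDs zero,
    equal means) give p = 1; zero SDs with unequal means give p = 0.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if sd1 == 0.0 and sd2 == 0.0:
        df = float(n1 + n2 - 2)
        if mean1 == mean2:
            return 0.0, df, 1.0
        return float("inf") * np.sign(mean1 - mean2), df, 0.0
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=variant == "student"
    )
    if variant == "student":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def chi_square_2x2(
    a: int, b: int, c: int, d: int, continuity: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]]; returns (chi2, p).

    One degree of freedom; Yates continuity correction optional (off by
    default). All four margins must be positive.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a table margin is zero")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=continuity)
    return float(chi2), float(p)


def compare_cohorts(group_n: CohortSummary, group_t: CohortSummary,
                    sex_test: str = "chi2") -> dict[str, float]:
    """Table-1-style cohort comparison: age t-test and sex-ratio test.

    ``sex_test='chi2'`` (default) runs the Pearson chi-square without
    continuity correction; ``'ttest'`` instead t-tests 0/1 sex codes, for
    fidelity to reports that analyse everything by t-test.
    """
    _, _, p_age = t_test_from_summary(
        group_n.age_mean, group_n.age_sd, group_n.n,
        group_t.age_mean, group_t.age_sd, group_t.n,
    )
    if sex_test == "chi2":
        _, p_sex = chi_square_2x2(
            group_n.n_female, group_t.n_female, group_n.n_male, group_t.n_male
        )
    elif sex_test == "ttest":
        codes_n = [1.0] * group_n.n_female + [0.0] * group_n.n_male
        codes_t = [1.0] * group_t.n_female + [0.0] * group_t.n_male
        from .differential import unpaired_t_test

        _, _, p_sex = unpaired_t_test(codes_n, codes_t)
    else:
        raise ValueError(f"unknown sex_test {sex_test!r}")
    return {"p_age": p_age, "p_sex": p_sex}
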