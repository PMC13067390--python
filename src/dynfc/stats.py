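"""Group-comparison statistics for sex-difference tables.

Covers the machinery behind the cohort tables: independent-samples t-tests
(Student pooled or Welch, one- or two-sided), Mann-Whitney U, Cohen's d with
a 95% CI, chi-square balance tests, the Spearman-Brown step-up for the
reliability of a two-session average, and Bonferroni screening.  Group 1 is
males and group 2 females everywhere, so differences read "males - females".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Mann-Whitney switches to exact enumeration at or below this product
EXACT_U_MAX_PRODUCT = 400


@dataclass
class GroupSummary:
    """Printed-table summary of one group: N, mean, SD (and optional median)."""

    n: int
    mean: float
    sd: float
    median: float | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group n must be at least 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass
class ComparisonResult:
    t: float
    df: float
    p_t: float
    test_variant: str  # "student" | "welch"
    sidedness: str  # "two-sided" | "less" | "greater"
    d: float | None = None
    d_ci_low: float | None = None
    d_ci_high: float | None = None
    u: float | None = None
    u_p: float | None = None


def cohens_d(
    n1: int, m1: float, s1: float, n2: int, m2: float, s2: float
) -> tuple[float, float, float]:
    """Cohen's d with pooled SD and a normal-approximation 95% CI.

    d = (m1 - m2)/s_p with s_p^2 = ((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2);
    CI = d +/- 1.96 * sqrt((n1+n2)/(n1*n2) + d^2/(2*(n1+n2))).
    Returns (d, ci_low, ci_high).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled SD: effect size undefined")
    d = (m1 - m2) / np.sqrt(sp2)
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    return float(d), float(d - 1.96 * se), float(d + 1.96 * se)


def cohens_d_from_samples(x, y) -> tuple[float, float, float]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return cohens_d(x.size, x.mean(), x.std(ddof=1), y.size, y.mean(), y.std(ddof=1))


def _resolve_variant(x, y, variant: str) -> str:
    if variant in ("student", "welch"):
        return variant
    if variant != "auto":
        raise ValueError(f"unknown t-test variant: {variant}")
    # Levene's test at p < .05 triggers Welch; with summaries only, caller
    # must pick the variant explicitly
    _, p_lev = sps.levene(x, y)
    return "welch" if p_lev < 0.05 else "student"


def t_test(
    x=None,
    y=None,
    *,
    summary1: GroupSummary | None = None,
    summary2: GroupSummary | None = None,
    variant: str = "auto",
    sidedness: str = "two-sided",
) -> ComparisonResult:
    """Independent-samples t-test from raw samples or printed summaries.

    ``variant``: "student" (pooled variance, df = n1+n2-2), "welch"
    (Satterthwaite df), or "auto" (Levene's test at p < .05 switches to
    Welch; samples required).  ``sidedness``: "two-sided", or "less"/
    "greater" for the one-sided alternative that group 1 (males) is
    smaller/larger.
    """
    if sidedness not in ("two-sided", "less", "greater"):
        raise ValueError("sidedness must be two-sided, less, or greater")
    if summary1 is not None and summary2 is not None:
        if variant == "auto":
            raise ValueError("summaries require an explicit student/welch variant")
        res = sps.ttest_ind_from_stats(
            summary1.mean, summary1.sd, summary1.n,
            summary2.mean, summary2.sd, summary2.n,
            equal_var=(variant == "student"),
            alternative=sidedness,
        )
        n1, n2 = summary1.n, summary2.n
        s1, s2 = summary1.sd, summary2.sd
    else:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            raise ValueError("zero variance in both groups")
        variant = _resolve_variant(x, y, variant)
        res = sps.ttest_ind(x, y, equal_var=(variant == "student"), alternative=sidedness)
        n1, n2 = x.size, y.size
        s1, s2 = x.std(ddof=1), y.std(ddof=1)
    if variant == "student":
        df = n1 + n2 - 2
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return ComparisonResult(
        t=float(res.statistic), df=float(df), p_t=float(res.pvalue),
        test_variant=variant, sidedness=sidedness,
    )


def _exact_u_p(x: np.ndarray, y: np.ndarray, u_obs: float, sidedness: str) -> float:
    """Enumerate all rank assignments (permutation distribution of U)."""
    pooled = np.concatenate([x, y])
    n1 = x.size
    idx = range(pooled.size)
    u_vals = []
    for comb in combinations(idx, n1):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(comb)] = True
        xa, ya = pooled[mask], pooled[~mask]
        u = sum(np.sum(xi > ya) + 0.5 * np.sum(xi == ya) for xi in xa)
        u_vals.append(u)
    u_vals = np.asarray(u_vals)
    if sidedness == "greater":
        return float(np.mean(u_vals >= u_obs))
    if sidedness == "less":
        return float(np.mean(u_vals <= u_obs))
    return float(min(1.0, 2 * min(np.mean(u_vals >= u_obs), np.mean(u_vals <= u_obs))))


def mann_whitney_u(x, y, sidedness: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U with exact enumeration for small samples.

    Exact when n1*n2 <= 400 and the data are tie-free; otherwise the
    tie-corrected, continuity-corrected normal approximation.  Returns
    (U, p) with U the statistic of group 1 (males).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size * y.size <= EXACT_U_MAX_PRODUCT and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=sidedness, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def chi_square_gof(counts) -> tuple[float, float]:
    """Pearson goodness-of-fit against an equal split across categories."""
    counts = np.asarray(counts, float)
    if counts.size < 2:
        raise ValueError("need at least 2 categories")
    if counts.sum() <= 0:
        raise ValueError("zero expected count")
    stat, p = sps.chisquare(counts)
    return float(stat), float(p)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table, df = 1, no Yates correction."""
    table = np.asarray(table, float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin")
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def reliability_of_average(icc_single: float, m: int = 2) -> float:
    """Spearman-Brown: reliability of the mean of m parallel sessions.

    Averaging m sessions shrinks the within-subject variance by m, so
    ICC_avg = m*ICC / (1 + (m-1)*ICC).
    """
    if not (0 < icc_single <= 1):
        raise ValueError("icc_single must lie in (0, 1]")
    return m * icc_single / (1 + (m - 1) * icc_single)


def bonferroni_screen(p_values, m: int = 66, alpha: float = 0.05) -> np.ndarray:
    """Boolean mask of p-values passing the Bonferroni threshold alpha/m."""
    p = np.asarray(p_values, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p < alpha / m


def compare_groups(
    table: pd.DataFrame,
    sex: pd.Series | np.ndarray,
    parameters: list[str] | None = None,
    sidedness_by_param: dict | None = None,
    variant_by_param: dict | None = None,
) -> pd.DataFrame:
    """Male-vs-female comparison table over the given parameter columns.

    Per parameter: per-sex N/mean/SD/median, t-test (default auto
    Student/Welch, two-sided unless overridden per hypothesis direction),
    Mann-Whitney U, and Cohen's d with 95% CI.  Subjects with a missing
    value are excluded per parameter (this is how the per-parameter Ns can
    differ).
    """
    sex = np.asarray(sex, int)
    parameters = parameters or [c for c in table.columns if c != "subject_id"]
    sidedness_by_param = sidedness_by_param or {}
    variant_by_param = variant_by_param or {}
    rows = []
    for param in parameters:
        vals = pd.to_numeric(table[param], errors="coerce").to_numpy(float)
        ok = np.isfinite(vals)
        x = vals[ok & (sex == 1)]
        y = vals[ok & (sex == 2)]
        if x.size < 2 or y.size < 2:
            continue
        side = sidedness_by_param.get(param, "two-sided")
        variant = variant_by_param.get(param, "auto")
        tt = t_test(x, y, variant=variant, sidedness=side)
        u, u_p = mann_whitney_u(x, y, sidedness=side)
        d, lo, hi = cohens_d_from_samples(x, y)
        rows.append(
            {
                "parameter": param,
                "n_male": x.size, "mean_male": x.mean(), "sd_male": x.std(ddof=1),
                "median_male": float(np.median(x)),
                "n_female": y.size, "mean_female": y.mean(), "sd_female": y.std(ddof=1),
                "median_female": float(np.median(y)),
                "t": tt.t, "df": tt.df, "p_t": tt.p_t,
                "variant": tt.test_variant, "sidedness": side,
                "u": u, "p_u": u_p,
                "d": d, "d_ci_low": lo, "d_ci_high": hi,
            }
        )
    return pd.DataFrame(rows)
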