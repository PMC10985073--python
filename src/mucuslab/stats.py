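"""Group-comparison statistics for replicate assay data.

Implements the comparison battery used on mucus/mucosa endpoints: ROUT
robust outlier removal (column mode, Q = 5%), one-way ANOVA with Tukey HSD
for three or more groups, Student's t with an automatic Welch fallback under
unequal variance (paired option), the Mann–Whitney U test (exact at small n),
Spearman rank correlation, percent-of-control normalization, and mean ± SD
summaries with N (biological, i.e. animals) / n (technical replicates)
bookkeeping. Technical replicates are averaged within each animal before any
between-group test: N is the unit of inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SampleGroup",
    "ComparisonResult",
    "rout_outliers",
    "anova_tukey",
    "two_group_test",
    "mann_whitney",
    "spearman",
    "normalize_to_control",
    "average_within_subject",
    "significance_stars",
]

ALPHA = 0.05


@dataclass
class SampleGroup:
    """Replicate measurements of one experimental group.

    ``values`` holds one number per biological replicate (animal); N is their
    count and ``n_technical`` records how many technical replicates each
    value was averaged from.
    """

    label: str
    values: np.ndarray
    n_technical: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) < 1:
            raise ValueError("a group needs at least one value")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def N(self) -> int:
        return len(self.values)


@dataclass
class ComparisonResult:
    """Outcome of one statistical comparison."""

    test: str
    statistic: float
    p_value: float
    significant: bool
    paired: bool = False
    labels: tuple[str, str] | None = None
    ok: bool = True  # False when the quantity is undefined (e.g. constant input)


def significance_stars(p: float) -> str:
    """The reporting convention: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if not np.isfinite(p):
        return "nd"
    for thr, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < thr:
            return stars
    return "ns"


# ---------------------------------------------------------------------------
# ROUT outlier removal (column mode)


def rout_outliers(values, Q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Robust outlier detection with a false-discovery rate Q.

    Column-mode ROUT: the robust fit is the median, the robust scale is the
    RSDR (the 68.27th percentile of the absolute residuals, inflated by
    sqrt(n/(n-1))), each point gets a two-sided t-tail p-value from
    |residual| / RSDR with n-1 degrees of freedom, and a Benjamini–Hochberg
    sequential rule at rate Q flags outliers starting from the most extreme
    point. Fewer than 4 values: nothing is removed (warning).

    Returns ``(kept, flagged)`` as arrays; flags are invariant under affine
    rescaling of the data.
    """
    x = np.asarray(values, dtype=float)
    if not 0 <= Q <= 1:
        raise ValueError("Q must be in [0, 1]")
    n = len(x)
    if n < 4:
        warnings.warn("ROUT needs more than 3 replicates; no removal performed")
        return x.copy(), np.empty(0)
    resid = np.abs(x - np.median(x))
    rsdr = np.percentile(resid, 68.27) * np.sqrt(n / (n - 1.0))
    if rsdr == 0:
        return x.copy(), np.empty(0)
    p = 2.0 * sps.t.sf(resid / rsdr, df=n - 1)
    order = np.argsort(p, kind="stable")  # most extreme first
    flag = np.zeros(n, dtype=bool)
    # BH step-up over the sorted p-values
    thresholds = Q * (np.arange(1, n + 1)) / n
    passing = np.nonzero(p[order] <= thresholds)[0]
    if len(passing):
        flag[order[: passing.max() + 1]] = True
    return x[~flag], x[flag]


# ---------------------------------------------------------------------------
# parametric comparisons


def anova_tukey(groups: list[SampleGroup]) -> tuple[ComparisonResult, list[ComparisonResult]]:
    """One-way ANOVA followed by Tukey HSD on every pair of groups.

    Requires at least 3 groups (with 2 groups, use :func:`two_group_test`)
    and at least 2 values per group. Returns (overall F result, pairwise
    Tukey results).
    """
    if len(groups) < 3:
        raise ValueError("anova_tukey needs >= 3 groups; use two_group_test for 2")
    if any(g.N < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    arrays = [g.values for g in groups]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input F = 0 case
        f_stat, f_p = sps.f_oneway(*arrays)
    if not np.isfinite(f_stat):  # all groups identical and constant
        f_stat, f_p = 0.0, 1.0
    overall = ComparisonResult("anova", float(f_stat), float(f_p), f_p < ALPHA)

    hsd = sps.tukey_hsd(*arrays)
    pairs = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p = float(hsd.pvalue[i, j])
            pairs.append(
                ComparisonResult(
                    "tukey", float(hsd.statistic[i, j]), p, p < ALPHA,
                    labels=(groups[i].label, groups[j].label),
                )
            )
    return overall, pairs


def two_group_test(
    a,
    b,
    paired: bool = False,
    force_welch_on_unequal_var: bool = True,
) -> ComparisonResult:
    """Student's t test, switching to Welch under unequal variance.

    Variance equality is screened with a two-sided F-ratio test at 0.05; when
    it rejects (and ``force_welch_on_unequal_var`` is set), the Welch test is
    used instead. ``paired=True`` tests the within-unit differences (equal
    lengths required); a degenerate all-zero difference vector reports
    statistic 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each arm needs at least 2 values")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal-length arms")
        d = a - b
        if np.all(d == d[0]) and d[0] == 0:
            return ComparisonResult("paired t", 0.0, 1.0, False, paired=True)
        t, p = sps.ttest_rel(a, b)
        return ComparisonResult("paired t", float(t), float(p), p < ALPHA, paired=True)

    welch = False
    if force_welch_on_unequal_var:
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va > 0 and vb > 0:
            f = va / vb
            dfa, dfb = len(a) - 1, len(b) - 1
            p_var = 2.0 * min(sps.f.sf(f, dfa, dfb), sps.f.cdf(f, dfa, dfb))
            welch = p_var < ALPHA
        elif va != vb:
            welch = True
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    name = "welch t" if welch else "student t"
    return ComparisonResult(name, float(t), float(p), p < ALPHA)


# ---------------------------------------------------------------------------
# non-parametric comparisons


def mann_whitney(a, b) -> ComparisonResult:
    """Two-sided Mann–Whitney U test.

    Exact null distribution (full enumeration) when both arms have at most 8
    untied observations; normal approximation with tie correction and
    continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each arm needs at least 3 values")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(f"mann-whitney ({method})", float(res.statistic),
                            float(res.pvalue), res.pvalue < ALPHA)


def spearman(x, y) -> ComparisonResult:
    """Spearman rank correlation on average ranks.

    Constant input leaves rho undefined; the result is flagged ``ok=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return ComparisonResult("spearman", float("nan"), float("nan"), False, ok=False)
    rho, p = sps.spearmanr(x, y)
    return ComparisonResult("spearman", float(rho), float(p), p < ALPHA)


# ---------------------------------------------------------------------------
# normalization and bookkeeping


def normalize_to_control(values, control_mean: float) -> np.ndarray:
    """Express values as percent of a control mean (control = 100%).

    An effect reported as "decreased by X%" corresponds to 100 − mean of the
    returned percentages. Non-positive control means are undefined (ND).
    """
    if not control_mean > 0:
        raise ValueError("control_mean must be positive (ND otherwise)")
    return 100.0 * np.asarray(values, dtype=float) / control_mean


def average_within_subject(
    df: pd.DataFrame,
    value_col: str = "value",
    subject_col: str = "piglet_id",
    group_col: str = "group",
) -> pd.DataFrame:
    """Average technical replicates within each biological unit.

    Tidy input (group, piglet_id, value) with one row per technical
    replicate; returns one row per animal with its replicate mean and count,
    the table on which between-group tests run (N is the unit of inference).
    """
    out = (
        df.groupby([group_col, subject_col])[value_col]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": value_col, "count": "n_technical"})
    )
    return out
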