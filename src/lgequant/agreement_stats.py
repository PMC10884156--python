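"""Agreement and comparison statistics for method-comparison studies.

Implements the statistical battery used to compare scar-quantification
methods against reference planimetry: descriptive summaries (mean +/- SD,
median with 25-75 percentiles), Bland-Altman bias with 1.96-SD limits of
agreement, two-way random-effects absolute-agreement intraclass correlation
ICC(A,1) with the >= 0.9 "optimal concordance" rule, the paired Wilcoxon
signed-rank test, and the chi-squared/Fisher and t/Mann-Whitney group
comparisons.

Pinned numerical conventions (these feed published-style tables, so the
exact convention matters for reproducibility):

* quartiles: linear interpolation (type-7);
* descriptive SD: sample (n-1) form;
* Bland-Altman differences: method minus reference, reference second;
* Wilcoxon: zero differences discarded, mid-ranks for ties, exact two-sided
  p by sign-assignment enumeration up to 25 nonzero pairs, otherwise a
  normal approximation with tie and continuity corrections;
* ICC: two-way random effects, absolute agreement, single measurement,
  computed from the explicit two-way mean squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .image_model import LgeQuantError

__all__ = [
    "StatsError",
    "SummaryStats",
    "AgreementResult",
    "ICCResult",
    "TestResult",
    "summarize",
    "bland_altman",
    "icc_absolute",
    "wilcoxon_paired",
    "compare_groups",
]


class StatsError(LgeQuantError):
    """Invalid input to a statistical routine."""


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    median: float
    q25: float
    q75: float
    n: int


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman agreement: bias and 95% limits ``bias +/- 1.96 sd``."""

    bias: float
    loa_lower: float
    loa_upper: float
    sd_diff: float
    means: np.ndarray
    diffs: np.ndarray


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ms_subject: float
    ms_rater: float
    ms_error: float
    concordance_label: str
    form: str


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    n_used: int


def summarize(values) -> SummaryStats:
    """Mean +/- SD and median (25-75 pct) of a vector of measurements."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise StatsError("summarize: empty input")
    if not np.all(np.isfinite(x)):
        raise StatsError("summarize: non-finite values in input")
    q25, med, q75 = np.percentile(x, [25, 50, 75])  # linear interpolation (type-7)
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return SummaryStats(float(x.mean()), sd, float(med), float(q25), float(q75), int(x.size))


def bland_altman(x, y) -> AgreementResult:
    """Bland-Altman agreement of method ``x`` against reference ``y``.

    Differences are ``x - y`` (method minus reference); limits of agreement
    are ``bias +/- 1.96 x SD(diff)`` with the sample SD.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise StatsError(f"bland_altman: length mismatch ({x.size} vs {y.size})")
    if x.size < 2:
        raise StatsError("bland_altman: need at least 2 pairs")
    diffs = x - y
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementResult(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        sd_diff=sd,
        means=(x + y) / 2.0,
        diffs=diffs,
    )


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------

def _concordance_label(icc: float) -> str:
    if icc >= 0.9:
        return "optimal"
    if icc >= 0.8:
        return "good"
    return "sub-optimal"


def icc_absolute(ratings, *, form: str = "single") -> ICCResult:
    """Absolute-agreement intraclass correlation from a subjects x raters grid.

    Two-way random-effects model.  ``form="single"`` gives ICC(A,1),

        (MS_S - MS_E) / (MS_S + (k-1) MS_E + (k/n)(MS_R - MS_E)),

    penalizing systematic rater offsets; ``form="average"`` gives the
    average-measure ICC(A,k).  The grid must be complete with at least two
    subjects and two raters.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise StatsError("icc_absolute: need a 2-D grid with >= 2 subjects and >= 2 raters")
    if not np.all(np.isfinite(x)):
        raise StatsError("icc_absolute: grid must be complete (no missing cells)")
    if form not in ("single", "average"):
        raise StatsError(f"icc_absolute: unknown form {form!r}")

    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_subject = k * np.sum((row_means - grand) ** 2)
    ss_rater = n * np.sum((col_means - grand) ** 2)
    # residuals computed directly so identical raters give an exact zero
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_error = np.sum(resid**2)

    ms_s = ss_subject / (n - 1)
    ms_r = ss_rater / (k - 1)
    ms_e = ss_error / ((n - 1) * (k - 1))

    if form == "single":
        denom = ms_s + (k - 1) * ms_e + (k / n) * (ms_r - ms_e)
    else:
        denom = ms_s + (ms_r - ms_e) / n
    icc = 1.0 if denom == 0 and ms_s == ms_e else float((ms_s - ms_e) / denom)
    return ICCResult(
        icc=icc,
        ms_subject=float(ms_s),
        ms_rater=float(ms_r),
        ms_error=float(ms_e),
        concordance_label=_concordance_label(icc),
        form=form,
    )


# ---------------------------------------------------------------------------
# Paired Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

EXACT_WILCOXON_MAX_N = 25


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Distribution of 2x(positive rank sum) under uniform sign flips.

    ``ranks2`` are the doubled ranks (integers even with mid-ranks).
    Returns counts c[w] over w = 0 .. sum(ranks2); total = 2^n.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_paired(x, y, *, method: str = "auto") -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test of ``x`` vs ``y``.

    Zero differences are discarded (classic convention, not Pratt); tied
    absolute differences receive mid-ranks.  With <= 25 nonzero pairs the
    two-sided p is exact over all sign assignments of the observed ranks;
    beyond that a normal approximation with tie and continuity corrections
    is used.  ``method`` forces ``"exact"`` or ``"approx"`` regardless of
    size.  All differences zero yields the degenerate p = 1 with a warning.
    """
    if method not in ("auto", "exact", "approx"):
        raise StatsError(f"wilcoxon_paired: unknown method {method!r}")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise StatsError(f"wilcoxon_paired: length mismatch ({x.size} vs {y.size})")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("wilcoxon_paired: all differences zero; p = 1", UserWarning, stacklevel=2)
        return TestResult(statistic=0.0, p_value=1.0, test_name="wilcoxon-paired", n_used=0)

    ranks = sps.rankdata(np.abs(d))  # mid-ranks for ties
    w_pos = float(ranks[d > 0].sum())

    use_exact = method == "exact" or (method == "auto" and n <= EXACT_WILCOXON_MAX_N)
    if use_exact:
        ranks2 = np.rint(2 * ranks).astype(np.int64)
        counts = _signed_rank_distribution(ranks2)
        total = counts.sum()
        w2 = int(round(2 * w_pos))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean_w = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / 48.0
        var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        delta = w_pos - mean_w
        # continuity correction toward the mean
        z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var_w) if var_w > 0 else 0.0
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(statistic=w_pos, p_value=float(p), test_name="wilcoxon-paired", n_used=n)


# ---------------------------------------------------------------------------
# Two-group comparisons
# ---------------------------------------------------------------------------

def compare_groups(values_or_counts, group_labels=None, *, kind: str) -> TestResult:
    """Two-group comparison with the conventional test-selection rules.

    ``kind="categorical"``: ``values_or_counts`` is a 2x2 contingency table;
    the chi-squared test (no continuity correction) is used unless any
    expected cell is below 5, in which case Fisher's exact test is used.

    ``kind="continuous"``: ``values_or_counts`` is a vector with matching
    ``group_labels`` (two levels); Student's t test is used when both groups
    pass a Shapiro normality screen at alpha = 0.05, otherwise the
    Mann-Whitney U test.
    """
    if kind == "categorical":
        table = np.asarray(values_or_counts, dtype=float)
        if table.shape != (2, 2) or np.any(table < 0):
            raise StatsError("categorical comparison requires a nonnegative 2x2 table")
        n = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
        if np.any(expected < 5):
            odds, p = sps.fisher_exact(table, alternative="two-sided")
            return TestResult(float(odds), float(p), "fisher-exact", int(n))
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        return TestResult(float(chi2), float(p), "chi-squared", int(n))

    if kind != "continuous":
        raise StatsError(f"kind must be 'continuous' or 'categorical', got {kind!r}")
    values = np.asarray(values_or_counts, dtype=float).ravel()
    labels = np.asarray(group_labels).ravel()
    if values.size != labels.size:
        raise StatsError("values and group_labels must have equal length")
    levels = np.unique(labels)
    if levels.size != 2:
        raise StatsError(f"continuous comparison requires exactly 2 groups, got {levels.size}")
    a = values[labels == levels[0]]
    b = values[labels == levels[1]]
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs >= 2 observations")

    def _normal(g: np.ndarray) -> bool:
        if np.ptp(g) == 0:  # constant: Shapiro undefined; treat as non-normal
            return False
        return sps.shapiro(g).pvalue > 0.05

    if _normal(a) and _normal(b):
        res = sps.ttest_ind(a, b)
        return TestResult(float(res.statistic), float(res.pvalue), "t-test", int(values.size))
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(float(res.statistic), float(res.pvalue), "mann-whitney", int(values.size))
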