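"""Agreement statistics: summaries, Bland-Altman, ICC(A,1), Wilcoxon,
group tests — each checked against an independent brute-force oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from lgequant import (
    StatsError,
    bland_altman,
    compare_groups,
    icc_absolute,
    summarize,
    wilcoxon_paired,
)

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def icc_a1_anova_oracle(x: np.ndarray) -> float:
    """ICC(A,1) from explicit elementwise sums of squares."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_total = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_rows = sum(k * (x[i, :].sum() / k - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].sum() / n - grand) ** 2 for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def wilcoxon_enumeration_oracle(x, y):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


def fisher_hypergeometric_oracle(table):
    """Two-sided Fisher p by full enumeration of the hypergeometric support."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {k: sps.hypergeom.pmf(k, n, r1, c1) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------------------
# summarize / bland_altman
# ---------------------------------------------------------------------------

class TestSummarize:
    def test_quartiles_linear_interpolation(self):
        s = summarize([1, 2, 3, 4, 5])
        assert (s.median, s.q25, s.q75) == (3, 2, 4)

    def test_constant_vector(self):
        assert summarize([7.0] * 5).sd == 0.0

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=37)
        s = summarize(x)
        xs = np.sort(x)

        def quantile(q):  # type-7 linear interpolation on the sorted vector
            h = (len(xs) - 1) * q
            lo = int(np.floor(h))
            return xs[lo] + (h - lo) * (xs[min(lo + 1, len(xs) - 1)] - xs[lo])

        assert s.median == pytest.approx(quantile(0.5))
        assert s.q25 == pytest.approx(quantile(0.25))
        assert s.q75 == pytest.approx(quantile(0.75))

    def test_empty_rejected(self):
        with pytest.raises(StatsError):
            summarize([])


class TestBlandAltman:
    def test_identical_methods_zero_bias_zero_limits(self):
        x = np.arange(10.0)
        res = bland_altman(x, x)
        assert (res.bias, res.loa_lower, res.loa_upper) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        res = bland_altman([1, 2, 3], [2, 3, 4])
        assert res.bias == pytest.approx(-1.0)
        assert res.sd_diff == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(StatsError):
            bland_altman([1, 2], [1, 2, 3])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 12))
        assert bland_altman(x, y).bias == pytest.approx(-bland_altman(y, x).bias)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

class TestIccAbsolute:
    def test_identical_raters_exactly_one(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        res = icc_absolute(x)
        assert res.icc == 1.0
        assert res.concordance_label == "optimal"

    def test_constant_offset_penalized(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        res = icc_absolute(np.column_stack([base, base + 10.0]))
        assert res.icc < 1.0

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=(8, 2)) + rng.normal(size=(8, 1))
            assert icc_absolute(x).icc == pytest.approx(icc_a1_anova_oracle(x), abs=1e-10)

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 3)) + 2 * rng.normal(size=(10, 1))
        df = pd.DataFrame(
            dict(
                subject=np.repeat(np.arange(10), 3),
                rater=np.tile(np.arange(3), 10),
                score=x.ravel(),
            )
        )
        ref = pingouin.intraclass_corr(df, "subject", "rater", "score")
        icc2 = float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_absolute(x).icc == pytest.approx(icc2, abs=1e-6)

    def test_permutation_invariant_to_subject_order(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(9, 2)) + rng.normal(size=(9, 1))
        perm = rng.permutation(9)
        assert icc_absolute(x).icc == pytest.approx(icc_absolute(x[perm]).icc, abs=1e-12)

    def test_monotone_decreasing_in_rater_noise(self):
        """Adding more independent rater noise lowers the ICC."""
        rng = np.random.default_rng(4)
        truth = rng.normal(scale=3.0, size=60)
        iccs = []
        for noise_sd in (0.1, 0.5, 1.5, 4.0):
            noise_rng = np.random.default_rng(5)
            grid = truth[:, None] + noise_rng.normal(scale=noise_sd, size=(60, 2))
            iccs.append(icc_absolute(grid).icc)
        assert all(a > b for a, b in zip(iccs, iccs[1:]))

    def test_average_form_at_least_single(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1))
        assert icc_absolute(x, form="average").icc >= icc_absolute(x).icc

    def test_labels_follow_rule(self):
        strong = np.column_stack([np.arange(10.0), np.arange(10.0) + 0.01])
        assert icc_absolute(strong).concordance_label == "optimal"
        weak = np.column_stack([np.arange(4.0), [3.0, 0.0, 1.0, 2.0]])
        assert icc_absolute(weak).icc < 0.9

    def test_small_designs_rejected(self):
        with pytest.raises(StatsError):
            icc_absolute(np.ones((1, 2)))
        with pytest.raises(StatsError):
            icc_absolute(np.ones((5, 1)))
        with pytest.raises(StatsError):
            icc_absolute(np.array([[1.0, np.nan], [2.0, 3.0]]))


# ---------------------------------------------------------------------------
# Wilcoxon
# ---------------------------------------------------------------------------

class TestWilcoxonPaired:
    def test_identical_vectors_degenerate(self):
        with pytest.warns(UserWarning, match="all differences zero"):
            res = wilcoxon_paired([1.0, 2.0], [1.0, 2.0])
        assert res.p_value == 1.0 and res.n_used == 0

    def test_six_uniform_negative_pairs(self):
        """All 6 differences negative, no ties: exact p = 2/2^6."""
        x = np.arange(6.0)
        res = wilcoxon_paired(x, x + 1.0)
        assert res.p_value == pytest.approx(2 / 64)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        x = rng.normal(size=n)
        y = x + rng.choice([-0.5, 0.0, 0.5, 1.0], size=n)  # ties and zeros
        res = wilcoxon_paired(x, y)
        assert res.p_value == pytest.approx(wilcoxon_enumeration_oracle(x, y))

    def test_matches_scipy_exact_no_ties(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=(2, 10))
        ours = wilcoxon_paired(x, y)
        ref = sps.wilcoxon(x, y, zero_method="wilcox", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_approximation_close_to_exact(self):
        """The tie/continuity-corrected normal approximation tracks the
        exact enumeration closely already at n = 12."""
        rng = np.random.default_rng(12)
        for _ in range(10):
            x = rng.normal(size=12)
            y = x + rng.normal(scale=0.8, size=12)
            p_exact = wilcoxon_paired(x, y, method="exact").p_value
            p_approx = wilcoxon_paired(x, y, method="approx").p_value
            assert abs(p_exact - p_approx) < 0.05

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_p_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        x, y = rng.normal(size=(2, n))
        assert 0.0 <= wilcoxon_paired(x, y).p_value <= 1.0


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

class TestCompareGroups:
    def test_chi_squared_two_by_two(self):
        res = compare_groups([[5, 20], [21, 20]], kind="categorical")
        assert res.test_name == "chi-squared"
        assert 0.010 <= res.p_value <= 0.013

    def test_identical_groups_p_one(self):
        res = compare_groups([[10, 10], [10, 10]], kind="categorical")
        assert res.p_value == pytest.approx(1.0)

    def test_fisher_when_expected_below_five(self):
        table = [[1, 9], [8, 2]]
        res = compare_groups(table, kind="categorical")
        assert res.test_name == "fisher-exact"
        assert res.p_value == pytest.approx(fisher_hypergeometric_oracle(table), abs=1e-12)

    def test_t_test_for_normal_groups(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(1, 1, 30)])
        labels = np.repeat([0, 1], 30)
        assert compare_groups(vals, labels, kind="continuous").test_name == "t-test"

    def test_mann_whitney_for_skewed_groups(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.lognormal(0, 1.5, 40), rng.lognormal(0.5, 1.5, 40)])
        labels = np.repeat([0, 1], 40)
        assert compare_groups(vals, labels, kind="continuous").test_name == "mann-whitney"

    def test_undersized_group_rejected(self):
        with pytest.raises(StatsError):
            compare_groups([1.0, 2.0, 3.0], [0, 0, 1], kind="continuous")
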