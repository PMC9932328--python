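"""Descriptives and rank tests against independent brute-force oracles."""

import math
from itertools import combinations, permutations

import numpy as np
import pytest
from scipy import stats as sps

from cfqct.stats import (
    bh_adjust,
    correlation_map,
    friedman_test,
    mcnemar_test,
    rate_correlation,
    summarize,
    summarize_binary,
    wmw_test,
)


class TestSummaries:
    def test_median_and_iqr(self):
        s = summarize([1, 2, 3, 4, 5])
        assert (s["median"], s["q1"], s["q3"]) == (3, 2, 4)

    def test_single_value_collapses(self):
        s = summarize([7.0])
        assert s["median"] == s["q1"] == s["q3"] == 7.0

    def test_quantiles_match_bruteforce_interpolation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=37)
        s = summarize(x)
        # brute-force order-statistic interpolation at h = (n-1)*q
        xs = np.sort(x)
        for q, key in ((0.25, "q1"), (0.5, "median"), (0.75, "q3")):
            h = (len(xs) - 1) * q
            lo, frac = int(np.floor(h)), h - int(np.floor(h))
            expected = xs[lo] + frac * (xs[lo + 1] - xs[lo]) if frac else xs[lo]
            assert s[key] == pytest.approx(expected)

    def test_binary_counts(self):
        s = summarize_binary([1, 0, 1, 1])
        assert s == {"n": 4, "positive": 3, "percent": 75.0}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])
        with pytest.raises(ValueError):
            summarize_binary([])


def _friedman_exact_oracle(M):
    """Independent enumeration: scipy statistic over all within-row orderings."""
    M = np.asarray(M, dtype=float)
    n, k = M.shape
    obs = sps.friedmanchisquare(*M.T).statistic
    perms = list(permutations(range(k)))
    hits = total = 0
    idx = [0] * n
    # odometer over per-row permutations
    while True:
        arranged = np.stack([M[i][list(perms[idx[i]])] for i in range(n)])
        stat = sps.friedmanchisquare(*arranged.T).statistic
        total += 1
        if stat >= obs - 1e-12:
            hits += 1
        j = 0
        while j < n:
            idx[j] += 1
            if idx[j] < len(perms):
                break
            idx[j] = 0
            j += 1
        if j == n:
            break
    return hits / total


class TestFriedman:
    def test_identical_columns_zero_statistic(self):
        M = np.tile([[3.0, 3.0, 3.0]], (5, 1))
        res = friedman_test(M)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        M = rng.normal(size=(5, 3))
        res = friedman_test(M)
        assert "exact" in res.note
        assert res.p == pytest.approx(_friedman_exact_oracle(M), abs=1e-12)

    def test_statistic_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(12, 4))
        res = friedman_test(M, exact=False)
        ref = sps.friedmanchisquare(*M.T)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_perfect_ordering_attains_design_maximum(self):
        # strictly increasing values for every subject: statistic = n*(k-1),
        # and only the k! all-rows-identical orderings attain it
        n, k = 5, 3
        M = np.arange(k)[None, :] + np.linspace(0, 0.1, n)[:, None]
        res = friedman_test(M)
        assert res.statistic == pytest.approx(n * (k - 1))
        assert res.p == pytest.approx(math.factorial(k) ** (1 - n))

    def test_incomplete_rows_dropped(self):
        M = np.array([[1.0, 2, 3], [2, 3, 1], [3, 1, 2], [1, np.nan, 2]])
        res = friedman_test(M)
        assert res.n == 3 and "1 incomplete" in res.note

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            friedman_test(np.ones((2, 3)))


class TestMcNemar:
    def test_balanced_discordance_closed_form(self):
        # 5 discordant pairs in each direction: ((|5-5|-1)^2)/10 with continuity
        before = [1] * 5 + [0] * 5 + [1, 1, 0, 0]
        after = [0] * 5 + [1] * 5 + [1, 1, 0, 0]
        res = mcnemar_test(before, after)
        assert res.statistic == pytest.approx(((abs(5 - 5) - 1) ** 2) / 10)
        assert res.p == pytest.approx(float(sps.chi2.sf(res.statistic, 1)))
        assert res.p > 0.7


def _wmw_exact_oracle(x, y):
    """Enumeration with U computed by direct pairwise comparison counts."""
    pooled = np.concatenate([x, y])
    n = len(x)

    def u_of(a, b):
        return sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)

    centre = len(x) * len(y) / 2
    dev = abs(u_of(x, y) - centre)
    hits = total = 0
    for pick in combinations(range(len(pooled)), n):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(pick)] = True
        total += 1
        if abs(u_of(pooled[sel], pooled[~sel]) - centre) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestWMW:
    def test_identical_groups_p_one(self):
        res = wmw_test([5.0, 5.0, 5.0], [5.0, 5.0])
        assert res.p == 1.0

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=4), rng.normal(size=4)
        res = wmw_test(x, y)
        assert res.p == pytest.approx(_wmw_exact_oracle(x, y), abs=1e-12)

    def test_exact_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(size=6), rng.normal(size=5)
        res = wmw_test(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_with_ties_matches_oracle(self):
        x, y = np.array([1.0, 2.0, 2.0, 3.0]), np.array([2.0, 3.0, 3.0])
        res = wmw_test(x, y)
        assert res.p == pytest.approx(_wmw_exact_oracle(x, y), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wmw_test([], [1.0])


def _bh_bruteforce(p):
    """Direct step-up definition: adj_(i) = min_{j>=i} p_(j)*m/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestBenjaminiHochberg:
    def test_matches_bruteforce_stepup(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=20)
        np.testing.assert_allclose(bh_adjust(p), _bh_bruteforce(p), atol=1e-12)

    def test_fixed_point_when_all_equal(self):
        p = np.full(7, 0.03)
        np.testing.assert_allclose(bh_adjust(p), p)

    def test_monotone_order_preserving_and_bounded(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=15)
        adj = bh_adjust(p)
        # order preservation: sorting by raw p sorts adjusted p
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)


class TestCorrelationMap:
    def test_perfect_linear_relation(self):
        import pandas as pd
        x = np.arange(10, dtype=float)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": np.r_[x[:-1], 4.0]})
        out = correlation_map(df, ["x", "y", "z"])
        row = out[(out.var_a == "x") & (out.var_b == "y")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.ci_low == pytest.approx(1.0) and row.ci_high == pytest.approx(1.0)

    def test_zero_variance_flagged_undefined(self):
        import pandas as pd
        df = pd.DataFrame({"x": np.arange(8.0), "c": np.ones(8)})
        out = correlation_map(df, ["x", "c"])
        assert out.iloc[0].rating == "undefined"
        assert np.isnan(out.iloc[0].p_adj)

    def test_bh_applied_over_all_defined_cells(self):
        import pandas as pd
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        out = correlation_map(df, list("abcd"))
        defined = out.p_raw.notna()
        np.testing.assert_allclose(
            out.loc[defined, "p_adj"], _bh_bruteforce(out.loc[defined, "p_raw"]), atol=1e-12
        )

    def test_rating_bands(self):
        assert rate_correlation(0.1) == "very weak"
        assert rate_correlation(-0.5) == "moderate"
        assert rate_correlation(0.95) == "very strong"
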