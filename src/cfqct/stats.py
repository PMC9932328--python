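"""Descriptive and hypothesis-testing layer of the cohort analysis.

Continuous variables are summarized as median and interquartile range,
binary variables as absolute and relative frequencies. Visit-to-visit
changes are tested with the Friedman test (continuous) and the McNemar test
(binary); two-group comparisons (e.g. A3 in chronically infected vs
uninfected patients) with the Wilcoxon-Mann-Whitney U test. Pairwise
associations use Pearson correlations pooled across visits and lobes, with
Fisher-z confidence intervals, Benjamini-Hochberg adjustment over the
correlation matrix, and verbal strength ratings.

All P-values are descriptive: this layer performs no global error-rate
control beyond the explicit BH adjustment of the correlation map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.multitest import multipletests

#: Verbal rating bands for |r| (Karlik-style grading).
CORRELATION_BANDS = (
    (0.2, "very weak"),
    (0.4, "weak"),
    (0.6, "moderate"),
    (0.8, "strong"),
    (1.01, "very strong"),
)


def rate_correlation(r: float) -> str:
    a = abs(r)
    for cut, name in CORRELATION_BANDS:
        if a < cut:
            return name
    return "very strong"


def summarize(values) -> dict:
    """Median and interquartile range (linear-interpolation quantiles)."""
    arr = np.asarray([v for v in np.ravel(values) if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {"n": int(arr.size), "median": float(med), "q1": float(q1), "q3": float(q3)}


def summarize_binary(flags) -> dict:
    arr = np.asarray(np.ravel(flags))
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    pos = int(np.sum(arr.astype(bool)))
    return {"n": int(arr.size), "positive": pos, "percent": 100.0 * pos / arr.size}


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    statistic: float
    p: float
    n: int
    note: str = ""


#: Designs with at most this many within-row rank arrangements get exact P.
FRIEDMAN_EXACT_LIMIT = 100_000


def _friedman_stat_from_colsums(colsums, n, k, den):
    num = (k - 1) * np.sum((colsums - n * (k + 1) / 2.0) ** 2, axis=-1)
    return num / den


def friedman_test(block_matrix, exact: str | bool = "auto") -> TestResult:
    """Friedman test over a subjects x timepoints block design.

    Rows with any missing value are dropped (complete-block analysis; count
    noted). Ranks use average ties; the tie-corrected statistic is
    (k-1) * sum_j (R_j - n(k+1)/2)^2 / (sum r^2 - n k (k+1)^2 / 4).

    P-values come from the exact permutation distribution — all (k!)^n
    equally likely within-subject orderings — whenever that enumeration has
    at most ``FRIEDMAN_EXACT_LIMIT`` arrangements (or ``exact=True``);
    larger designs use the chi-square reference with k-1 degrees of freedom.
    A matrix with identical columns scores 0 with P = 1.
    """
    M = np.asarray(block_matrix, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least two timepoints")
    complete = ~np.isnan(M).any(axis=1)
    dropped = int((~complete).sum())
    M = M[complete]
    n, k = M.shape
    if n < 3:
        raise ValueError(f"need at least 3 complete subjects, have {n}")
    ranks = np.apply_along_axis(sps.rankdata, 1, M)
    colsum = ranks.sum(axis=0)
    # sum of squared ranks is invariant under within-row permutation
    den = float(np.sum(ranks**2)) - n * k * (k + 1) ** 2 / 4.0
    if den <= 0:
        return TestResult(0.0, 1.0, n, note=f"all ranks tied; {dropped} incomplete dropped")
    stat = float(_friedman_stat_from_colsums(colsum, n, k, den))

    n_arrangements = float(math.factorial(k)) ** n if k <= 12 else np.inf
    use_exact = exact is True or (exact == "auto" and n_arrangements <= FRIEDMAN_EXACT_LIMIT)
    if use_exact:
        from itertools import permutations

        perms = list(permutations(range(k)))
        colsums = np.zeros((1, k))
        for i in range(n):
            row_variants = np.stack([ranks[i][list(pm)] for pm in perms])  # (k!, k)
            colsums = (colsums[:, None, :] + row_variants[None, :, :]).reshape(-1, k)
        stats_all = _friedman_stat_from_colsums(colsums, n, k, den)
        p = float(np.mean(stats_all >= stat - 1e-12))
        note = f"exact permutation ({len(colsums)} arrangements); {dropped} incomplete dropped"
    else:
        p = float(sps.chi2.sf(stat, k - 1))
        note = f"chi-square approximation; {dropped} incomplete dropped"
    return TestResult(stat, p, n, note=note)


def mcnemar_test(before, after) -> TestResult:
    """McNemar test on paired binary flags (continuity-corrected chi-square)."""
    b = np.asarray(before).astype(bool)
    a = np.asarray(after).astype(bool)
    if b.shape != a.shape or b.size == 0:
        raise ValueError("need equal-length non-empty paired binary vectors")
    table = np.array([
        [np.sum(~b & ~a), np.sum(~b & a)],
        [np.sum(b & ~a), np.sum(b & a)],
    ])
    res = _sm_mcnemar(table, exact=False, correction=True)
    return TestResult(float(res.statistic), float(res.pvalue), int(b.size))


def _wmw_u(x, y) -> float:
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0)


def wmw_test(group_a, group_b, exact_max_n: int = 8) -> TestResult:
    """Wilcoxon-Mann-Whitney U test.

    Small samples (both sizes <= ``exact_max_n``) are evaluated exactly by
    enumerating all group assignments of the pooled sample (ties included);
    larger samples use the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size <= exact_max_n and y.size <= exact_max_n:
        pooled = np.concatenate([x, y])
        n = len(x)
        u_obs = _wmw_u(x, y)
        centre = len(x) * len(y) / 2.0
        dev = abs(u_obs - centre)
        hits = total = 0
        for pick in combinations(range(len(pooled)), n):
            mask = np.zeros(len(pooled), dtype=bool)
            mask[list(pick)] = True
            u = _wmw_u(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - centre) >= dev - 1e-12:
                hits += 1
        return TestResult(u_obs, hits / total, int(x.size + y.size), note="exact enumeration")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue), int(x.size + y.size),
                      note="tie-corrected normal approximation")


# ---------------------------------------------------------------------------
# Benjamini-Hochberg and the correlation map
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n < 4 or abs(r) >= 1.0:
        return (r, r)  # degenerate: perfect correlation or too few pairs
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = sps.norm.ppf(0.5 + level / 2.0)
    return float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))


def correlation_map(table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Pairwise Pearson correlations with Fisher CIs and BH-adjusted P.

    Rows of ``table`` are observations pooled across visits and lobes;
    ``variables`` are column names. Returns a tidy frame with one row per
    unordered pair: r, ci_low, ci_high, p_raw, p_adj, rating, n. Pairs with
    fewer than 3 complete observations or zero variance are flagged
    undefined (NaN r) and excluded from the BH family.
    """
    rows = []
    for a, b in combinations(variables, 2):
        sub = table[[a, b]].dropna()
        n = len(sub)
        if n < 3 or sub[a].std() == 0 or sub[b].std() == 0:
            rows.append({"var_a": a, "var_b": b, "r": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p_raw": np.nan, "n": n,
                         "rating": "undefined"})
            continue
        r, p = sps.pearsonr(sub[a], sub[b])
        lo, hi = _fisher_ci(float(r), n)
        rows.append({"var_a": a, "var_b": b, "r": float(r), "ci_low": lo, "ci_high": hi,
                     "p_raw": float(p), "n": n, "rating": rate_correlation(float(r))})
    out = pd.DataFrame(rows)
    defined = out["p_raw"].notna()
    out["p_adj"] = np.nan
    if defined.any():
        out.loc[defined, "p_adj"] = bh_adjust(out.loc[defined, "p_raw"].to_numpy())
    return out
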