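"""Group-comparison battery for contribution scores.

Nonparametric throughout, matching how right-skewed nutrient data are
analysed: medians/IQRs for description, Kruskal-Wallis across Nova groups
with Bonferroni-corrected pairwise comparisons, Mann-Whitney U for the
healthy-vs-unhealthy dichotomy, chi-square for quartile cross-tabs, and a
binary logistic model for above-median contribution on Nova group and
FOPL status.

Small samples: the chi-square / normal approximations to the rank tests
are unreliable below roughly a dozen observations, so when the number of
distinct label assignments is small the permutation null is enumerated
exhaustively and the returned p-value is exact. Study-scale data always
take the asymptotic path.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

#: Above this many distinct label assignments, rank tests use the
#: asymptotic approximation instead of exhaustive enumeration.
EXACT_ENUMERATION_LIMIT = 20_000

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


class SeparationError(RuntimeError):
    """Logistic fit abandoned because a covariate perfectly separates the outcome."""


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    median: float
    q25: float
    q75: float


@dataclass(frozen=True)
class TestResult:
    comparison: tuple[str, ...]
    statistic: float
    df: int | None
    p: float
    p_adjusted: float | None = None
    method: str = ""

    def adjust(self, m: int) -> "TestResult":
        """Bonferroni: adjusted p = min(1, raw p x m)."""
        return TestResult(
            self.comparison, self.statistic, self.df, self.p,
            min(1.0, self.p * m), self.method,
        )


def summarise_groups(
    scores: Sequence[float], group_labels: Sequence[str]
) -> list[GroupSummary]:
    """Median and IQR per group (linear interpolation between order statistics).

    NaN scores are dropped; empty groups are omitted.
    """
    s = np.asarray(scores, dtype=float)
    g = np.asarray(group_labels)
    out = []
    for label in pd.unique(g):
        v = s[(g == label) & ~np.isnan(s)]
        if len(v) == 0:
            continue
        q25, med, q75 = np.quantile(v, [0.25, 0.5, 0.75])
        out.append(GroupSummary(str(label), len(v), float(med), float(q25), float(q75)))
    return out


def _clean_groups(scores, group_labels) -> list[np.ndarray]:
    s = np.asarray(scores, dtype=float)
    g = np.asarray(group_labels)
    keep = ~np.isnan(s)
    s, g = s[keep], g[keep]
    groups = [s[g == label] for label in pd.unique(g)]
    if any(len(x) == 0 for x in groups):
        raise ValueError("every group must be non-empty")
    return groups


def _kw_statistic(ranks: np.ndarray, sizes: Sequence[int], tie_factor: float) -> float:
    """Tie-corrected H from pooled midranks split consecutively by sizes."""
    n = len(ranks)
    h = 0.0
    start = 0
    for sz in sizes:
        r = ranks[start : start + sz]
        h += r.sum() ** 2 / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    return h / tie_factor if tie_factor > 0 else 0.0


def _tie_factor(pooled: np.ndarray) -> float:
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    return 1.0 - (counts**3 - counts).sum() / (n**3 - n)


def _n_assignments(sizes: Sequence[int]) -> int:
    total = math.factorial(sum(sizes))
    for sz in sizes:
        total //= math.factorial(sz)
    return total


def _partitions(indices: tuple[int, ...], sizes: Sequence[int]):
    """All distinct splits of ``indices`` into consecutive groups of ``sizes``."""
    if len(sizes) == 1:
        yield (indices,)
        return
    for first in itertools.combinations(indices, sizes[0]):
        rest = tuple(i for i in indices if i not in set(first))
        for tail in _partitions(rest, sizes[1:]):
            yield (first, *tail)


def kruskal_wallis(
    scores: Sequence[float], group_labels: Sequence[str], method: str = "auto"
) -> TestResult:
    """Kruskal-Wallis H over >= 2 groups.

    ``method``: 'asymptotic' (tie-corrected H against chi-square, k-1 df),
    'exact' (exhaustive permutation of labels; p = P(H >= H_obs)), or
    'auto' (exact when the assignment count is within
    EXACT_ENUMERATION_LIMIT).
    """
    groups = _clean_groups(scores, group_labels)
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires at least two groups")
    labels = tuple(str(x) for x in pd.unique(np.asarray(group_labels)))
    pooled = np.concatenate(groups)
    sizes = [len(x) for x in groups]
    df = len(groups) - 1
    if np.all(pooled == pooled[0]):
        return TestResult(labels, 0.0, df, 1.0, method="kruskal-wallis (constant data)")
    tie = _tie_factor(pooled)
    ranks = sps.rankdata(pooled)
    h_obs = _kw_statistic(ranks, sizes, tie)
    n_assign = _n_assignments(sizes)
    if method == "auto":
        method = "exact" if n_assign <= EXACT_ENUMERATION_LIMIT else "asymptotic"
    if method == "asymptotic":
        p = float(sps.chi2.sf(h_obs, df))
        return TestResult(labels, float(h_obs), df, p, method="kruskal-wallis chi2")
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    count = 0
    for part in _partitions(tuple(range(len(pooled))), sizes):
        perm_ranks = ranks[np.fromiter(itertools.chain(*part), int)]
        if _kw_statistic(perm_ranks, sizes, tie) >= h_obs - 1e-12:
            count += 1
    return TestResult(
        labels, float(h_obs), df, count / n_assign, method="kruskal-wallis exact"
    )


def mann_whitney(
    a: Sequence[float], b: Sequence[float], method: str = "auto",
    comparison: tuple[str, str] = ("a", "b"),
) -> TestResult:
    """Two-sided Mann-Whitney U.

    Asymptotic path: midranks, tie-corrected normal approximation with
    continuity correction (the convention of mainstream statistics
    packages). Exact path: exhaustive enumeration of label assignments;
    p = P(|U - n1 n2 / 2| >= |U_obs - n1 n2 / 2|), which the midrank U
    distribution makes a symmetric two-sided tail.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    if np.all(pooled == pooled[0]):
        return TestResult(comparison, n1 * n2 / 2.0, None, 1.0,
                          method="mann-whitney (constant data)")
    n_assign = math.comb(n1 + n2, n1)
    if method == "auto":
        method = "exact" if n_assign <= EXACT_ENUMERATION_LIMIT else "asymptotic"
    if method == "asymptotic":
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        return TestResult(comparison, float(res.statistic), None, float(res.pvalue),
                          method="mann-whitney normal approx")
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    ranks = sps.rankdata(pooled)
    mid = n1 * n2 / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mid)
    count = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - mid) >= dev_obs - 1e-12:
            count += 1
    return TestResult(comparison, float(u_obs), None, count / n_assign,
                      method="mann-whitney exact")


def pairwise_bonferroni(
    scores: Sequence[float], group_labels: Sequence[str], method: str = "auto",
    alpha: float = 0.05,
) -> list[TestResult]:
    """Two-group Kruskal-Wallis for every unordered pair of groups.

    Adjusted p = min(1, raw p x number of pairs tested).
    """
    s = np.asarray(scores, dtype=float)
    g = np.asarray(group_labels)
    keep = ~np.isnan(s)
    s, g = s[keep], g[keep]
    labels = [str(x) for x in pd.unique(g)]
    pairs = list(itertools.combinations(labels, 2))
    results = []
    for la, lb in pairs:
        sub = np.isin(g, [la, lb])
        r = kruskal_wallis(s[sub], g[sub], method=method)
        results.append(TestResult((la, lb), r.statistic, r.df, r.p, method=r.method))
    return [r.adjust(len(pairs)) for r in results]


def letter_display(
    groups: Sequence[str], pairwise: Sequence[TestResult], alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not significantly
    different (adjusted p >= alpha); unlike letters mark significant pairs."""
    different = {
        frozenset(r.comparison)
        for r in pairwise
        if (r.p_adjusted if r.p_adjusted is not None else r.p) < alpha
    }
    classes: list[set[str]] = []
    for grp in groups:
        placed = False
        for cls in classes:
            if all(frozenset((grp, other)) not in different for other in cls):
                cls.add(grp)
                placed = True
        if not placed:
            classes.append({grp})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, cls in zip(alphabet, classes):
        for g in groups:
            if g in cls:
                out[g] += letter
    return out


def quartile_assign(scores: Sequence[float]) -> np.ndarray:
    """Quartile labels Q1..Q4 with cut points at the 25/50/75 percentiles.

    A score exactly at a cut point goes to the lower quartile. All-constant
    input collapses to a single quartile (with a warning).
    """
    s = np.asarray(scores, dtype=float)
    cuts = np.quantile(s[~np.isnan(s)], [0.25, 0.5, 0.75])
    if cuts[0] == cuts[2]:
        import warnings

        warnings.warn("constant scores: all items fall in a single quartile")
    idx = (s[:, None] > cuts[None, :]).sum(axis=1)
    labels = np.array(QUARTILE_LABELS, dtype=object)[idx]
    labels[np.isnan(s)] = None
    return labels


def crosstab_chi2(
    row_labels: Sequence[str], col_labels: Sequence[str], yates_2x2: bool = False
) -> tuple[pd.DataFrame, TestResult]:
    """Contingency table and Pearson chi-square with (r-1)(c-1) df.

    No continuity correction for tables larger than 2x2; for 2x2 tables
    the Yates correction is off by default and configurable.
    """
    rows = pd.Series(row_labels)
    cols = pd.Series(col_labels)
    if len(rows) != len(cols):
        raise ValueError("label vectors must have equal length")
    table = pd.crosstab(rows, cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("chi-square needs at least two categories on each margin")
    correction = yates_2x2 and table.shape == (2, 2)
    chi2, p, df, _ = sps.chi2_contingency(table.to_numpy(), correction=correction)
    return table, TestResult(
        ("rows", "cols"), float(chi2), int(df), float(p), method="pearson chi2"
    )


def median_split(scores: Sequence[float]) -> np.ndarray:
    """1 for scores strictly above the median, 0 at or below (NaN stays NaN)."""
    s = np.asarray(scores, dtype=float)
    med = np.nanmedian(s)
    out = (s > med).astype(float)
    out[np.isnan(s)] = np.nan
    return out


@dataclass(frozen=True)
class LogisticFit:
    """ML logistic fit: one row per term with OR and 95% Wald CI."""

    terms: pd.DataFrame  # index: term; columns: coef, se, or_, ci_low, ci_high, p
    reference: dict[str, str]
    converged: bool
    n: int

    def odds_ratio(self, term: str) -> tuple[float, float, float]:
        r = self.terms.loc[term]
        return float(r["or_"]), float(r["ci_low"]), float(r["ci_high"])

    def inverse_odds_ratio(self, term: str) -> tuple[float, float, float]:
        """OR in the reciprocal direction (reference vs level), CI swapped."""
        or_, lo, hi = self.odds_ratio(term)
        return 1.0 / or_, 1.0 / hi, 1.0 / lo


def fit_logistic(
    outcome: Sequence[float],
    nova_labels: Sequence[str],
    healthy_flags: Sequence[bool],
    reference_nova: str = "MPF",
) -> LogisticFit:
    """Logistic regression of a binary outcome on Nova group and FOPL status.

    Fit by IRLS (maximum likelihood); reference levels are MPF and healthy,
    so each Nova coefficient is log-odds versus MPF and the FOPL term is
    unhealthy versus healthy. Complete separation raises SeparationError
    naming the covariate.
    """
    y = np.asarray(outcome, dtype=float)
    nova = pd.Series(nova_labels).astype(str)
    unhealthy = (~np.asarray(healthy_flags, dtype=bool)).astype(float)
    keep = ~np.isnan(y)
    y, nova, unhealthy = y[keep], nova[keep].reset_index(drop=True), unhealthy[keep]
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    X = pd.DataFrame({"intercept": np.ones(len(y))})
    levels = sorted(l for l in pd.unique(nova) if l != reference_nova)
    for level in levels:
        X[f"nova_{level}"] = (nova == level).astype(float)
    X["unhealthy"] = unhealthy
    # a covariate with no variation is inestimable; drop it rather than
    # handing a singular design to the optimiser
    X = X.drop(columns=[c for c in X.columns[1:] if X[c].nunique() == 1])
    for col in X.columns[1:]:
        sub = y[X[col] == 1]
        if len(sub) and sub.min() == sub.max():
            # a dummy whose outcomes are all 0 or all 1 has a divergent MLE
            raise SeparationError(f"covariate {col!r} perfectly separates the outcome")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=100)
    except Exception as e:  # statsmodels raises PerfectSeparationError et al.
        raise SeparationError(f"logistic fit failed: {e}") from e
    if not res.converged:
        raise RuntimeError("logistic fit did not converge within 100 IRLS iterations")
    if np.any(np.abs(res.params) > 20):
        bad = res.params.index[np.abs(res.params).argmax()]
        raise SeparationError(f"quasi-separation: coefficient for {bad!r} diverged")
    z = sps.norm.ppf(0.975)
    terms = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "or_": np.exp(res.params),
            "ci_low": np.exp(res.params - z * res.bse),
            "ci_high": np.exp(res.params + z * res.bse),
            "p": res.pvalues,
        }
    )
    return LogisticFit(
        terms=terms,
        reference={"nova": reference_nova, "fopl": "healthy"},
        converged=bool(res.converged),
        n=len(y),
    )
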