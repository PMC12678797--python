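"""Nonparametric comparisons, lesion-size correlations, and rater agreement.

Group comparisons use the Kruskal-Wallis test and the pairwise Wilcoxon
signed-rank test (repeated phantom scans pair naturally by repeat index).
Lesion-size correlations use Spearman's rho with the conventional strength
classes (|rho| > 0.3 low, > 0.5 medium, > 0.7 strong, applied to negative
values as well).  Rater agreement on ordinal 0-4 Likert scores uses weighted
kappa (linear weights by default) with an asymptotic 95% CI, interpreted on
the Altman scale, plus raw percent agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

ALPHA = 0.05
LIKERT_CATEGORIES = (0, 1, 2, 3, 4)


# ---------------------------------------------------------------- group tests

@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    degenerate: bool = False  # all differences zero / all values identical
    note: str = ""


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Rank-based H test with tie correction; chi-square p-value.

    When every value in every group is identical the statistic is 0 and
    p = 1 (no evidence of any difference), rather than an error.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        return TestResult(0.0, 1.0, degenerate=True, note="all values identical")
    h, p = sps.kruskal(*arrays)
    return TestResult(float(h), float(p))


def wilcoxon_pairwise(
    a: Sequence[float], b: Sequence[float], paired_by_repeat: bool = True
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired series.

    Zero differences are excluded (classic signed-rank); the exact null
    distribution is used for n <= 25 after exclusion, the tie-corrected
    normal approximation beyond.  When every difference is zero the statistic
    is undefined and the result is flagged degenerate with p = 1, mirroring
    how identical repeat series admit no test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired_by_repeat and a.size != b.size:
        raise ValueError("paired series must have equal length")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return TestResult(float("nan"), 1.0, degenerate=True,
                          note="all differences zero; test undefined")
    method = "exact" if nonzero.size <= 25 else "approx"
    res = sps.wilcoxon(a, b, zero_method="wilcox", correction=False,
                       alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------- correlation

STRENGTH_THRESHOLDS = (("strong", 0.7), ("medium", 0.5), ("low", 0.3))


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    strength_class: str  # none | low | medium | strong

    @staticmethod
    def classify(rho: float) -> str:
        """Strength class by |rho| with strict '>' thresholds (0.7 itself is medium)."""
        a = abs(rho)
        for name, thr in STRENGTH_THRESHOLDS:
            if a > thr:
                return name
        return "none"


def spearman_classified(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Tie-corrected Spearman rho with two-sided p and a strength class."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman rho undefined")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), CorrelationResult.classify(float(rho)))


# ------------------------------------------------------------ rater agreement

ALTMAN_BANDS = (  # upper edge (inclusive), name; gaps fall to the lower band
    (0.21, "poor"),
    (0.41, "fair"),
    (0.61, "moderate"),
    (0.81, "good"),
    (np.inf, "very_good"),
)


def altman_category(kappa: float) -> str:
    """Altman interpretation band for a kappa value (<=1)."""
    if kappa > 1:
        raise ValueError("kappa cannot exceed 1")
    for upper, name in ALTMAN_BANDS:
        if kappa < upper:
            return name
    return "very_good"


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci95: tuple[float, float]
    altman: str
    percent_agreement: float
    degenerate: bool = False
    weights: str = "linear"


def _weight_matrix(n_cat: int, scheme: str) -> np.ndarray:
    i, j = np.indices((n_cat, n_cat))
    d = np.abs(i - j) / (n_cat - 1)
    if scheme == "linear":
        return 1.0 - d
    if scheme == "quadratic":
        return 1.0 - d**2
    raise ValueError(f"unknown weights {scheme!r}")


def weighted_kappa(
    r1: Sequence[int],
    r2: Sequence[int],
    weights: str = "linear",
    categories: Sequence[int] = LIKERT_CATEGORIES,
) -> KappaResult:
    """Cohen's weighted kappa on ordinal scores, with asymptotic 95% CI.

    kappa = (Po_w - Pe_w) / (1 - Pe_w), with agreement weights
    w_ij = 1 - |i-j|/(k-1) (linear; quadratic uses the squared distance).
    The CI uses the large-sample variance of the weighted kappa
    (Fleiss, Cohen & Everitt).  When both raters are constant and identical,
    chance agreement is 1 and kappa is undefined; the result is flagged
    degenerate with 100% raw agreement.
    """
    r1 = np.asarray(r1, dtype=int)
    r2 = np.asarray(r2, dtype=int)
    if r1.size != r2.size or r1.size == 0:
        raise ValueError("raters must score the same nonzero number of images")
    cats = np.asarray(categories)
    if not (np.isin(r1, cats).all() and np.isin(r2, cats).all()):
        raise ValueError(f"scores must be in {list(categories)}")

    n = r1.size
    k = cats.size
    cat_index = {c: i for i, c in enumerate(cats.tolist())}
    obs = np.zeros((k, k))
    for s1, s2 in zip(r1, r2):
        obs[cat_index[s1], cat_index[s2]] += 1
    p_obs = obs / n
    p1 = p_obs.sum(axis=1)
    p2 = p_obs.sum(axis=0)

    w = _weight_matrix(k, weights)
    po = float((w * p_obs).sum())
    pe = float((w * np.outer(p1, p2)).sum())
    agreement = float((r1 == r2).mean() * 100.0)

    if np.isclose(pe, 1.0):
        return KappaResult(float("nan"), (float("nan"), float("nan")),
                           "very_good" if agreement == 100.0 else "poor",
                           agreement, degenerate=True, weights=weights)

    kappa = (po - pe) / (1.0 - pe)

    # asymptotic variance (Fleiss, Cohen & Everitt 1969)
    w_row = w @ p2  # E[w | rater-1 category]
    w_col = w.T @ p1  # E[w | rater-2 category]
    term = (w - np.add.outer(w_row, w_col) * (1 - kappa)) ** 2
    var = ((p_obs * term).sum() - (kappa - pe * (1 - kappa)) ** 2) / (n * (1 - pe) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    z = sps.norm.ppf(0.975)
    ci = (float(kappa - z * se), float(min(kappa + z * se, 1.0)))

    return KappaResult(float(kappa), ci, altman_category(float(kappa)),
                       agreement, weights=weights)


def percent_agreement(r1: Sequence[int], r2: Sequence[int]) -> tuple[int, float]:
    """Exact-match agreement: (rounded percent, raw fraction)."""
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    if r1.size != r2.size or r1.size == 0:
        raise ValueError("raters must score the same nonzero number of images")
    frac = float((r1 == r2).mean())
    return int(round(frac * 100)), frac
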