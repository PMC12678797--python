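"""Nonparametric tests vs enumeration oracles, correlation classes, kappa."""

from itertools import product

import numpy as np
import pytest
from scipy import stats as sps

from dwiphantom.stats import (
    CorrelationResult,
    altman_category,
    kruskal_wallis,
    percent_agreement,
    spearman_classified,
    weighted_kappa,
    wilcoxon_pairwise,
)
from dwiphantom.ratings import rating_vectors, reference_rating_table


# ------------------------------------------------------------------- oracles

def wilcoxon_exact_oracle(diffs):
    """Two-sided signed-rank p by enumerating all sign assignments."""
    diffs = np.asarray([d for d in diffs if d != 0], dtype=float)
    n = diffs.size
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    w_all = np.array([np.sum(ranks[list(signs)]) for signs in
                      (np.array(bits, dtype=bool) for bits in product([0, 1], repeat=n))])
    lower = np.mean(w_all <= w_obs)
    upper = np.mean(w_all >= w_obs)
    return min(1.0, 2 * min(lower, upper))


def kruskal_oracle(groups):
    """H statistic from first principles (tie-corrected rank sums)."""
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = sps.rankdata(flat)
    n = flat.size
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        start += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(flat, return_counts=True)
    tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


def kappa_contingency_oracle(r1, r2, n_cat=5):
    """Linear-weight kappa by explicit contingency-table sums."""
    n = len(r1)
    w = np.zeros((n_cat, n_cat))
    for i in range(n_cat):
        for j in range(n_cat):
            w[i, j] = 1 - abs(i - j) / (n_cat - 1)
    obs = np.zeros((n_cat, n_cat))
    for a, b in zip(r1, r2):
        obs[a, b] += 1 / n
    p1, p2 = obs.sum(axis=1), obs.sum(axis=0)
    po = (w * obs).sum()
    pe = (w * np.outer(p1, p2)).sum()
    return (po - pe) / (1 - pe)


# ------------------------------------------------------------ Kruskal-Wallis

class TestKruskalWallis:
    def test_identical_groups_degenerate(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0], [2.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.degenerate

    def test_matches_first_principles_oracle(self):
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(kruskal_oracle(groups), abs=1e-10)

    def test_oracle_with_ties(self):
        groups = [[1.0, 2.0, 2.0], [2.0, 3.0], [3.0, 5.0, 5.0]]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(kruskal_oracle(groups), abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


# ----------------------------------------------------------------- Wilcoxon

class TestWilcoxon:
    def test_all_differences_zero_degenerate(self):
        res = wilcoxon_pairwise([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p_value == 1.0

    def test_extreme_n5_exact_p(self):
        # all differences -1: p = 2/2^5 = 0.0625
        res = wilcoxon_pairwise([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert res.p_value == pytest.approx(0.0625)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_enumeration_oracle_n10(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 10).round(2)
        b = (a + rng.normal(0.3, 1, 10)).round(2)
        res = wilcoxon_pairwise(a, b)
        assert res.p_value == pytest.approx(wilcoxon_exact_oracle(a - b), abs=1e-9)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_pairwise([1.0, 2.0], [1.0])


# ----------------------------------------------------------------- Spearman

class TestSpearman:
    def test_monotone_increasing_is_strong_positive(self):
        res = spearman_classified([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.rho == pytest.approx(1.0) and res.strength_class == "strong"

    def test_monotone_decreasing_is_strong_negative(self):
        res = spearman_classified([1, 2, 3, 4], [8, 6, 4, 2])
        assert res.rho == pytest.approx(-1.0) and res.strength_class == "strong"

    @pytest.mark.parametrize("rho, expected", [
        (0.0, "none"), (0.3, "none"), (0.31, "low"), (0.45, "low"),
        (0.5, "low"), (0.51, "medium"), (0.7, "medium"), (0.71, "strong"),
        (-0.45, "low"), (-0.9, "strong"), (1.0, "strong"),
    ])
    def test_strength_classification_step_function(self, rho, expected):
        assert CorrelationResult.classify(rho) == expected

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_classified([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_linear_metric_vs_diameter_detected_as_strong(self):
        # metric rising linearly in diameter + small noise: strong in >95% of seeds
        diameters = np.repeat([10.0, 7.0, 5.0, 4.0, 3.0], 10)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = 2.0 * diameters + rng.normal(0, 1.0, diameters.size)
            if spearman_classified(diameters, y).strength_class == "strong":
                hits += 1
        assert hits > 95


# -------------------------------------------------------------------- kappa

class TestWeightedKappa:
    def test_perfect_agreement_kappa_one(self):
        res = weighted_kappa([3, 2, 4, 1], [3, 2, 4, 1])
        assert res.kappa == pytest.approx(1.0)
        assert res.altman == "very_good"
        assert res.percent_agreement == 100.0

    def test_hand_computed_example(self):
        # Po_w = 0.9167, Pe_w = 0.8611 -> kappa = 0.40, Altman fair
        res = weighted_kappa([3, 3, 2], [3, 2, 2])
        assert res.kappa == pytest.approx(0.40, abs=1e-6)
        assert res.altman == "fair"

    def test_degenerate_constant_equal_raters(self):
        res = weighted_kappa([3, 3, 3], [3, 3, 3])
        assert res.degenerate and np.isnan(res.kappa)
        assert res.percent_agreement == 100.0

    def test_constant_but_unequal_raters_nonpositive(self):
        res = weighted_kappa([3, 3, 3, 3], [2, 2, 2, 2])
        assert res.kappa == pytest.approx(kappa_contingency_oracle([3, 3, 3, 3],
                                                                   [2, 2, 2, 2]))
        assert res.kappa <= 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_contingency_oracle_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        r1 = rng.integers(0, 5, 30)
        r2 = np.clip(r1 + rng.integers(-1, 2, 30), 0, 4)
        res = weighted_kappa(r1, r2)
        assert res.kappa == pytest.approx(kappa_contingency_oracle(r1, r2), abs=1e-10)
        sklearn = pytest.importorskip("sklearn.metrics")
        ref = sklearn.cohen_kappa_score(r1, r2, labels=[0, 1, 2, 3, 4], weights="linear")
        assert res.kappa == pytest.approx(ref, abs=1e-10)

    def test_quadratic_weights_option(self):
        res = weighted_kappa([3, 3, 2], [3, 2, 2], weights="quadratic")
        sklearn = pytest.importorskip("sklearn.metrics")
        ref = sklearn.cohen_kappa_score([3, 3, 2], [3, 2, 2],
                                        labels=[0, 1, 2, 3, 4], weights="quadratic")
        assert res.kappa == pytest.approx(ref, abs=1e-10)

    def test_ci_contains_kappa_and_respects_upper_bound(self):
        res = weighted_kappa([3, 2, 4, 1, 0, 2, 3], [3, 2, 3, 1, 1, 2, 4])
        lo, hi = res.ci95
        assert lo <= res.kappa <= hi <= 1.0


class TestAltman:
    @pytest.mark.parametrize("kappa, band", [
        (0.57, "moderate"), (1.0, "very_good"), (0.40, "fair"),
        (0.19, "poor"), (0.205, "poor"), (0.61, "good"), (-0.3, "poor"),
        (0.81, "very_good"),
    ])
    def test_bands(self, kappa, band):
        assert altman_category(kappa) == band

    def test_kappa_above_one_rejected(self):
        with pytest.raises(ValueError):
            altman_category(1.2)


# -------------------------------------------------------------- agreement

class TestPercentAgreement:
    def test_contrast_criterion_reconstruction_gives_93(self):
        table = reference_rating_table()
        r1, r2 = rating_vectors(table, "contrast")
        pct, frac = percent_agreement(r1, r2)
        assert pct == 93
        assert frac == pytest.approx(14 / 15)

    def test_identical_and_disjoint(self):
        assert percent_agreement([1, 2], [1, 2])[0] == 100
        assert percent_agreement([1, 2], [2, 1])[0] == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percent_agreement([], [])
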