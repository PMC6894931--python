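"""Connectivity proportions, Fisher's exact test, Wald CI, equivalence, ranks."""

import math

import numpy as np
import pytest

from multipatch.errors import InvalidArgumentError
from multipatch.stats import (
    connection_probability,
    distance_summary,
    equivalence_report,
    fisher_exact,
    rank_tests,
    wald_ci_diff,
)


def hypergeom_two_sided(a, b, c, d):
    """Exhaustive enumeration oracle for the two-sided Fisher p."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    probs = {x: math.comb(r1, x) * math.comb(n - r1, c1 - x) / math.comb(n, c1)
             for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


def test_connection_probability():
    assert connection_probability(38, 150) == pytest.approx(38 / 150)
    assert connection_probability(0, 50) == 0.0
    assert connection_probability(50, 50) == 1.0
    with pytest.raises(InvalidArgumentError):
        connection_probability(1, 0)
    with pytest.raises(InvalidArgumentError):
        connection_probability(5, 4)


def test_fisher_small_table_oracle_value():
    assert fisher_exact(3, 4, 1, 4) == pytest.approx(0.485714285714, abs=1e-9)


def test_fisher_identical_proportions_p_one():
    assert fisher_exact(5, 20, 5, 20) == pytest.approx(1.0)


def test_fisher_matches_enumeration_on_grid():
    for t1 in range(1, 9):
        for t2 in range(1, 9):
            for f1 in range(0, t1 + 1, 2):
                for f2 in range(0, t2 + 1, 2):
                    p = fisher_exact(f1, t1, f2, t2)
                    oracle = hypergeom_two_sided(f1, t1 - f1, f2, t2 - f2)
                    assert p == pytest.approx(oracle, abs=1e-9)
                    assert 0.0 < p <= 1.0


def test_wald_ci_hand_arithmetic():
    cmp_ = wald_ci_diff(20, 100, 10, 100, level=0.90)
    assert cmp_.diff == pytest.approx(0.10)
    assert cmp_.z == pytest.approx(1.6449, abs=1e-4)
    assert cmp_.ci[0] == pytest.approx(0.01775, abs=1e-4)
    assert cmp_.ci[1] == pytest.approx(0.18225, abs=1e-4)
    assert cmp_.ci[0] <= cmp_.diff <= cmp_.ci[1]


def test_wald_ci_symmetric_when_equal():
    cmp_ = wald_ci_diff(15, 60, 15, 60)
    assert cmp_.diff == 0.0
    assert cmp_.ci[0] == pytest.approx(-cmp_.ci[1])
    assert cmp_.fisher_p == pytest.approx(1.0)


def test_wald_ci_width_shrinks_with_n():
    widths = []
    for n in (50, 500, 5000):
        c = wald_ci_diff(n // 5, n, n // 10, n)
        widths.append(c.ci[1] - c.ci[0])
    assert widths == sorted(widths, reverse=True)
    assert widths[-1] < 0.05


def test_wald_sign_flips_under_relabeling():
    ab = wald_ci_diff(20, 100, 10, 100)
    ba = wald_ci_diff(10, 100, 20, 100)
    assert ab.diff == pytest.approx(-ba.diff)
    assert ab.ci[0] == pytest.approx(-ba.ci[1])
    assert ab.fisher_p == pytest.approx(ba.fisher_p)


def test_equivalence_exact_match():
    x = np.array([100.0, 90.0, 110.0, 95.0, 105.0])
    rep = equivalence_report(x, x, paired=True, bound_pct=20.0)
    assert rep.mean_rel_diff_pct == 0.0
    assert rep.equivalent
    assert rep.ci_pct[0] <= 0.0 <= rep.ci_pct[1]


def test_equivalence_detects_large_shift():
    rng = np.random.default_rng(1)
    before = rng.normal(100.0, 5.0, 25)
    after = before * 1.30 + rng.normal(0.0, 10.0, 25)
    rep = equivalence_report(before, after, paired=True, bound_pct=20.0)
    assert not rep.equivalent
    assert rep.mean_rel_diff_pct > 20.0


def test_equivalence_ci_coverage():
    """The 90% CI of the mean relative difference covers the true +5% shift
    in at least 88% of 1000 replicates."""
    rng = np.random.default_rng(11)
    covered = 0
    for _ in range(1000):
        before = rng.normal(100.0, 10.0, 25)
        after = before * 1.05 + rng.normal(0.0, 10.0, 25)
        rep = equivalence_report(before, after, paired=True)
        covered += rep.ci_pct[0] <= 5.0 <= rep.ci_pct[1]
    assert covered / 1000 >= 0.88


def test_equivalence_unpaired_group_means():
    rng = np.random.default_rng(2)
    a = rng.normal(100.0, 8.0, 30)
    b = rng.normal(100.0, 8.0, 24)
    rep = equivalence_report(a, b, paired=False, bound_pct=20.0)
    assert abs(rep.mean_rel_diff_pct) < 10.0
    assert rep.ci_pct[0] < rep.mean_rel_diff_pct < rep.ci_pct[1]


def test_equivalence_zero_baseline_rows_skipped():
    rep = equivalence_report([100.0, 0.0, 100.0, 100.0], [105.0, 5.0, 95.0, 100.0])
    assert rep.n_undefined == 1
    assert rep.n == 3


def test_rank_identical_groups():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    assert rank_tests(x, x, paired=False) == pytest.approx(1.0)


def test_rank_disjoint_supports_exact():
    a = [1.0, 2.0, 3.0, 4.0, 5.0]
    b = [10.0, 11.0, 12.0, 13.0, 14.0]
    # 2 / C(10, 5) = 2/252 for complete separation, two-sided exact
    assert rank_tests(a, b, paired=False) == pytest.approx(2 / 252, abs=1e-9)


def test_rank_exact_vs_asymptotic_close_at_n10():
    rng = np.random.default_rng(4)
    for _ in range(10):
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.3, 1.0, 10)
        from scipy.stats import mannwhitneyu

        exact = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        approx = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert abs(exact - approx) < 0.02


def test_rank_paired_wilcoxon():
    a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    b = [1.5, 2.5, 3.1, 4.4, 5.2, 6.9]
    p = rank_tests(a, b, paired=True)
    assert 0.0 < p < 0.1  # consistent one-directional shift


def test_rank_degenerate_rejected():
    with pytest.raises(InvalidArgumentError):
        rank_tests([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], paired=True)
    with pytest.raises(InvalidArgumentError):
        rank_tests([1.0, 2.0], [1.0, 2.0, 3.0], paired=False)


def test_distance_summary_trivial_and_grouped():
    single = distance_summary([(84.0, 1)])
    assert single.loc[0, "median_um"] == 84.0
    assert single.loc[0, "q25_um"] == 84.0 == single.loc[0, "q75_um"]
    three = distance_summary([(60.0, 1), (84.0, 1), (110.0, 1)])
    assert three.loc[0, "median_um"] == 84.0


def test_distance_rounds_statistically_indistinguishable():
    """Uniform[50, 120] distances resampled per round mirror a null design:
    medians near 85 um and rank tests mostly non-significant."""
    rng = np.random.default_rng(8)
    nonsig = 0
    n_rep = 40
    for _ in range(n_rep):
        r1 = rng.uniform(50.0, 120.0, 278)
        r2 = rng.uniform(50.0, 120.0, 218)
        summary = distance_summary(
            [(d, 1) for d in r1] + [(d, 2) for d in r2]
        )
        assert summary["median_um"].between(75.0, 95.0).all()
        nonsig += rank_tests(r1, r2, paired=False) > 0.05
    assert nonsig / n_rep >= 0.9


def test_distance_negative_rejected():
    with pytest.raises(InvalidArgumentError):
        distance_summary([(-5.0, 1)])
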