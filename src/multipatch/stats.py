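"""Connectivity and equivalence statistics.

Connection probability is found/tested over directed pairs.  Two
probabilities are compared with Fisher's exact test and with the simple
asymptotic ("Wald") confidence interval for a difference of proportions,

    (p1 - p2) +/- z * sqrt(p1(1-p1)/n1 + p2(1-p2)/n2),

without continuity correction.  Equivalence of paired before/after
measurements is reported as the mean relative difference with its
t-based 90% confidence interval; the two-one-sided-tests (TOST) verdict at
alpha = 0.05 is equivalent to that 90% CI lying inside the equivalence
bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .errors import InvalidArgumentError

__all__ = [
    "ProportionComparison",
    "EquivalenceReport",
    "connection_probability",
    "wald_ci_diff",
    "fisher_exact",
    "equivalence_report",
    "rank_tests",
    "distance_summary",
    "repeated_measures_anova",
]


def connection_probability(found: int, tested: int) -> float:
    """Fraction of tested directed pairs that were connected."""
    if tested <= 0:
        raise InvalidArgumentError("tested count must be positive")
    if not 0 <= found <= tested:
        raise InvalidArgumentError(f"found={found} outside [0, tested={tested}]")
    return found / tested


@dataclass
class ProportionComparison:
    p1: float
    p2: float
    n1: int
    n2: int
    z: float
    diff: float
    ci: tuple
    fisher_p: float
    level: float

    def __post_init__(self):
        assert self.ci[0] <= self.diff <= self.ci[1]


def fisher_exact(found1: int, tested1: int, found2: int, tested2: int) -> float:
    """Two-sided Fisher exact p for two found/tested proportions.

    The two-sided p sums hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's (the common probability-mass ordering).
    """
    for f, t in ((found1, tested1), (found2, tested2)):
        if not 0 <= f <= t:
            raise InvalidArgumentError("need 0 <= found <= tested")
    if tested1 == 0 or tested2 == 0:
        raise InvalidArgumentError("empty margins")
    table = [[found1, tested1 - found1], [found2, tested2 - found2]]
    return float(_st.fisher_exact(table, alternative="two-sided")[1])


def wald_ci_diff(
    found1: int, tested1: int, found2: int, tested2: int, level: float = 0.90
) -> ProportionComparison:
    """Wald CI for p1 - p2 (no continuity correction) plus Fisher's exact p."""
    p1 = connection_probability(found1, tested1)
    p2 = connection_probability(found2, tested2)
    z = float(_st.norm.ppf((1.0 + level) / 2.0))
    se = math.sqrt(p1 * (1 - p1) / tested1 + p2 * (1 - p2) / tested2)
    diff = p1 - p2
    return ProportionComparison(
        p1=p1, p2=p2, n1=tested1, n2=tested2, z=z, diff=diff,
        ci=(diff - z * se, diff + z * se),
        fisher_p=fisher_exact(found1, tested1, found2, tested2),
        level=level,
    )


@dataclass
class EquivalenceReport:
    mean_rel_diff_pct: float
    ci_pct: tuple
    bound_pct: float
    equivalent: bool
    paired: bool
    n: int
    level: float
    n_undefined: int = 0  # paired rows with zero baseline, skipped

    def __post_init__(self):
        lo, hi = self.ci_pct
        assert self.equivalent == (-self.bound_pct <= lo and hi <= self.bound_pct)


def equivalence_report(
    before,
    after,
    paired: bool = True,
    bound_pct: float = 20.0,
    level: float = 0.90,
) -> EquivalenceReport:
    """Relative-difference equivalence report (CI-TOST duality).

    Paired: per-pair relative differences 100*(after-before)/before, mean
    and t-based CI at ``level``.  Unpaired: relative difference of group
    means with a delta-method standard error.  Equivalent iff the CI lies
    within +/- ``bound_pct``.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise InvalidArgumentError("paired samples must have equal length")
        ok = b != 0
        n_undef = int((~ok).sum())
        rel = 100.0 * (a[ok] - b[ok]) / b[ok]
        n = rel.size
        if n < 2:
            raise InvalidArgumentError("need at least 2 defined pairs")
        mean = float(rel.mean())
        sem = float(rel.std(ddof=1) / math.sqrt(n))
        tq = float(_st.t.ppf((1.0 + level) / 2.0, n - 1))
        ci = (mean - tq * sem, mean + tq * sem)
    else:
        n_undef = 0
        if b.size < 2 or a.size < 2:
            raise InvalidArgumentError("need at least 2 values per group")
        mb, ma = float(b.mean()), float(a.mean())
        if mb == 0:
            raise InvalidArgumentError("zero baseline group mean")
        vb = float(b.var(ddof=1)) / b.size
        va = float(a.var(ddof=1)) / a.size
        mean = 100.0 * (ma - mb) / mb
        # delta method on f(ma, mb) = 100*(ma-mb)/mb
        se = 100.0 * math.sqrt(va / mb**2 + (ma**2 * vb) / mb**4)
        # Welch-Satterthwaite df on the two group means
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        tq = float(_st.t.ppf((1.0 + level) / 2.0, df))
        ci = (mean - tq * se, mean + tq * se)
        n = min(a.size, b.size)
    equivalent = bool(-bound_pct <= ci[0] and ci[1] <= bound_pct)
    return EquivalenceReport(
        mean_rel_diff_pct=mean, ci_pct=ci, bound_pct=bound_pct,
        equivalent=equivalent, paired=paired, n=n, level=level,
        n_undefined=n_undef,
    )


def rank_tests(group_a, group_b, paired: bool = False) -> float:
    """Two-sided rank test p: Wilcoxon signed-rank (paired) or Mann-Whitney U.

    Exact null distributions are used for small samples without ties,
    normal approximation beyond.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InvalidArgumentError("need at least 3 observations per group")
    if paired:
        if a.size != b.size:
            raise InvalidArgumentError("paired groups must have equal length")
        d = a - b
        if np.all(d == 0):
            raise InvalidArgumentError("all-ties input: signed-rank test undefined")
        method = "exact" if a.size <= 10 else "approx"
        return float(_st.wilcoxon(a, b, method=method).pvalue)
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        raise InvalidArgumentError("degenerate all-ties input")
    method = "exact" if (a.size <= 10 and b.size <= 10) else "asymptotic"
    try:
        return float(_st.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
    except ValueError:  # exact method refuses ties
        return float(_st.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic").pvalue)


def distance_summary(pairs) -> pd.DataFrame:
    """Median and IQR of intersomatic distance per recording round.

    ``pairs`` is an iterable of (distance_um, round_index).  Returns one row
    per round with columns round, n, median_um, q25_um, q75_um.
    """
    df = pd.DataFrame(pairs, columns=["distance_um", "round"])
    if (df["distance_um"] < 0).any():
        raise InvalidArgumentError("distances must be >= 0")
    rows = []
    for rnd, grp in df.groupby("round"):
        d = grp["distance_um"].to_numpy()
        rows.append({
            "round": rnd,
            "n": d.size,
            "median_um": float(np.median(d)),
            "q25_um": float(np.percentile(d, 25)),
            "q75_um": float(np.percentile(d, 75)),
        })
    return pd.DataFrame(rows)


def repeated_measures_anova(values: pd.DataFrame, subject: str, within: str, dv: str) -> float:
    """Convenience wrapper around a standard repeated-measures ANOVA; returns p."""
    from statsmodels.stats.anova import AnovaRM

    res = AnovaRM(values, depvar=dv, subject=subject, within=[within]).fit()
    return float(res.anova_table["Pr > F"].iloc[0])
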