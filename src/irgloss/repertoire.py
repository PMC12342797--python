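"""Crop-vs-wild repertoire difference testing.

For each crop / wild-relative pair the per-class count differences are
normalized (each class difference divided by the sum of absolute
differences, wild − crop convention), then tested for a median/mean shift
away from zero: a Shapiro–Wilk normality gate (P > 0.05) dispatches to a
one-sample t-test, otherwise to a one-sample Wilcoxon signed-rank test.
Raw p-values are corrected with the Benjamini–Hochberg step-up procedure
across the crops of one scope (full 14-class repertoire, the 9 NLR
classes, or the 5 PRR classes).

The Wilcoxon test uses the exact null distribution of the positive rank
sum (all 2^m equally likely sign assignments) whenever the differences
are tie-free and zero-free with m ≤ 25; otherwise a normal approximation
with tie-corrected variance and a continuity correction is used, matching
the convention of R's ``wilcox.test``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .classify import IRG_CLASSES, NLR_CLASSES, PRR_CLASSES, IRGClass, RepertoireCounts

__all__ = [
    "Scope",
    "NormalizedDiffVector",
    "RepertoireTestResult",
    "WilcoxonResult",
    "normalize_differences",
    "shapiro_wilk",
    "one_sample_t",
    "wilcoxon_signed_rank",
    "signed_rank_null_counts",
    "bh_adjust",
    "compare_repertoires",
]


class Scope(str, Enum):
    """Which part of the repertoire a test covers."""

    FULL = "full"
    NLR = "nlr"
    PRR = "prr"

    @property
    def classes(self) -> tuple[IRGClass, ...]:
        if self is Scope.FULL:
            return IRG_CLASSES
        if self is Scope.NLR:
            return NLR_CLASSES
        return PRR_CLASSES


@dataclass
class NormalizedDiffVector:
    """Normalized per-class repertoire differences for one crop.

    ``diffs[c] = (wild[c] - crop[c]) / sum(|wild - crop|)`` over the scope
    classes; the all-zero vector encodes identical repertoires.  For any
    non-identical pair the absolute values sum to 1 by construction.
    """

    crop_id: str
    diffs: dict[IRGClass, float]
    scope: Scope

    def values(self) -> np.ndarray:
        return np.array([self.diffs[c] for c in self.scope.classes], dtype=float)


@dataclass
class RepertoireTestResult:
    crop_id: str
    scope: Scope
    test_used: str  # "one_sample_t" | "wilcoxon_signed_rank" | "degenerate"
    shapiro_p: float
    statistic: float
    p_raw: float
    p_adjusted: float = float("nan")


def normalize_differences(
    crop: RepertoireCounts, wild: RepertoireCounts, scope: Scope = Scope.FULL
) -> NormalizedDiffVector:
    """Normalized wild-minus-crop count differences over a scope.

    The denominator is the sum of absolute differences so that the result
    is a signed composition (|diffs| sums to 1); identical repertoires
    yield the all-zero vector.
    """
    scope = Scope(scope)
    raw = {c: float(wild[c] - crop[c]) for c in scope.classes}
    denom = sum(abs(v) for v in raw.values())
    if denom == 0:
        diffs = {c: 0.0 for c in scope.classes}
    else:
        diffs = {c: v / denom for c, v in raw.items()}
    return NormalizedDiffVector(crop_id=crop.species_id, diffs=diffs, scope=scope)


def shapiro_wilk(x) -> float:
    """Shapiro–Wilk normality test p-value (Royston approximation).

    Raises ``ValueError`` outside the supported 3 ≤ n ≤ 5000 range or for
    zero-variance input.
    """
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for zero-variance sample")
    return float(stats.shapiro(x).pvalue)


def one_sample_t(x, mu0: float = 0.0) -> tuple[float, int, float]:
    """One-sample two-sided t-test of mean(x) == mu0.

    Returns ``(t, df, p)`` with t = (mean − mu0)/(sd/√n) and df = n − 1.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("one-sample t-test requires n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("one-sample t-test undefined for zero-variance sample")
    t = (x.mean() - mu0) / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def signed_rank_null_counts(m: int) -> np.ndarray:
    """Counts of sign assignments per value of the positive rank sum.

    Under the null every one of the 2^m assignments of signs to the ranks
    1..m is equally likely; entry ``k`` of the returned array (length
    m(m+1)/2 + 1) is the number of assignments with positive rank sum k.
    Computed by the standard counting recursion, which enumerates the same
    distribution as listing all 2^m sign vectors.
    """
    max_v = m * (m + 1) // 2
    counts = np.zeros(max_v + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in range(1, m + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted
    return counts


@dataclass
class WilcoxonResult:
    statistic: float  # V, the sum of positive ranks
    p_value: float
    method: str  # "exact" | "normal"
    n_used: int  # m after dropping zeros


def wilcoxon_signed_rank(x, mu0: float = 0.0) -> WilcoxonResult:
    """One-sample two-sided Wilcoxon signed-rank test against ``mu0``.

    Exact zeros (x == mu0) are dropped before ranking; absolute
    differences are ranked with average ranks for ties; V is the sum of
    the ranks of the positive differences.  The exact two-sided p-value is
    used when m ≤ 25 with no ties and at least one value remaining;
    otherwise the tie-corrected normal approximation with continuity
    correction is applied.
    """
    x = np.asarray(x, dtype=float)
    d = x - mu0
    d = d[d != 0]
    m = d.size
    if m == 0:
        raise ValueError("all values equal mu0: signed-rank test undefined")
    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    V = float(ranks[d > 0].sum())

    has_ties = np.unique(absd).size < m
    if m <= 25 and not has_ties:
        counts = signed_rank_null_counts(m)
        total = 2.0**m
        v_int = int(round(V))
        p_le = counts[: v_int + 1].sum() / total
        p_ge = counts[v_int:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(V, float(p), "exact", m)

    mean = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over tie groups
    _, tie_counts = np.unique(absd, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        raise ValueError("zero variance in signed-rank normal approximation")
    delta = V - mean
    # continuity correction shrinks |delta| by 0.5
    z = (delta - 0.5 * np.sign(delta)) / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return WilcoxonResult(V, float(p), "normal", m)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    ``adj_(i) = min_{j >= i} p_(j) * m / j`` over the sorted p-values,
    capped at 1 and mapped back to the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj_sorted
    return out


def _single_test(
    diffs: NormalizedDiffVector, shapiro_threshold: float
) -> tuple[str, float, float, float]:
    """Dispatch one normalized-difference vector; returns
    (test_used, shapiro_p, statistic, p_raw)."""
    v = diffs.values()
    if np.all(v == 0):
        # identical repertoires: nothing to test
        return "degenerate", float("nan"), 0.0, 1.0
    if np.ptp(v) == 0:
        # all equal and nonzero: Shapiro undefined, data are pure sign — Wilcoxon
        w = wilcoxon_signed_rank(v)
        return "wilcoxon_signed_rank", float("nan"), w.statistic, w.p_value
    sp = shapiro_wilk(v)
    if sp > shapiro_threshold:
        t, _, p = one_sample_t(v)
        return "one_sample_t", sp, t, p
    w = wilcoxon_signed_rank(v)
    return "wilcoxon_signed_rank", sp, w.statistic, w.p_value


def compare_repertoires(
    pairs: list[tuple[RepertoireCounts, RepertoireCounts]],
    scope: Scope = Scope.FULL,
    shapiro_threshold: float = 0.05,
) -> list[RepertoireTestResult]:
    """Test every (crop, wild) pair for a repertoire shift within one scope.

    Per crop: normalize the count differences, gate on Shapiro–Wilk at
    ``shapiro_threshold`` (strictly greater ⇒ one-sample t, otherwise
    Wilcoxon signed-rank), then BH-adjust across all crops in the scope.
    """
    scope = Scope(scope)
    results: list[RepertoireTestResult] = []
    for crop, wild in pairs:
        d = normalize_differences(crop, wild, scope)
        test_used, sp, stat, p_raw = _single_test(d, shapiro_threshold)
        results.append(
            RepertoireTestResult(
                crop_id=crop.species_id,
                scope=scope,
                test_used=test_used,
                shapiro_p=sp,
                statistic=stat,
                p_raw=p_raw,
            )
        )
    adj = bh_adjust([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return results
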