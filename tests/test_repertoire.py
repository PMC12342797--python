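"""Tests for normalized repertoire differences and the test battery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from irgloss import (
    IRGClass,
    Scope,
    bh_adjust,
    compare_repertoires,
    normalize_differences,
    one_sample_t,
    shapiro_wilk,
    wilcoxon_signed_rank,
)

from conftest import make_counts


# ---------------------------------------------------------------- normalization

def test_identical_repertoires_give_all_zeros():
    crop = make_counts("c", CNL=5, LYP=5)
    wild = make_counts("w", CNL=5, LYP=5)
    d = normalize_differences(crop, wild, Scope.FULL)
    assert all(v == 0 for v in d.diffs.values())


def test_hand_computed_normalization():
    # wild {CNL:8, NL:2}, crop {CNL:6, NL:3}: diffs (2, -1)/3
    crop = make_counts("c", CNL=6, NL=3)
    wild = make_counts("w", CNL=8, NL=2)
    d = normalize_differences(crop, wild, Scope.FULL)
    assert d.diffs[IRGClass.CNL] == pytest.approx(2 / 3)
    assert d.diffs[IRGClass.NL] == pytest.approx(-1 / 3)


@given(
    st.lists(st.integers(0, 50), min_size=14, max_size=14),
    st.lists(st.integers(0, 50), min_size=14, max_size=14),
)
def test_absolute_diffs_sum_to_one_when_not_identical(c_counts, w_counts):
    crop = make_counts("c", **dict(zip([k.value for k in Scope.FULL.classes], c_counts)))
    wild = make_counts("w", **dict(zip([k.value for k in Scope.FULL.classes], w_counts)))
    d = normalize_differences(crop, wild, Scope.FULL)
    total = sum(abs(v) for v in d.diffs.values())
    if c_counts == w_counts:
        assert total == 0
    else:
        assert total == pytest.approx(1.0)


# ---------------------------------------------------------------- shapiro

def test_shapiro_classic_reference_sample():
    # 11-value textbook sample; W = 0.78881, p = 0.006704 in R's shapiro.test
    x = [148, 154, 158, 160, 161, 162, 166, 170, 182, 195, 236]
    assert shapiro_wilk(x) == pytest.approx(0.006704, abs=2e-4)


def test_shapiro_null_p_values_are_uniform():
    rng = np.random.default_rng(11)
    ps = [shapiro_wilk(rng.standard_normal(50)) for _ in range(200)]
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_shapiro_power_on_lognormal():
    rng = np.random.default_rng(12)
    rejected = sum(
        shapiro_wilk(np.exp(rng.standard_normal(50))) < 0.05 for _ in range(100)
    )
    assert rejected >= 95


def test_shapiro_input_validation():
    with pytest.raises(ValueError):
        shapiro_wilk([1.0, 2.0])
    with pytest.raises(ValueError):
        shapiro_wilk([3.0, 3.0, 3.0, 3.0])


# ---------------------------------------------------------------- one-sample t

def test_t_symmetric_pair_gives_zero():
    t, df, p = one_sample_t([-1.0, 1.0])
    assert t == 0 and df == 1 and p == pytest.approx(1.0)


def test_t_hand_arithmetic():
    t, df, p = one_sample_t([1, 2, 3, 4, 5])
    assert t == pytest.approx(4.242641, abs=1e-5)
    assert df == 4


def test_t_two_sided_sign_invariance():
    x = np.array([0.3, -1.2, 2.2, 0.7, 1.9])
    _, _, p1 = one_sample_t(x)
    _, _, p2 = one_sample_t(-x)
    assert p1 == pytest.approx(p2)


# ---------------------------------------------------------------- wilcoxon

def enumeration_p(d):
    """Brute-force exact two-sided p over all 2^m sign assignments."""
    d = np.asarray(d, dtype=float)
    ranks = stats.rankdata(np.abs(d))
    v_obs = ranks[d > 0].sum()
    m = len(d)
    vs = np.array(
        [ranks[np.array(signs, dtype=bool)].sum()
         for signs in itertools.product([0, 1], repeat=m)]
    )
    p_le = np.mean(vs <= v_obs)
    p_ge = np.mean(vs >= v_obs)
    return min(1.0, 2 * min(p_le, p_ge))


def test_all_positive_14_values():
    res = wilcoxon_signed_rank(np.arange(1.0, 15.0))
    assert res.statistic == 105
    assert res.p_value == pytest.approx(2 * 2**-14)
    assert res.method == "exact"


def test_all_positive_9_values():
    res = wilcoxon_signed_rank(np.arange(1.0, 10.0))
    assert res.statistic == 45
    assert res.p_value == pytest.approx(2 * 2**-9)


def test_tied_symmetric_pair():
    res = wilcoxon_signed_rank([-3.0, 3.0])
    assert res.statistic == pytest.approx(1.5)  # average rank of the tie
    assert res.p_value == pytest.approx(1.0)
    assert res.method == "normal"


def test_zeros_are_dropped():
    a = wilcoxon_signed_rank([0.0, 1.0, 2.0, -3.0])
    b = wilcoxon_signed_rank([1.0, 2.0, -3.0])
    assert a.statistic == b.statistic and a.p_value == b.p_value
    assert a.n_used == 3


def test_all_zero_rejected():
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([0.0, 0.0])


@settings(deadline=None, max_examples=100)
@given(
    st.lists(
        st.integers(-1000, 1000).filter(lambda v: v != 0),
        min_size=1, max_size=10, unique_by=abs,
    )
)
def test_exact_p_matches_sign_enumeration(d):
    d = [float(v) for v in d]
    res = wilcoxon_signed_rank(d)
    assert res.method == "exact"
    assert res.p_value == pytest.approx(enumeration_p(d), abs=1e-12)


@settings(deadline=None, max_examples=100)
@given(
    st.lists(
        st.integers(-1000, 1000).filter(lambda v: v != 0),
        min_size=2, max_size=12, unique_by=abs,
    )
)
def test_v_reflection_identity(d):
    """V(x) + V(-x) = m(m+1)/2 in the tie-free case."""
    d = np.array(d, dtype=float)
    m = len(d)
    v1 = wilcoxon_signed_rank(d).statistic
    v2 = wilcoxon_signed_rank(-d).statistic
    assert v1 + v2 == pytest.approx(m * (m + 1) / 2)
    assert 0 <= v1 <= m * (m + 1) / 2


def test_large_or_tied_samples_match_r_convention():
    # normal approximation with continuity correction, as in R wilcox.test
    rng = np.random.default_rng(5)
    x = np.round(rng.standard_normal(30), 1)  # rounding induces ties
    x = x[x != 0]
    res = wilcoxon_signed_rank(x)
    ref = stats.wilcoxon(x, correction=True, mode="approx")
    # scipy reports the *smaller* rank sum; convert ours for comparison
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)


# ---------------------------------------------------------------- BH

def test_bh_single_p_unchanged():
    assert bh_adjust([0.031])[0] == pytest.approx(0.031)


def test_bh_smallest_of_15():
    p = np.array([2 * 2**-14] + [0.5] * 14)
    adj = bh_adjust(p)
    assert adj[0] == pytest.approx(2 * 2**-14 * 15)
    assert round(adj[0], 4) == 0.0018


def test_bh_tied_pair_of_15():
    p = np.array([0.00390625, 0.00390625] + [0.5] * 13)
    adj = bh_adjust(p)
    assert adj[0] == adj[1] == pytest.approx(0.00390625 * 15 / 2)
    assert round(adj[0], 3) == 0.029


@settings(deadline=None, max_examples=100)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
def test_bh_matches_statsmodels_and_bounds(p):
    from statsmodels.stats.multitest import multipletests

    adj = bh_adjust(p)
    ref = multipletests(p, method="fdr_bh")[1]
    assert adj == pytest.approx(ref, abs=1e-12)
    assert np.all(adj >= np.asarray(p) - 1e-15)  # never below raw
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone in sorted order


# ---------------------------------------------------------------- dispatch

def test_compare_repertoires_uniform_reduction_hits_extreme():
    """A crop reduced in every class gives the all-same-sign extreme p."""
    pairs = []
    wild = make_counts("wild_0", **{c.value: 20 + i for i, c in enumerate(Scope.FULL.classes)})
    crop_counts = {c.value: 20 + i - (i + 1) for i, c in enumerate(Scope.FULL.classes)}
    crop = make_counts("crop_0", **crop_counts)
    pairs.append((crop, wild))
    for k in range(1, 4):  # null crops
        c = make_counts(f"crop_{k}", CNL=10, NL=8, LRR_RLK=12, TNL=3)
        w = make_counts(f"wild_{k}", CNL=11, NL=7, LRR_RLK=13, TNL=3)
        pairs.append((c, w))
    results = compare_repertoires(pairs, Scope.FULL)
    r0 = results[0]
    assert r0.test_used in ("one_sample_t", "wilcoxon_signed_rank")
    if r0.test_used == "wilcoxon_signed_rank":
        assert r0.statistic == 105
        assert r0.p_raw == pytest.approx(2 * 2**-14)
    # dispatch is a pure function of shapiro_p at threshold 0.05
    for r in results:
        if r.test_used == "one_sample_t":
            assert r.shapiro_p > 0.05
        elif r.test_used == "wilcoxon_signed_rank" and not np.isnan(r.shapiro_p):
            assert r.shapiro_p <= 0.05


def test_compare_repertoires_identical_counts_never_reject():
    pairs = [
        (make_counts(f"crop_{k}", CNL=5, TNL=2), make_counts(f"wild_{k}", CNL=5, TNL=2))
        for k in range(6)
    ]
    for scope in Scope:
        results = compare_repertoires(pairs, scope)
        assert all(r.p_adjusted == 1.0 for r in results)
        assert all(r.test_used == "degenerate" for r in results)


def test_bh_false_rejection_rate_under_null(rng):
    """Family-wise BH false rejections stay at or below nominal under the
    null (equal crop/wild sampling), over replicate cohorts."""
    n_crops, reps, alpha = 15, 300, 0.05
    any_reject = 0
    classes = [c.value for c in Scope.FULL.classes]
    lam = np.array([20, 4, 12, 5, 8, 2, 1, 4, 2, 25, 14, 2, 2, 10], dtype=float)
    for _ in range(reps):
        pairs = []
        for k in range(n_crops):
            c = rng.poisson(lam)
            w = rng.poisson(lam)
            pairs.append(
                (make_counts(f"c{k}", **dict(zip(classes, c))),
                 make_counts(f"w{k}", **dict(zip(classes, w))))
            )
        results = compare_repertoires(pairs, Scope.FULL)
        if any(r.p_adjusted < alpha for r in results):
            any_reject += 1
    # BH controls FDR at 5%; the familywise any-rejection rate under the
    # complete null equals FDR here. Allow 3 binomial SEs of slack.
    bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / reps)
    assert any_reject / reps <= bound
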