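"""Statistical primitives: exact-test oracles, calibration, and invariances."""

import math

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from orientrack.stats import (
    ContingencyTable2x2,
    auroc,
    binomial_ci,
    bonferroni_alpha,
    fisher_exact_two_sided,
    normalized_cell_counts,
    permutation_test_laser,
    rank_tests,
    shuffle_significance,
)

import pandas as pd


# ---------------------------------------------------------------------------
# Fisher exact test

def fisher_two_sided_oracle(a, b, c, d):
    """Exact-fraction enumeration over all tables with the observed margins."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    from fractions import Fraction

    def pmf(k):
        return Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), math.comb(n, c1))

    k_lo, k_hi = max(0, c1 - (n - r1)), min(r1, c1)
    p_obs = pmf(a)
    total = sum(pmf(k) for k in range(k_lo, k_hi + 1) if pmf(k) <= p_obs)
    return float(total)


def test_fisher_balanced_table_gives_p_one():
    assert fisher_exact_two_sided([[1, 1], [1, 1]]) == pytest.approx(0.0, abs=1e-12)


def test_fisher_matches_enumeration_on_diagonal_table():
    # all 6 tables with margins (5,5)/(5,5): only the two diagonal ones are
    # as extreme, each with probability 1/252
    expected = fisher_two_sided_oracle(5, 0, 0, 5)
    assert expected == pytest.approx(2 / 252)
    assert 10 ** fisher_exact_two_sided([[5, 0], [0, 5]]) == pytest.approx(expected, rel=1e-9)


@given(
    st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
)
@settings(max_examples=120, deadline=None)
def test_fisher_agrees_with_exhaustive_enumeration(a, b, c, d):
    if a + b + c + d == 0:
        return
    log_p = fisher_exact_two_sided([[a, b], [c, d]])
    expected = fisher_two_sided_oracle(a, b, c, d)
    assert log_p == pytest.approx(math.log10(expected), rel=1e-10, abs=1e-10)


def test_fisher_handles_extreme_tables_beyond_float_underflow():
    # a table whose p-value underflows double precision is still finite in log space
    log_p = fisher_exact_two_sided([[5000, 0], [0, 5000]])
    assert np.isfinite(log_p) and log_p < -300


def test_fisher_cross_checked_against_scipy():
    for table in ([[233, 35], [48, 261]], [[4, 264], [156, 153]], [[12, 3], [5, 9]]):
        p_scipy = sps.fisher_exact(table)[1]
        assert 10 ** fisher_exact_two_sided(table) == pytest.approx(p_scipy, rel=1e-8)


def test_fisher_rejects_empty_table():
    with pytest.raises(ValueError, match="empty table"):
        fisher_exact_two_sided([[0, 0], [0, 0]])
    with pytest.raises(ValueError):
        ContingencyTable2x2(-1, 1, 1, 1)


# ---------------------------------------------------------------------------
# binomial CI

def test_binomial_ci_boundaries_and_derived_interval():
    assert binomial_ci(0, 10)[0] == 0.0
    assert binomial_ci(10, 10)[1] == 1.0
    lo, hi = binomial_ci(5, 10)
    # tail inversion at 2.5% each side
    assert lo == pytest.approx(sps.beta.ppf(0.025, 5, 6), abs=1e-9)
    assert hi == pytest.approx(sps.beta.ppf(0.975, 6, 5), abs=1e-9)
    assert (lo, hi) == pytest.approx((0.187, 0.813), abs=2e-3)


@given(st.integers(1, 60), st.data())
@settings(max_examples=60, deadline=None)
def test_binomial_ci_brackets_the_point_estimate(n, data):
    k = data.draw(st.integers(0, n))
    lo, hi = binomial_ci(k, n)
    assert lo <= k / n <= hi

def test_binomial_ci_rejects_bad_inputs():
    with pytest.raises(ValueError):
        binomial_ci(0, 0)
    with pytest.raises(ValueError):
        binomial_ci(5, 3)


# ---------------------------------------------------------------------------
# AUROC

def auroc_bruteforce(pos, neg):
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


@given(
    st.lists(st.integers(-5, 5), min_size=1, max_size=8),
    st.lists(st.integers(-5, 5), min_size=1, max_size=8),
)
@settings(max_examples=200, deadline=None)
def test_auroc_matches_pairwise_bruteforce(pos, neg):
    assert auroc(pos, neg) == pytest.approx(auroc_bruteforce(pos, neg), abs=1e-12)
    assert auroc(pos, neg) + auroc(neg, pos) == pytest.approx(1.0)


def test_auroc_edge_cases():
    assert auroc([2, 3], [0, 1]) == 1.0
    assert auroc([1, 1], [1, 1]) == 0.5
    assert auroc([1, 3], [2]) == 0.5
    with pytest.raises(ValueError):
        auroc([], [1.0])


# ---------------------------------------------------------------------------
# shuffle significance

def _pref(a, b):
    return 2.0 * (auroc(a, b) - 0.5)


def test_shuffle_identical_groups_not_significant():
    x = np.arange(10.0)
    res = shuffle_significance(x, x.copy(), _pref, n_shuffles=300, seed=0)
    assert not res.significant


def test_shuffle_separated_groups_significant_and_deterministic():
    a = np.arange(5.0) + 100.0
    b = np.arange(5.0)
    r1 = shuffle_significance(a, b, _pref, n_shuffles=1000, seed=42)
    r2 = shuffle_significance(a, b, _pref, n_shuffles=1000, seed=42)
    assert r1.significant and r1.observed == 1.0
    assert r1 == r2


def test_shuffle_invariant_to_monotone_transform_of_rank_score():
    rng = np.random.default_rng(3)
    a, b = rng.normal(1, 1, 12), rng.normal(0, 1, 12)
    r_raw = shuffle_significance(a, b, _pref, n_shuffles=400, seed=7)
    r_exp = shuffle_significance(np.exp(a), np.exp(b), _pref, n_shuffles=400, seed=7)
    assert r_raw.observed == pytest.approx(r_exp.observed)
    assert r_raw.significant == r_exp.significant
    assert (r_raw.null_lo, r_raw.null_hi) == pytest.approx((r_exp.null_lo, r_exp.null_hi))


# ---------------------------------------------------------------------------
# permutation test

def _mean_diff(cols, laser):
    return float(cols["y"][laser].mean() - cols["y"][~laser].mean())


def _animal(rng, n=60, shift=0.0):
    laser = np.zeros(n, dtype=bool)
    laser[rng.choice(n, n // 3, replace=False)] = True
    y = rng.normal(0, 1, n) + shift * laser
    return pd.DataFrame({"laser": laser, "y": y})


def test_permutation_label_invariant_metric_gives_p_one():
    rng = np.random.default_rng(0)
    tables = [_animal(rng) for _ in range(3)]
    res = permutation_test_laser(tables, lambda cols, laser: 1.23, n_perm=100, seed=1)
    assert res.p_two_sided == 1.0
    assert res.resolution == pytest.approx(0.01)


def test_permutation_detects_large_shift_and_is_deterministic():
    rng = np.random.default_rng(1)
    tables = [_animal(rng, shift=1.5) for _ in range(4)]
    r1 = permutation_test_laser(tables, _mean_diff, n_perm=500, seed=9)
    r2 = permutation_test_laser(tables, _mean_diff, n_perm=500, seed=9)
    assert r1.p_two_sided < 0.01
    assert np.array_equal(r1.null_samples, r2.null_samples)


def test_permutation_requires_both_conditions_per_animal():
    good = pd.DataFrame({"laser": [True, False, True, False], "y": [1.0, 2, 3, 4]})
    bad = pd.DataFrame({"laser": [True, True], "y": [1.0, 2.0]})
    with pytest.raises(ValueError, match="animal 1"):
        permutation_test_laser([good, bad], _mean_diff, n_perm=10, seed=0)


# ---------------------------------------------------------------------------
# rank tests

def test_ranksum_extreme_small_sample_exact_p():
    # most extreme assignment of ranks for n=3 vs 3: exact two-sided p = 2/20
    p, z = rank_tests([1, 2, 3], [4, 5, 6], paired=False)
    assert p == pytest.approx(0.1)
    assert z < 0  # x ranks below y


def test_rank_tests_symmetry_and_errors():
    x = [1.0, 4.0, 2.5, 7.0, 5.0, 3.0]
    y = [2.0, 3.5, 2.0, 9.0, 1.0, 2.5]
    p_xy, z_xy = rank_tests(x, y, paired=True)
    p_yx, z_yx = rank_tests(y, x, paired=True)
    assert p_xy == pytest.approx(p_yx)
    assert z_xy == pytest.approx(-z_yx)
    with pytest.raises(ValueError):
        rank_tests(x, x, paired=True)  # no usable differences


def test_rank_tests_asymptotic_agrees_with_scipy_z():
    rng = np.random.default_rng(5)
    x, y = rng.normal(0.5, 1, 40), rng.normal(0, 1, 35)
    p, z = rank_tests(x, y, paired=False)
    # z^2 consistent with the two-sided asymptotic p
    p_from_z = 2 * sps.norm.sf(abs(z))
    p_scipy = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                               use_continuity=False).pvalue
    assert p_from_z == pytest.approx(p_scipy, rel=1e-6)


def test_one_sided_rank_sum_direction():
    p_greater, _ = rank_tests([5, 6, 7, 8], [1, 2, 3, 4], paired=False, alternative="greater")
    p_less, _ = rank_tests([5, 6, 7, 8], [1, 2, 3, 4], paired=False, alternative="less")
    assert p_greater < 0.05 < p_less


# ---------------------------------------------------------------------------
# count normalization

def test_normalized_cell_counts_arithmetic_and_distractors():
    cells = pd.DataFrame({"ap_mm": [0.1, 0.2, 0.3, 0.4, 0.6, 0.7, 1.1, 1.2, 1.3, 1.4]})
    out = normalized_cell_counts(cells, bin_width=0.5, normalization_range=(0.0, 3.0))
    assert out["proportion"].sum() == pytest.approx(1.0)
    first_bin = out.loc[out["bin_lo"] == 0.0, "proportion"].item()
    assert first_bin == pytest.approx(0.4)
    # distractor cells outside the range change neither denominator nor bins in range
    noisy = pd.concat(
        [cells, pd.DataFrame({"ap_mm": [-2.0, -2.1, 5.0]})], ignore_index=True
    )
    out2 = normalized_cell_counts(noisy, bin_width=0.5, normalization_range=(0.0, 3.0))
    assert out2.loc[out2["bin_lo"] == 0.0, "proportion"].item() == pytest.approx(0.4)


def test_normalized_cell_counts_empty_range_errors():
    cells = pd.DataFrame({"ap_mm": [5.0, 6.0]})
    with pytest.raises(ValueError, match="normalization range"):
        normalized_cell_counts(cells, normalization_range=(0.0, 3.0))


def test_bonferroni_pair_alpha():
    assert bonferroni_alpha(0.05, 2) == 0.025
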