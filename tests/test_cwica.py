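"""Split-half estimator: splitting, rank correlation, R_q, drop rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

import icdim
from icdim import (
    BackendSpec,
    CrossCorrelationBlock,
    cw_ica,
    first_differences,
    mix_signals,
    rank_correlation_block,
    rq_statistic,
    select_q_single,
    simulate_sources,
    split_two_blocks,
)


# ---------------------------------------------------------------- splitting

@pytest.mark.parametrize("p,sizes", [(20, (10, 10)), (7, (4, 3)), (31, (16, 15))])
def test_split_sizes(p, sizes):
    s = split_two_blocks(p, seed=0)
    assert (len(s.block1_rows), len(s.block2_rows)) == sizes
    union = np.sort(np.concatenate([s.block1_rows, s.block2_rows]))
    np.testing.assert_array_equal(union, np.arange(p))


def test_split_too_few_channels():
    with pytest.raises(ValueError, match="p >= 4"):
        split_two_blocks(3, seed=0)


def test_split_is_uniform_over_seeds():
    """Each of 30 channels lands in block 1 in about half of 100 seeded
    splits (two-sided binomial test not rejected at alpha=0.01)."""
    from scipy.stats import binomtest

    counts = np.zeros(30, dtype=int)
    for seed in range(100):
        counts[split_two_blocks(30, seed=seed).block1_rows] += 1
    for c in counts:
        assert binomtest(int(c), 100, 0.5).pvalue > 0.01


# ------------------------------------------------------- rank correlation

def _spearman_oracle(a, b):
    ra, rb = rankdata(a), rankdata(b)
    return np.corrcoef(ra, rb)[0, 1]


def test_spearman_examples():
    S = np.array([[1.0, 2, 3, 4, 5]])
    T = np.array([[1.0, 4, 9, 16, 25]])
    block = rank_correlation_block(S, T)
    assert block.values[0, 0] == pytest.approx(1.0)  # monotone transform
    block = rank_correlation_block(S, S)
    assert block.values[0, 0] == pytest.approx(1.0)
    # tie handling, frozen from the rank-then-Pearson oracle
    a = np.array([[3.0, 1, 2, 5, 4]])
    b = np.array([[2.0, 1, 1, 4, 5]])
    got = rank_correlation_block(a, b).values[0, 0]
    assert got == pytest.approx(0.8720815992723809, abs=1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 5), min_size=4, max_size=12),
       st.lists(st.integers(0, 5), min_size=4, max_size=12))
def test_spearman_matches_rank_then_pearson_oracle(xs, ys):
    n = min(len(xs), len(ys))
    a = np.array(xs[:n], dtype=float)
    b = np.array(ys[:n], dtype=float)
    if a.std() == 0 or b.std() == 0 or rankdata(a).std() == 0 or rankdata(b).std() == 0:
        return
    got = rank_correlation_block(a[None, :], b[None, :]).values[0, 0]
    assert got == pytest.approx(_spearman_oracle(a, b), abs=1e-12)


def test_constant_component_correlates_as_zero():
    a = np.array([[1.0, 1, 1, 1, 1], [1.0, 2, 3, 4, 5]])
    b = np.array([[5.0, 4, 3, 2, 1], [1.0, 3, 2, 5, 4]])
    with pytest.warns(UserWarning, match="constant component"):
        block = rank_correlation_block(a, b)
    np.testing.assert_array_equal(block.values[0], [0.0, 0.0])


def test_mismatched_shapes_rejected():
    with pytest.raises(ValueError, match="shape"):
        rank_correlation_block(np.ones((2, 5)), np.ones((3, 5)))


# ---------------------------------------------------------- R_q statistic

def test_rq_examples():
    assert rq_statistic(CrossCorrelationBlock(np.eye(4))) == pytest.approx(1.0)
    assert rq_statistic(CrossCorrelationBlock(np.zeros((3, 3)))) == 0.0
    block = CrossCorrelationBlock(np.array(
        [[0.9, 0.1, 0.2], [0.1, -0.8, 0.3], [0.2, 0.1, 0.05]]))
    assert rq_statistic(block) == pytest.approx(0.3)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.integers(2, 10), st.integers(0, 2**31 - 1))
def test_rq_oracle_and_invariance(q, seed):
    rng = np.random.default_rng(seed)
    M = rng.uniform(-1, 1, size=(q, q))
    got = rq_statistic(CrossCorrelationBlock(M))
    oracle = min(max(abs(M[i, j]) for i in range(q)) for j in range(q))
    assert got == pytest.approx(oracle, abs=1e-12)
    # exact invariance to sign flips and row/column permutations
    signs = rng.choice([-1.0, 1.0], size=(q, 1))
    perm = rng.permutation(q)
    assert rq_statistic(CrossCorrelationBlock((signs * M)[perm])) == got
    assert rq_statistic(CrossCorrelationBlock(M[:, perm] * signs.T)) == got


# ------------------------------------------------ drop rule and selection

def test_first_differences_examples():
    np.testing.assert_allclose(first_differences(np.array([1.0, 1.0, 0.2])),
                               [0.0, -0.8])
    np.testing.assert_allclose(first_differences(np.full(5, 0.7)), np.zeros(4))
    r = np.array([0.97, 0.95, 0.96, 0.91, 0.30, 0.25])  # q = 2..7
    d = first_differences(r)
    assert np.argmin(d) + 3 == 6  # drop at q = 6


def test_first_differences_propagates_missing():
    r = np.array([0.9, np.nan, 0.8, 0.7])
    d = first_differences(r)
    assert np.isnan(d[0]) and np.isnan(d[1])
    assert d[2] == pytest.approx(-0.1)
    with pytest.raises(ValueError, match="present"):
        first_differences(np.array([0.9, np.nan, np.nan]))


def test_select_q_examples():
    q, fb = select_q_single(np.array([0.97, 0.95, 0.96, 0.91, 0.30, 0.25]))
    assert (q, fb) == (5, False)  # drop at q=6 -> optimum 5
    q, fb = select_q_single(np.array([1.0, 0.0]))
    assert (q, fb) == (2, False)
    # monotone increase: fallback to argmax R, flagged
    q, fb = select_q_single(np.array([0.1, 0.2, 0.9]))
    assert (q, fb) == (4, True)


def test_select_q_tie_breaks_toward_smaller_q():
    q, _ = select_q_single(np.array([0.9, 0.4, 0.8, 0.3]))  # two -0.5 drops
    assert q == 2


# ------------------------------------------------------------- end-to-end

def test_cw_ica_deterministic(five_source_mixture):
    _, X, _ = five_source_mixture
    a = cw_ica(X, a_max=10, rep=1, seed=123)
    b = cw_ica(X, a_max=10, rep=1, seed=123)
    assert a.q_opt == b.q_opt and a.per_rep_q == b.per_rep_q
    np.testing.assert_array_equal(a.profile.r_values, b.profile.r_values)


def test_cw_ica_constraints(five_source_mixture):
    _, X, _ = five_source_mixture
    with pytest.raises(ValueError, match="a_max"):
        cw_ica(X, a_max=11, seed=0)  # > floor(20/2)
    with pytest.raises(ValueError, match="rep"):
        cw_ica(X, a_max=10, rep=0, seed=0)


def test_profile_values_in_unit_interval(five_source_mixture):
    _, X, _ = five_source_mixture
    res = cw_ica(X, a_max=10, rep=3, seed=7)
    rv = res.profile.r_values
    assert np.nanmin(rv) >= 0.0 and np.nanmax(rv) <= 1.0


def test_under_and_over_decomposition_regimes(five_source_mixture):
    """Reproducibility stays clearly higher below the true dimension than
    beyond it, and collapses two steps past the truth."""
    _, X, _ = five_source_mixture
    res = cw_ica(X, a_max=10, rep=10, seed=5)
    mean_r = np.nanmean(res.profile.r_values, axis=0)  # q = 2..10
    q_true = 5
    r_at_true = mean_r[q_true - 2]
    r_over = mean_r[q_true]  # q_true + 2
    assert r_over < r_at_true
    assert all(mean_r[j] > r_over for j in range(q_true - 2))
    assert r_at_true > 0.8


@pytest.mark.parametrize("q_true", [3, 5, 8])
def test_parameter_recovery_across_dimensions(q_true):
    """Modal estimate hits the true dimension in >=90% of independent
    noiseless simulations (p = 4*q_true, n = 512)."""
    hits = 0
    runs = 7
    for k in range(runs):
        src = simulate_sources(q_true, 512, seed=100 + k)
        X, _ = mix_signals(src, 4 * q_true, seed=200 + k)
        res = cw_ica(X, a_max=min(q_true + 4, 2 * q_true), rep=10, seed=300 + k)
        hits += res.q_opt == q_true
    assert hits / runs >= 0.9


def test_sign_and_permutation_do_not_change_scores(rng):
    """Metamorphic: flipping signs or permuting component rows in either
    block leaves the R_q statistic exactly unchanged."""
    S1 = rng.normal(size=(4, 60))
    S2 = rng.normal(size=(4, 60))
    base = rq_statistic(rank_correlation_block(S1, S2))
    flip = np.diag(rng.choice([-1.0, 1.0], 4))
    perm = rng.permutation(4)
    assert rq_statistic(rank_correlation_block(flip @ S1[perm], S2)) == base
    assert rq_statistic(rank_correlation_block(S1, flip @ S2[perm])) == base
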