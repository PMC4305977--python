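import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppcount.stats import (
    bonferroni_adjust,
    compare_groups,
    diagnostic_performance,
    mann_whitney,
    pearson_correlation,
)

from _oracles import mann_whitney_exact_reference


def test_mann_whitney_separated_samples():
    """U = 0 and exact two-sided p = 2/20 for fully separated triples."""
    u, p = mann_whitney([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)


def test_mann_whitney_identical_samples():
    _, p = mann_whitney([3, 1, 4, 1, 5], [3, 1, 4, 1, 5])
    assert p == 1.0


@pytest.mark.parametrize("seed", range(30))
def test_mann_whitney_exact_matches_enumeration(seed):
    """The rank-sum exact path equals an independent pairwise-win
    enumeration, including tied observations (combined n <= 8)."""
    rng = np.random.default_rng(seed)
    n1 = int(rng.integers(2, 5))
    n2 = int(rng.integers(2, 9 - n1))
    x = rng.integers(0, 5, n1).tolist()  # small range forces ties
    y = rng.integers(0, 5, n2).tolist()
    u, p = mann_whitney(x, y)
    u_ref, p_ref = mann_whitney_exact_reference(x, y)
    assert u == pytest.approx(u_ref)
    assert p == pytest.approx(p_ref)


def test_mann_whitney_large_samples_use_normal_approximation():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 30)
    y = rng.normal(1, 1, 30)
    _, p = mann_whitney(x, y)
    assert 0.0 < p < 0.05


def test_kruskal_wallis_hand_computed():
    """Three separated triples: H = 7.2 by the rank-sum formula."""
    res = compare_groups([[1, 2, 3], [4, 5, 6], [7, 8, 9]], "kruskal_wallis")
    assert res.statistic == pytest.approx(7.2)
    assert res.group_sizes == (3, 3, 3)


def test_t_test_and_chi_square():
    res = compare_groups([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]], "t_test")
    assert res.p_value < 0.05
    res = compare_groups([[20, 10], [10, 20]], "chi_square")
    assert res.statistic == pytest.approx(6.6667, abs=1e-3)
    with pytest.raises(ValueError):
        compare_groups([[1.5, 2], [3, 4]], "chi_square")


def test_compare_groups_validation():
    with pytest.raises(ValueError):
        compare_groups([[1, 2], []], "mann_whitney")
    with pytest.raises(ValueError):
        compare_groups([[1, 2], [3], [4]], "mann_whitney")
    with pytest.raises(ValueError):
        compare_groups([[1, 2], [3, 4]], "anova")


@pytest.mark.parametrize(
    "ps, m, expected",
    [([0.004], 6, [0.024]), ([0.5], 6, [1.0]), ([0.01, 0.002], 2, [0.02, 0.004])],
)
def test_bonferroni_examples(ps, m, expected):
    assert bonferroni_adjust(ps, m) == pytest.approx(expected)


@given(
    st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=6),
    st.integers(6, 20),
)
def test_bonferroni_properties(ps, m):
    adjusted = bonferroni_adjust(ps, m)
    order = np.argsort(ps)
    assert all(adjusted[i] >= ps[i] for i in range(len(ps)))
    assert all(0 <= a <= 1 for a in adjusted)
    sorted_adj = [adjusted[i] for i in order]
    assert sorted_adj == sorted(sorted_adj)  # monotone in raw p


def test_bonferroni_m_too_small():
    with pytest.raises(ValueError):
        bonferroni_adjust([0.1, 0.2], 1)


@pytest.mark.parametrize(
    "x, y, r_expected",
    [
        ([1, 2, 3], [2, 4, 6], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
    ],
)
def test_pearson_known_values(x, y, r_expected):
    r, p = pearson_correlation(x, y)
    assert r == pytest.approx(r_expected)
    assert 0 <= p <= 1


def test_pearson_validation():
    with pytest.raises(ValueError):
        pearson_correlation([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        pearson_correlation([1, 2], [1, 2])


def test_diagnostic_performance_counts():
    """49 true / 1 false positive and 5 true / 1 false negative give the
    PPV 0.98 / NPV ~0.83 pattern."""
    scores = [3.0] * 49 + [3.0] + [1.0] * 5 + [1.0]
    labels = [True] * 49 + [False] + [False] * 5 + [True]
    d = diagnostic_performance(scores, labels, threshold_pct=2.0)
    assert (d.tp, d.fp, d.tn, d.fn) == (49, 1, 5, 1)
    assert d.ppv == pytest.approx(0.98)
    assert d.npv == pytest.approx(5 / 6)


def test_diagnostic_perfect_separation():
    d = diagnostic_performance([5, 6, 1, 0], [True, True, False, False], 2.0)
    assert d.ppv == 1.0 and d.npv == 1.0


def test_diagnostic_undefined_flags():
    d = diagnostic_performance([1.0, 0.5], [True, False], 2.0)
    assert d.ppv is None  # nothing predicted positive
    d = diagnostic_performance([5.0, 4.0], [True, False], 2.0)
    assert d.npv is None
    with pytest.raises(ValueError):
        diagnostic_performance([1, 2], [True, True], 2.0)


def test_simulation_calibration_small():
    """Seeded mini version of the type-I / power check: null rejections stay
    near the nominal rate, a 4x shift is detected almost always."""
    from ppcount.synthetic import draw_group_fractions

    rng = np.random.default_rng(99)
    null_rej = power_rej = 0
    reps = 30
    for _ in range(reps):
        a = 100 * draw_group_fractions(10, 0.0123, 1.0, 0.3, rng)
        b = 100 * draw_group_fractions(10, 0.0123, 1.0, 0.3, rng)
        c = 100 * draw_group_fractions(10, 0.0123, 4.0, 0.3, rng)
        null_rej += mann_whitney(a, b)[1] < 0.05
        power_rej += mann_whitney(a, c)[1] < 0.05
    assert null_rej <= 5
    assert power_rej >= reps - 2
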