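"""Ranks, concentration index, curve, and bootstrap: oracles and invariants.

The independent oracle for the covariance-form index is the direct sum form
C = 2/(n*mu) * sum(y_i R_i) - 1 (equal weights, midpoint ranks); the curve
supplies a second oracle through the area identity C = 1 - 2 * area.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chequity import (
    bootstrap_ci,
    concentration_curve,
    concentration_index,
    fractional_rank,
)
from chequity.exceptions import DegenerateOutcomeError


def direct_sum_index(y, ranks):
    """Independent closed-form oracle (equal weights, midpoint ranks)."""
    y = np.asarray(y, float)
    return 2.0 / (y.size * y.mean()) * float(np.sum(y * ranks)) - 1.0


# ---------------------------------------------------------------- ranks

def test_midpoint_ranks_equal_weights():
    assert fractional_rank([10, 20, 30]) == pytest.approx([1/6, 1/2, 5/6])


def test_tied_incomes_share_average_midpoint():
    assert fractional_rank([10, 10, 20]) == pytest.approx([1/3, 1/3, 5/6])


def test_weighted_midpoint_ranks():
    ranks = fractional_rank([1, 2], weight=[0.25, 0.75])
    assert ranks == pytest.approx([0.125, 0.625])


def test_weighted_mean_rank_is_half(rng):
    income = rng.lognormal(9, 1, 500)
    w = rng.uniform(0.5, 3.0, 500)
    ranks = fractional_rank(income, weight=w)
    assert np.average(ranks, weights=w) == pytest.approx(0.5, abs=1e-12)


def test_paper_rank_mode_is_plain_i_over_n():
    ranks = fractional_rank([5.0, 1.0, 3.0], mode="paper")
    assert ranks == pytest.approx([3/3, 1/3, 2/3])


# ---------------------------------------------------------------- index

def test_constant_outcome_has_zero_index():
    res = concentration_index([3.0] * 10, ranks=fractional_rank(range(10)))
    assert res.index == pytest.approx(0.0, abs=1e-15)


def test_hand_computed_three_point_index():
    res = concentration_index([1, 2, 3], ranks=[1/6, 1/2, 5/6])
    assert res.index == pytest.approx(2/9, abs=1e-12)


def test_rich_half_indicator_approaches_half():
    n = 20000
    ranks = fractional_rank(np.arange(n))
    y = (ranks > 0.5).astype(float)
    res = concentration_index(y, ranks=ranks)
    assert res.index == pytest.approx(0.5, abs=1e-3)


def test_all_zero_outcome_is_degenerate():
    with pytest.raises(DegenerateOutcomeError):
        concentration_index([0.0] * 5, ranks=fractional_rank(range(5)))


def test_covariance_form_matches_direct_sum_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(3, 200))
        y = rng.gamma(1.0, 1.0, n) + 1e-6
        ranks = fractional_rank(rng.normal(size=n))
        res = concentration_index(y, ranks=ranks)
        assert abs(res.index - direct_sum_index(y, ranks)) < 1e-12


def test_convenient_regression_slope_equals_index(rng):
    y = rng.gamma(1.0, 2.0, 300) + 1e-6
    ranks = fractional_rank(rng.normal(size=300))
    res = concentration_index(y, ranks=ranks)
    # independent route: OLS slope of 2*var(R)*y/mu on R via polyfit
    lhs = 2 * np.var(ranks) * y / y.mean()
    slope = np.polyfit(ranks, lhs, 1)[0]
    assert res.index == pytest.approx(slope, abs=1e-10)


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**31 - 1), st.floats(0.1, 100.0))
def test_scale_invariance(seed, k):
    rng = np.random.default_rng(seed)
    y = rng.gamma(1.0, 1.0, 40) + 1e-3
    ranks = fractional_rank(rng.normal(size=40))
    a = concentration_index(y, ranks=ranks).index
    b = concentration_index(k * y, ranks=ranks).index
    assert a == pytest.approx(b, abs=1e-10)


def test_rank_reversal_negates_index(rng):
    y = rng.gamma(1.0, 1.0, 100) + 1e-3
    ranks = fractional_rank(rng.normal(size=100))
    a = concentration_index(y, ranks=ranks).index
    b = concentration_index(y, ranks=1.0 - ranks).index
    assert a == pytest.approx(-b, abs=1e-12)


def test_binary_outcome_bound_and_attainment(rng):
    n = 200
    ranks = fractional_rank(np.arange(n))
    for _ in range(20):
        y = (rng.random(n) < rng.uniform(0.05, 0.95)).astype(float)
        if y.sum() == 0:
            continue
        c = concentration_index(y, ranks=ranks).index
        assert abs(c) <= 1 - y.mean() + 1e-12
    # mass on the poorest k units attains C = mu - 1
    y = np.zeros(n)
    y[np.argsort(ranks)[:40]] = 1.0
    c = concentration_index(y, ranks=ranks).index
    assert c == pytest.approx(y.mean() - 1.0, abs=1e-12)


# ---------------------------------------------------------------- curve

def test_constant_outcome_curve_is_diagonal():
    curve = concentration_curve([2.0] * 8, ranks=fractional_rank(range(8)))
    assert curve.population_share == pytest.approx(curve.outcome_share)


def test_all_mass_on_poorest_unit():
    y = [1.0, 0.0, 0.0, 0.0]
    curve = concentration_curve(y, ranks=fractional_rank([1, 2, 3, 4]))
    assert (0.25, 1.0) in {tuple(p) for p in curve.points}


def test_curve_endpoints_and_monotonicity(rng):
    y = rng.gamma(1, 1, 100) + 1e-6
    curve = concentration_curve(y, rng.lognormal(9, 1, 100))
    assert tuple(curve.points[0]) == (0.0, 0.0)
    assert tuple(curve.points[-1]) == (1.0, 1.0)
    assert (np.diff(curve.population_share) >= 0).all()
    assert (np.diff(curve.outcome_share) >= 0).all()


def test_area_identity_recovers_index(rng):
    y = rng.gamma(1, 1, 500) + 1e-6
    income = rng.lognormal(9, 1, 500)
    res = concentration_index(y, income)
    curve = concentration_curve(y, income, n_points=10_000)
    assert curve.index_from_area() == pytest.approx(res.index, abs=1e-3)


def test_curve_above_diagonal_iff_negative_index(rng):
    income = rng.lognormal(9, 1, 2000)
    ranks = fractional_rank(income)
    y = (rng.random(2000) < (0.4 - 0.3 * ranks)).astype(float)  # pro-poor
    res = concentration_index(y, ranks=ranks)
    curve = concentration_curve(y, ranks=ranks)
    assert res.index < 0
    interior = curve.points[1:-1]
    assert np.mean(interior[:, 1] >= interior[:, 0]) > 0.99


# ------------------------------------------------------------- bootstrap

def test_bootstrap_constant_outcome_interval_is_degenerate():
    res = bootstrap_ci([1.0] * 30, ranks=fractional_rank(range(30)),
                       n_reps=100, seed=0)
    assert res.ci95 == (0.0, 0.0)


def test_bootstrap_same_seed_reproducible(rng):
    y = rng.gamma(1, 1, 80) + 1e-6
    ranks = fractional_rank(rng.normal(size=80))
    a = bootstrap_ci(y, ranks=ranks, n_reps=200, seed=7)
    b = bootstrap_ci(y, ranks=ranks, n_reps=200, seed=7)
    assert a.ci95 == b.ci95


def test_bootstrap_requires_minimum_reps():
    with pytest.raises(ValueError):
        bootstrap_ci([1, 2], ranks=[0.25, 0.75], n_reps=10)


def test_bootstrap_coverage_of_known_index():
    """With p(CHE | rank r) = 0.3 - 0.2 r the large-sample index is -1/6;
    the percentile interval should cover it in at least ~90% of replicates."""
    truth = -1/6
    hits = 0
    for rep in range(100):
        rng = np.random.default_rng(1000 + rep)
        income = rng.lognormal(9, 1, 2000)
        ranks = fractional_rank(income)
        y = (rng.random(2000) < (0.3 - 0.2 * ranks)).astype(float)
        lo, hi = bootstrap_ci(y, ranks=ranks, n_reps=100,
                              seed=rep).ci95
        hits += lo <= truth <= hi
    assert hits >= 90
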