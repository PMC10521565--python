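"""Probit fit, marginal effects, and the concentration-index decomposition."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from chequity import (
    WagstaffDecomposition,
    build_design,
    concentration_index,
    decompose_ci,
    fit_probit,
    fractional_rank,
    group_contributions,
)
from chequity.decomposition import DEFAULT_DUMMY_FAMILIES
from chequity.exceptions import ConvergenceError


def _probit_data(rng, n, beta=(0.5, -0.3), alpha=-0.2):
    X = pd.DataFrame({
        "x1": rng.normal(size=n),
        "x2": (rng.random(n) < 0.4).astype(float),
    })
    latent = alpha + X.to_numpy() @ np.asarray(beta) + rng.normal(size=n)
    return X, (latent > 0).astype(float)


def test_probit_recovers_true_coefficients(rng):
    X, y = _probit_data(rng, 20000)
    fit = fit_probit(X, y)
    res = sm.Probit(y, sm.add_constant(X)).fit(disp=0)
    for name, truth in [("x1", 0.5), ("x2", -0.3)]:
        assert abs(fit.params[name] - truth) < 3 * res.bse[name]


def test_probit_ame_matches_statsmodels_margeff(rng):
    X, y = _probit_data(rng, 5000)
    fit = fit_probit(X, y)
    oracle = sm.Probit(y, sm.add_constant(X)).fit(disp=0).get_margeff(
        at="overall")  # derivative-based AME, independent code path
    assert fit.marginal_effects.to_numpy() == pytest.approx(
        oracle.margeff, abs=1e-6)


def test_null_model_marginal_effects_near_zero(rng):
    X = pd.DataFrame({"x1": rng.normal(size=30000),
                      "x2": (rng.random(30000) < 0.5).astype(float)})
    y = (rng.random(30000) < 0.3).astype(float)
    fit = fit_probit(X, y)
    assert np.all(np.abs(fit.marginal_effects) < 0.02)


def test_constant_column_rejected(rng):
    X = pd.DataFrame({"x1": rng.normal(size=50), "x2": np.ones(50)})
    y = (rng.random(50) < 0.5).astype(float)
    with pytest.raises(ValueError, match="x2"):
        fit_probit(X, y)


def test_one_class_outcome_rejected(rng):
    X = pd.DataFrame({"x1": rng.normal(size=50)})
    with pytest.raises(ValueError, match="binary"):
        fit_probit(X, np.ones(50))


def test_perfect_separation_raises_convergence_error(rng):
    x = np.r_[np.zeros(30), np.ones(30)]
    y = x.copy()
    X = pd.DataFrame({"sep": x, "noise": rng.normal(size=60)})
    with pytest.raises(ConvergenceError, match="sep"):
        fit_probit(X, y)


# ----------------------------------------------------------- decomposition

def test_identity_holds_to_machine_precision(flagged_panel):
    X, y, income = build_design(flagged_panel, 2013)
    res = decompose_ci(X, y.to_numpy(), income.to_numpy())
    gap = res.total - res.rows["contribution"].sum() - res.residual
    assert abs(gap) < 1e-10


def test_covariate_cindex_shares_inequality_code_path(flagged_panel):
    X, y, income = build_design(flagged_panel, 2013)
    est = WagstaffDecomposition().fit(X, y.to_numpy(), income.to_numpy())
    ranks = fractional_rank(income.to_numpy())
    for col in ("chronic", "econ_highest", "hh_size"):
        expected = concentration_index(X[col].to_numpy(), ranks=ranks).index
        assert est.rows_.loc[col, "cindex"] == pytest.approx(expected,
                                                             abs=1e-14)


def test_zero_marginal_effects_give_zero_contributions(flagged_panel):
    X, y, income = build_design(flagged_panel, 2013)
    est = WagstaffDecomposition().fit(X, y.to_numpy(), income.to_numpy())
    rows = est.rows_.copy()
    rows["contribution"] = 0.0 * rows["elasticity"]
    # with every contribution forced to zero the residual is all of C
    assert est.total_ - rows["contribution"].sum() == pytest.approx(
        est.total_)


def test_percent_contributions_sum_to_total_minus_residual(flagged_panel):
    X, y, income = build_design(flagged_panel, 2015)
    res = decompose_ci(X, y.to_numpy(), income.to_numpy())
    assert res.rows["percent"].sum() == pytest.approx(
        100.0 - res.residual_percent, abs=1e-10)


def test_group_totals_equal_member_sums(flagged_panel):
    X, y, income = build_design(flagged_panel, 2013)
    est = WagstaffDecomposition().fit(X, y.to_numpy(), income.to_numpy())
    for family, members in DEFAULT_DUMMY_FAMILIES.items():
        assert est.group_totals_.loc[family, "percent"] == pytest.approx(
            est.rows_.loc[members, "percent"].sum(), abs=1e-12)


def test_economic_status_dominates_when_it_drives_che(rng):
    """Outcome generated from economic-status dummies only: that family
    should absorb the bulk of C, other rows staying within noise of zero."""
    n = 20000
    income = rng.lognormal(9.4, 0.8, n)
    quint = pd.qcut(pd.Series(income).rank(method="first"), 5,
                    labels=False).to_numpy()
    X = pd.DataFrame({
        "econ_lower": (quint == 1).astype(float),
        "econ_middle": (quint == 2).astype(float),
        "econ_higher": (quint == 3).astype(float),
        "econ_highest": (quint == 4).astype(float),
        "noise_a": (rng.random(n) < 0.5).astype(float),
        "noise_b": rng.normal(size=n),
    })
    latent = (-0.4 - 0.3 * X["econ_lower"] - 0.6 * X["econ_middle"]
              - 0.9 * X["econ_higher"] - 1.2 * X["econ_highest"]
              + rng.normal(size=n))
    y = (latent > 0).to_numpy(dtype=float)
    res = decompose_ci(
        X, y, income,
        dummy_families={"economic_status": [
            "econ_lower", "econ_middle", "econ_higher", "econ_highest"]})
    econ_pct = res.group_totals.loc["economic_status", "percent"]
    assert res.total < 0
    assert econ_pct > 80.0
    for col in ("noise_a", "noise_b"):
        assert abs(res.rows.loc[col, "percent"]) < 5.0


def test_group_contributions_published_2013_consistency():
    """The printed per-dummy percent columns aggregate exactly to the
    headline family totals (73.50 economic status, 25.13 age)."""
    percents = {
        "econ_lower": 1.36, "econ_middle": -0.05, "econ_higher": 15.41,
        "econ_highest": 56.78,
        "age_51_60": -11.68, "age_61_70": 2.62, "age_71_plus": 34.19,
    }
    totals = group_contributions(percents, DEFAULT_DUMMY_FAMILIES | {
        "economic_status": ["econ_lower", "econ_middle", "econ_higher",
                            "econ_highest"]})
    assert totals["economic_status"] == pytest.approx(73.50, abs=1e-9)
    assert totals["age"] == pytest.approx(25.13, abs=1e-9)


def test_group_contributions_single_member_and_unknown():
    assert group_contributions({"a": 3.5}, {"fam": ["a"]}) == {"fam": 3.5}
    with pytest.raises(KeyError, match="missing"):
        group_contributions({"a": 1.0}, {"fam": ["a", "missing"]})


def test_at_means_mode_differs_but_keeps_identity(flagged_panel):
    X, y, income = build_design(flagged_panel, 2013)
    res = decompose_ci(X, y.to_numpy(), income.to_numpy(), me_mode="at_means")
    gap = res.total - res.rows["contribution"].sum() - res.residual
    assert abs(gap) < 1e-10
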