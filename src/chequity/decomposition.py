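"""Wagstaff decomposition of the concentration index via probit marginal effects.

For a binary outcome y (the CHE flag) modelled as a probit in determinants
x_j, the concentration index of y decomposes as

    C = sum_j (beta_j^m * xbar_j / mu) * C_j  +  residual

where beta_j^m is the average marginal effect of x_j, xbar_j its mean, mu the
outcome mean, and C_j the concentration index of x_j against the *same*
income ranks.  Each determinant's absolute contribution is its elasticity
(beta_j^m * xbar_j / mu) times C_j; the residual is defined as the remainder
C - sum of contributions, which makes the identity hold to machine precision
by construction (it coincides analytically with the generalised concentration
index of the probit residuals scaled by mu).

Dummy families (e.g. the four economic-status dummies against the lowest
quintile, the three age bands against <=50) can be declared so group totals
are reported alongside per-dummy rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import ConvergenceError, DegenerateOutcomeError
from .inequality import ConcentrationIndex, fractional_rank

__all__ = [
    "DEFAULT_DUMMY_FAMILIES",
    "ProbitFit",
    "DecompositionResult",
    "WagstaffDecomposition",
    "build_design",
    "fit_probit",
    "decompose_ci",
    "group_contributions",
]

# dummy families matching how the published tables aggregate rows
DEFAULT_DUMMY_FAMILIES = {
    "age": ["age_51_60", "age_61_70", "age_71_plus"],
    "economic_status": ["econ_lower", "econ_middle", "econ_higher",
                        "econ_highest"],
}

_ECON_LABELS = ["econ_lowest", "econ_lower", "econ_middle", "econ_higher",
                "econ_highest"]


def build_design(flagged: pd.DataFrame, wave=None, *, drop: tuple = ()):
    """Design matrix, outcome, and income for the decomposition/regressions.

    Takes a panel with a ``che`` column (see ``CheFlagger``), keeps one wave
    if requested, drops rows with an undefined flag, codes reference-category
    dummies (age bands vs <=50, economic-status quintiles of within-wave
    income vs lowest), and returns ``(X, y, income)`` aligned by row.

    ``drop`` removes whole covariate groups by name ("age", "chronic",
    "education") for stratified analyses where the stratifier is held out.
    """
    df = flagged
    if wave is not None:
        df = df[df["wave"] == wave]
    df = df[df["che"].notna()].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no includable records for wave {wave!r}")

    X = pd.DataFrame(index=df.index)
    if wave is None and df["wave"].nunique() > 1:
        # earliest wave is the reference category
        for w in sorted(df["wave"].unique())[1:]:
            X[f"wave_{w}"] = (df["wave"] == w).astype(float)
    X["male"] = df["male"].astype(float)
    if "age" not in drop:
        X["age_51_60"] = (df["age_band"] == "51-60").astype(float)
        X["age_61_70"] = (df["age_band"] == "61-70").astype(float)
        X["age_71_plus"] = (df["age_band"] == ">=71").astype(float)
    X["spouse_else"] = 1.0 - df["spouse"].astype(float)
    X["hh_size"] = df["hh_size"].astype(float)

    # economic-status quintiles of household income, computed within wave
    econ = (
        df.groupby("wave")["income"]
        .transform(lambda s: pd.qcut(s.rank(method="first"), 5, labels=False))
        if df["wave"].nunique() > 1
        else pd.qcut(df["income"].rank(method="first"), 5, labels=False)
    )
    for code, label in enumerate(_ECON_LABELS):
        if code == 0:
            continue  # lowest quintile is the reference
        X[label] = (econ == code).astype(float)

    if "education" not in drop:
        X["edu_junior_plus"] = df["edu_junior_plus"].astype(float)
    X["insured"] = df["insured"].astype(float)
    X["smoke"] = df["smoke"].astype(float)
    X["drink"] = df["drink"].astype(float)
    X["disability"] = df["disability"].astype(float)
    if "chronic" not in drop:
        X["chronic"] = df["chronic"].astype(float)
    X["outpatient"] = df["outpatient"].astype(float)
    X["outpatient_times"] = df["outpatient_times"].astype(float)
    X["inpatient"] = df["inpatient"].astype(float)
    X["inpatient_times"] = df["inpatient_times"].astype(float)

    return X, df["che"].astype(float), df["income"].astype(float)


def _validate_design(X: pd.DataFrame, y: np.ndarray) -> None:
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise ValueError(f"design column {col!r} is constant")
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise ValueError("design matrix is rank-deficient (exact collinearity)")
    classes = np.unique(y)
    if classes.size != 2 or not set(classes) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary with both classes present")


def _separation_hint(X: pd.DataFrame, y: np.ndarray) -> str:
    """Name binary columns whose cells carry no outcome variation (the usual
    cause of a non-existent probit MLE)."""
    culprits = []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if not set(np.unique(v)) <= {0.0, 1.0}:
            continue
        for level in (0.0, 1.0):
            cell = y[v == level]
            if cell.size and (cell.min() == cell.max()):
                culprits.append(col)
                break
    return f" (separation suspected in column(s): {culprits})" if culprits else ""


@dataclass(frozen=True)
class ProbitFit:
    """A converged probit fit with average marginal effects and residuals."""

    params: pd.Series              # latent-scale coefficients (incl. const)
    marginal_effects: pd.Series    # dy/dx_j, sample-averaged
    residuals: np.ndarray = field(repr=False)   # y_i - Phi(x_i beta)
    converged: bool = True
    log_likelihood: float = np.nan

    @property
    def residual_mean(self) -> float:
        return float(np.mean(self.residuals))


def fit_probit(X: pd.DataFrame, y, *, me_mode: str = "ame") -> ProbitFit:
    """Maximum-likelihood probit with derivative-based marginal effects.

    ``me_mode="ame"`` (default) averages ``phi(x_i beta) * beta_j`` over the
    sample; ``"at_means"`` evaluates the density at the covariate means.
    Perfect separation or non-convergence raises :class:`ConvergenceError`.
    """
    y = np.asarray(y, dtype=float)
    _validate_design(X, y)
    exog = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    model = sm.Probit(y, exog)
    try:
        with warnings.catch_warnings():
            # convergence is checked explicitly below
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, method="newton", tol=1e-8, maxiter=100)
            if not res.mle_retvals.get("converged", False):
                # Newton can cycle under quasi-separation (e.g. an event-free
                # reference cell); BFGS to the same gradient tolerance is
                # more robust
                res = model.fit(disp=0, method="bfgs", gtol=1e-8,
                                maxiter=2000)
    except Exception as exc:  # statsmodels raises PerfectSeparation subclasses
        raise ConvergenceError(
            f"probit fit failed{_separation_hint(X, y)}: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"probit fit did not converge{_separation_hint(X, y)}")
    beta = res.params
    if not np.all(np.isfinite(beta)):
        raise ConvergenceError(
            f"probit coefficients are not finite{_separation_hint(X, y)}")
    if np.abs(beta).max() > 10:
        # a latent-scale coefficient this size means fitted probabilities of
        # 0/1 in some cell: the MLE does not exist (separation)
        raise ConvergenceError(
            f"probit coefficients diverged{_separation_hint(X, y)}")
    xb = exog @ beta
    if me_mode == "ame":
        density = float(np.mean(stats.norm.pdf(xb)))
    elif me_mode == "at_means":
        density = float(stats.norm.pdf(exog.mean(axis=0) @ beta))
    else:
        raise ValueError(f"unknown me_mode: {me_mode!r}")
    names = ["const"] + list(X.columns)
    return ProbitFit(
        params=pd.Series(beta, index=names),
        marginal_effects=pd.Series(density * beta[1:], index=list(X.columns)),
        residuals=y - stats.norm.cdf(xb),
        converged=True,
        log_likelihood=float(res.llf),
    )


@dataclass
class DecompositionResult:
    """Per-determinant contributions to the concentration index of CHE.

    ``rows`` has one row per design column: elasticity, the determinant's own
    concentration index, the absolute contribution and the percent of C.
    ``group_totals`` sums declared dummy families.  ``residual`` is
    ``total - rows.contribution.sum()`` and ``percent_excl_residual``
    rescales percents to sum to 100 without the residual.
    """

    rows: pd.DataFrame
    residual: float
    total: float
    mu: float
    wave: object = None
    group_totals: pd.DataFrame | None = None

    @property
    def residual_percent(self) -> float:
        return 100.0 * self.residual / self.total

    def with_percent_excl_residual(self) -> pd.DataFrame:
        out = self.rows.copy()
        denom = out["contribution"].sum()
        out["percent_excl_residual"] = (
            100.0 * out["contribution"] / denom if denom != 0 else np.nan)
        return out


class WagstaffDecomposition(BaseEstimator):
    """Concentration-index decomposition estimator.

    Parameters
    ----------
    dummy_families : mapping of family name to member column names whose
        contributions are summed into group totals.
    me_mode : "ame" (average marginal effects, default) or "at_means".
    rank_mode : fractional-rank convention for income.

    After ``fit(X, y, income)``: ``rows_``, ``residual_``, ``total_``,
    ``mu_``, ``group_totals_``, ``probit_``, ``result_``.
    """

    def __init__(self, dummy_families: dict | None = None,
                 me_mode: str = "ame", rank_mode: str = "midpoint"):
        self.dummy_families = dummy_families
        self.me_mode = me_mode
        self.rank_mode = rank_mode

    def fit(self, X: pd.DataFrame, y, income, *, wave=None):
        y = np.asarray(y, dtype=float)
        mu = float(np.mean(y))
        if mu == 0.0:
            raise DegenerateOutcomeError("outcome mean is zero")
        probit = fit_probit(X, y, me_mode=self.me_mode)
        ranks = fractional_rank(np.asarray(income, dtype=float),
                                mode=self.rank_mode)
        ci = ConcentrationIndex(rank_mode=self.rank_mode)
        total = ci.fit(y, ranks=ranks).index_

        records = []
        for col in X.columns:
            xj = X[col].to_numpy(dtype=float)
            elasticity = probit.marginal_effects[col] * xj.mean() / mu
            cj = ConcentrationIndex(rank_mode=self.rank_mode).fit(
                xj, ranks=ranks).index_
            contribution = elasticity * cj
            records.append((col, elasticity, cj, contribution))
        rows = pd.DataFrame(
            records,
            columns=["variable", "elasticity", "cindex", "contribution"],
        ).set_index("variable")
        rows["percent"] = 100.0 * rows["contribution"] / total
        residual = total - float(rows["contribution"].sum())

        families = (self.dummy_families if self.dummy_families is not None
                    else {k: [m for m in v if m in rows.index]
                          for k, v in DEFAULT_DUMMY_FAMILIES.items()})
        families = {k: v for k, v in families.items() if v}
        totals = pd.DataFrame(
            {
                name: {
                    "contribution": rows.loc[members, "contribution"].sum(),
                    "percent": rows.loc[members, "percent"].sum(),
                }
                for name, members in families.items()
            }
        ).T

        self.probit_ = probit
        self.rows_ = rows
        self.residual_ = residual
        self.total_ = total
        self.mu_ = mu
        self.group_totals_ = totals
        self.result_ = DecompositionResult(
            rows=rows, residual=residual, total=total, mu=mu, wave=wave,
            group_totals=totals)
        return self


def decompose_ci(X: pd.DataFrame, y, income, *, wave=None,
                 dummy_families: dict | None = None, me_mode: str = "ame",
                 rank_mode: str = "midpoint") -> DecompositionResult:
    """Functional wrapper over :class:`WagstaffDecomposition`."""
    est = WagstaffDecomposition(dummy_families=dummy_families,
                                me_mode=me_mode, rank_mode=rank_mode)
    est.fit(X, y, income, wave=wave)
    return est.result_


def group_contributions(percents, families: dict) -> dict:
    """Sum per-variable percent contributions into named family totals.

    ``percents`` maps variable name to percent contribution (a dict, a
    pandas Series, or a DecompositionResult's rows).  Unknown members raise
    ``KeyError`` naming the missing row.
    """
    if isinstance(percents, DecompositionResult):
        percents = percents.rows["percent"]
    if isinstance(percents, pd.DataFrame):
        percents = percents["percent"]
    series = pd.Series(percents, dtype=float)
    out = {}
    for name, members in families.items():
        missing = [m for m in members if m not in series.index]
        if missing:
            raise KeyError(f"family {name!r}: unknown member(s) {missing}")
        out[name] = float(series[members].sum())
    return out
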