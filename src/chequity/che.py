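"""Catastrophic health expenditure (CHE) flagging and per-wave incidence.

A household incurs CHE when its out-of-pocket health spending (OOP) reaches a
threshold share of its capacity to pay (CTP), here defined as household
non-food expenditure:

    CHE = 1  if  OOP / CTP >= threshold      (threshold defaults to 0.40)

The boundary is inclusive ("40% or more").  Records with CTP <= 0 have an
undefined ratio; they are excluded, not errored, and the exclusion is
reported so runs can quantify the dropped fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "CheConfig",
    "CheResult",
    "CheFlagger",
    "compute_ctp",
    "flag_che",
    "incidence",
]

_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class CheConfig:
    """CHE definition: threshold share of capacity to pay, and the CTP base.

    threshold : fraction in (0, 1), default 0.40.
    ctp_definition : currently only "nonfood" (CTP = non-food expenditure);
        the enum exists so alternative bases can be added.
    ci_method : "normal" (default) or "wilson" interval for incidence.
    """

    threshold: float = 0.40
    ctp_definition: str = "nonfood"
    ci_method: str = "normal"

    def __post_init__(self):
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.ctp_definition not in ("nonfood",):
            raise ValueError(f"unknown ctp_definition: {self.ctp_definition!r}")
        if self.ci_method not in ("normal", "wilson"):
            raise ValueError(f"unknown ci_method: {self.ci_method!r}")


@dataclass(frozen=True)
class CheResult:
    """Per-wave CHE incidence with a 95% confidence interval."""

    wave: object
    n: int
    n_che: int
    incidence: float
    ci95: tuple[float, float]

    def __post_init__(self):
        if not (0 <= self.n_che <= self.n):
            raise ValueError("n_che must lie in [0, n]")


def compute_ctp(nonfood_exp, config: CheConfig | None = None):
    """Capacity to pay for one record or a vector of records.

    Under the default definition this is the non-food expenditure itself.
    Values <= 0 are returned as NaN — an exclusion signal, not an error —
    because the CHE ratio is undefined for them.
    """
    config = config or CheConfig()
    ctp = np.asarray(nonfood_exp, dtype=float)
    out = np.where(ctp > 0, ctp, np.nan)
    return float(out) if out.ndim == 0 else out


def flag_che(oop, ctp, config: CheConfig | None = None):
    """Binary CHE flag: 1 iff oop/ctp >= threshold (boundary inclusive).

    NaN CTP (exclusion signal) yields a NaN flag.
    """
    config = config or CheConfig()
    oop = np.asarray(oop, dtype=float)
    ctp = np.asarray(ctp, dtype=float)
    with np.errstate(invalid="ignore"):
        flags = np.where(
            np.isnan(ctp), np.nan, (oop >= config.threshold * ctp).astype(float)
        )
    return float(flags) if flags.ndim == 0 else flags


class CheFlagger(BaseEstimator):
    """Transformer adding a ``che`` flag column to a household panel.

    Rows with CTP <= 0 receive a NaN flag and are counted in
    ``exclusions_``; downstream incidence/inequality stages drop them.

    Parameters mirror :class:`CheConfig`.
    """

    def __init__(self, threshold: float = 0.40, ctp_definition: str = "nonfood",
                 ci_method: str = "normal"):
        self.threshold = threshold
        self.ctp_definition = ctp_definition
        self.ci_method = ci_method

    @property
    def config_(self) -> CheConfig:
        return CheConfig(self.threshold, self.ctp_definition, self.ci_method)

    def fit(self, X: pd.DataFrame, y=None):
        cfg = self.config_  # validates parameters
        if "oop" not in X.columns or "nonfood_exp" not in X.columns:
            raise KeyError("panel must contain 'oop' and 'nonfood_exp' columns")
        self.n_excluded_ = int((X["nonfood_exp"] <= 0).sum())
        self.config_checked_ = cfg
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cfg = self.config_
        out = X.copy()
        ctp = compute_ctp(out["nonfood_exp"].to_numpy(), cfg)
        out["ctp"] = ctp
        out["che"] = flag_che(out["oop"].to_numpy(), ctp, cfg)
        return out

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)

    def incidence_by_wave(self, X: pd.DataFrame) -> list[CheResult]:
        flagged = self.fit_transform(X)
        return [
            incidence(flagged, self.config_, wave)
            for wave in sorted(flagged["wave"].unique())
        ]


def _proportion_ci(k: int, n: int, method: str) -> tuple[float, float]:
    p = k / n
    if method == "wilson":
        lo, hi = stats.binomtest(k, n).proportion_ci(method="wilson")
        return float(lo), float(hi)
    se = np.sqrt(p * (1 - p) / n)
    return float(max(0.0, p - _Z95 * se)), float(min(1.0, p + _Z95 * se))


def incidence(panel: pd.DataFrame, config: CheConfig | None = None,
              wave=None) -> CheResult:
    """CHE incidence for one wave: flagged households over includable ones.

    ``panel`` must carry a ``che`` column (see :class:`CheFlagger`) or the
    raw ``oop``/``nonfood_exp`` columns, in which case flags are computed.
    The 95% interval uses the normal approximation by default, clamped to
    [0, 1]; a Wilson interval is available via ``config.ci_method``.
    """
    config = config or CheConfig()
    df = panel
    if wave is not None:
        df = df[df["wave"] == wave]
        if df.empty:
            raise ValueError(f"no records for wave {wave!r}")
    if "che" not in df.columns:
        flags = flag_che(df["oop"].to_numpy(),
                         compute_ctp(df["nonfood_exp"].to_numpy(), config), config)
    else:
        flags = df["che"].to_numpy(dtype=float)
    flags = flags[~np.isnan(flags)]
    n = flags.size
    if n == 0:
        raise ValueError(f"no includable records for wave {wave!r}")
    k = int(flags.sum())
    return CheResult(
        wave=wave,
        n=n,
        n_che=k,
        incidence=k / n,
        ci95=_proportion_ci(k, n, config.ci_method),
    )
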