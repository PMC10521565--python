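"""Seeded synthetic household-panel generator.

Emulates a balanced rural household panel in the style of the China Health
and Retirement Longitudinal Study (CHARLS): ~2,575 households observed in
three waves (2013/2015/2018), with head-of-household covariates at their
published 2013 marginal prevalences, log-normal household income, non-food
expenditure as a clamped share of income (the capacity-to-pay base), and
out-of-pocket health spending (OOP) that is zero with some probability and
otherwise gamma-distributed.

The income gradient is the generator's key inequality knob.  Positive OOP is

    OOP = Gamma(shape, scale) * (income / exp(income_log_mean))
          * exp(income_gradient * (log income - income_log_mean)
                + covariate effects + age-band effect + wave effect)

so OOP has income elasticity ``1 + income_gradient``: at gradient 0 the OOP
share of capacity to pay is independent of income (a null concentration
index downstream), and a negative gradient makes poorer households spend a
larger share, inducing pro-poor inequality in catastrophic spending.

Default covariate prevalences follow the published 2013 household-head
descriptives (e.g. male 48.85%, chronic disease 66.52%, insurance 96.23%).
Everything is driven by a single numpy Generator seeded once per panel, so
identical config + seed yields a bit-identical panel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, PanelParseError, SchemaError

__all__ = [
    "GeneratorConfig",
    "PanelDataset",
    "generate_panel",
    "expected_marginals",
    "write_panel",
    "read_panel",
    "PANEL_COLUMNS",
]

PANEL_COLUMNS = [
    "household_id", "wave", "income", "food_exp", "nonfood_exp", "oop",
    "male", "age_band", "age_years", "spouse", "hh_size", "edu_junior_plus",
    "insured", "smoke", "drink", "disability", "chronic",
    "outpatient", "outpatient_times", "inpatient", "inpatient_times",
]

AGE_BANDS = ("<=50", "51-60", "61-70", ">=71")

# 2013 marginal prevalences of the head-of-household indicators
DEFAULT_PREVALENCES = {
    "male": 0.4885,
    "spouse": 0.8769,
    "edu_junior_plus": 0.2757,
    "insured": 0.9623,
    "smoke": 0.6159,
    "drink": 0.4866,
    "disability": 0.0691,
    "chronic": 0.6652,
    "outpatient": 0.2959,
    "inpatient": 0.1068,
}

# published band frequencies (<=50, 51-60, 61-70, >=71); renormalised at use
DEFAULT_AGE_BAND_PROBS = (0.0183, 0.3243, 0.4062, 0.2513)

# log-scale shifts on positive OOP spending
DEFAULT_COVARIATE_EFFECTS = {
    "chronic": 0.35,
    "disability": 0.25,
    "outpatient": 0.45,
    "inpatient": 0.70,
}
DEFAULT_AGE_BAND_EFFECTS = {"<=50": 0.0, "51-60": 0.15, "61-70": 0.35, ">=71": 0.55}
DEFAULT_WAVE_EFFECTS = {2013: 0.0, 2015: -0.10, 2018: 0.20}


@dataclass(frozen=True)
class GeneratorConfig:
    """All distributional knobs, plus the seed, for one synthetic panel."""

    n_households: int = 2575
    n_waves: int = 3
    seed: int = 0
    waves: tuple[int, ...] = (2013, 2015, 2018)
    income_log_mean: float = 9.4
    income_log_sd: float = 0.8
    income_wave_sd: float = 0.15
    nonfood_share_mean: float = 0.45
    nonfood_share_sd: float = 0.15
    food_share_mean: float = 0.30
    food_share_sd: float = 0.08
    oop_base_rate: float = 0.85
    oop_gamma_shape: float = 0.8
    oop_gamma_scale: float = 800.0
    income_gradient: float = -0.3
    covariate_prevalences: dict = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    age_band_probs: tuple[float, ...] = DEFAULT_AGE_BAND_PROBS
    age_band_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_AGE_BAND_EFFECTS))
    wave_effects: dict = field(default_factory=lambda: dict(DEFAULT_WAVE_EFFECTS))
    hh_size_mean: float = 1.69
    hh_size_sd: float = 0.46

    def __post_init__(self):
        if not (isinstance(self.n_households, (int, np.integer))
                and self.n_households >= 2):
            raise ConfigError(f"n_households must be an integer >= 2, "
                              f"got {self.n_households!r}")
        if not (isinstance(self.n_waves, (int, np.integer)) and self.n_waves >= 1):
            raise ConfigError(f"n_waves must be a positive integer, "
                              f"got {self.n_waves!r}")
        if len(self.waves) < self.n_waves:
            raise ConfigError("waves: fewer wave labels than n_waves")
        for name in ("income_log_sd", "income_wave_sd", "nonfood_share_sd",
                     "food_share_sd", "oop_gamma_shape", "oop_gamma_scale",
                     "hh_size_sd"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ConfigError(f"{name} must be > 0, got {v!r}")
        for name in ("oop_base_rate", "nonfood_share_mean", "food_share_mean"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v!r}")
        for cov, p in self.covariate_prevalences.items():
            if cov not in DEFAULT_PREVALENCES:
                raise ConfigError(f"covariate_prevalences: unknown covariate "
                                  f"{cov!r}")
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"covariate_prevalences[{cov!r}] must be in "
                                  f"[0, 1], got {p!r}")
        if len(self.age_band_probs) != len(AGE_BANDS):
            raise ConfigError("age_band_probs must have one entry per band")
        if any(p < 0 for p in self.age_band_probs) or sum(self.age_band_probs) <= 0:
            raise ConfigError("age_band_probs must be nonnegative, summing > 0")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        for key in ("waves", "age_band_probs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PanelDataset:
    """A balanced household panel: one row per (household_id, wave)."""

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in PANEL_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"panel missing mandatory column(s): {missing}")
        if (self.frame["income"] <= 0).any():
            raise ValueError("income must be strictly positive")
        if (self.frame[["nonfood_exp", "oop"]] < 0).to_numpy().any():
            raise ValueError("nonfood_exp and oop must be nonnegative")

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, PanelDataset) and self.frame.equals(other.frame)

    @property
    def n_households(self) -> int:
        return self.frame["household_id"].nunique()

    @property
    def waves(self) -> list:
        return sorted(self.frame["wave"].unique())

    @property
    def balanced(self) -> bool:
        counts = self.frame.groupby("household_id")["wave"].nunique()
        return bool((counts == len(self.waves)).all()) and len(self) == (
            self.n_households * len(self.waves))


def generate_panel(config: GeneratorConfig) -> PanelDataset:
    """Generate one balanced panel from a single seeded random stream."""
    rng = np.random.default_rng(config.seed)
    n = config.n_households
    waves = list(config.waves[: config.n_waves])

    # --- time-invariant household draws -------------------------------
    probs = np.asarray(config.age_band_probs, dtype=float)
    probs = probs / probs.sum()
    band_idx = rng.choice(len(AGE_BANDS), size=n, p=probs)
    band_lo = np.array([45.0, 51.0, 61.0, 71.0])[band_idx]
    band_hi = np.array([50.0, 60.0, 70.0, 90.0])[band_idx]
    age_years = np.round(band_lo + rng.random(n) * (band_hi - band_lo), 1)

    cov = {}
    for name in DEFAULT_PREVALENCES:
        p = config.covariate_prevalences.get(name, DEFAULT_PREVALENCES[name])
        cov[name] = (rng.random(n) < p).astype(np.int64)
    hh_size = np.clip(
        np.round(rng.normal(config.hh_size_mean, config.hh_size_sd, n)), 1, 8
    ).astype(np.int64)
    outpatient_times = cov["outpatient"] * (1 + rng.poisson(0.5, n))
    inpatient_times = cov["inpatient"] * (1 + rng.poisson(0.08, n))

    base_log_income = rng.normal(config.income_log_mean, config.income_log_sd, n)

    effect = np.zeros(n)
    for name, e in config.covariate_effects.items():
        if name not in cov:
            raise ConfigError(f"covariate_effects: unknown covariate {name!r}")
        effect += e * cov[name]
    band_effect = np.array(
        [config.age_band_effects.get(b, 0.0) for b in AGE_BANDS])[band_idx]
    effect += band_effect

    # --- per-wave draws ----------------------------------------------
    rows = []
    for wave in waves:
        log_inc = base_log_income + rng.normal(0.0, config.income_wave_sd, n)
        income = np.exp(log_inc)
        nf_share = np.clip(
            rng.normal(config.nonfood_share_mean, config.nonfood_share_sd, n),
            0.05, 0.95)
        food_share = np.clip(
            rng.normal(config.food_share_mean, config.food_share_sd, n),
            0.02, 0.90)
        spender = rng.random(n) < config.oop_base_rate
        magnitude = rng.gamma(config.oop_gamma_shape, config.oop_gamma_scale, n)
        shift = (config.income_gradient * (log_inc - config.income_log_mean)
                 + effect + config.wave_effects.get(wave, 0.0))
        oop = np.where(
            spender,
            magnitude * (income / np.exp(config.income_log_mean)) * np.exp(shift),
            0.0)
        rows.append(pd.DataFrame({
            "household_id": np.arange(n, dtype=np.int64),
            "wave": np.full(n, wave, dtype=np.int64),
            "income": income,
            "food_exp": food_share * income,
            "nonfood_exp": nf_share * income,
            "oop": oop,
            "male": cov["male"],
            "age_band": pd.Categorical.from_codes(band_idx, list(AGE_BANDS))
            .astype(str),
            "age_years": age_years,
            "spouse": cov["spouse"],
            "hh_size": hh_size,
            "edu_junior_plus": cov["edu_junior_plus"],
            "insured": cov["insured"],
            "smoke": cov["smoke"],
            "drink": cov["drink"],
            "disability": cov["disability"],
            "chronic": cov["chronic"],
            "outpatient": cov["outpatient"],
            "outpatient_times": outpatient_times,
            "inpatient": cov["inpatient"],
            "inpatient_times": inpatient_times,
        }))
    frame = pd.concat(rows, ignore_index=True)[PANEL_COLUMNS]
    return PanelDataset(frame)


def expected_marginals(config: GeneratorConfig) -> dict:
    """Configured marginal prevalence of every 0/1 covariate.

    Generated panels match these within binomial sampling error.
    """
    out = dict(DEFAULT_PREVALENCES)
    out.update(config.covariate_prevalences)
    return out


_FLOAT_COLS = ["income", "food_exp", "nonfood_exp", "oop", "age_years"]
_INT_COLS = [
    "household_id", "wave", "male", "spouse", "hh_size", "edu_junior_plus",
    "insured", "smoke", "drink", "disability", "chronic",
    "outpatient", "outpatient_times", "inpatient", "inpatient_times",
]


def write_panel(panel: PanelDataset, path) -> None:
    """Write a panel as UTF-8 comma-separated text with a header row.

    Floats are written in shortest round-trip form, so write -> read
    reproduces every numeric field bit-exactly.
    """
    panel.frame.to_csv(path, index=False)


def read_panel(path) -> PanelDataset:
    """Read a panel written by :func:`write_panel` (round-trip identity).

    Raises :class:`SchemaError` naming any missing mandatory column and
    :class:`PanelParseError` citing the file row of the first non-numeric
    value in a numeric column.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PANEL_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"panel file missing mandatory column(s): {missing}")
    frame = pd.DataFrame(index=raw.index)
    for col in PANEL_COLUMNS:
        if col == "age_band":
            frame[col] = raw[col].astype(str)
            continue
        values = pd.to_numeric(raw[col], errors="coerce")
        bad = values.isna() & (raw[col].str.strip().str.lower() != "nan")
        if bad.any():
            i = int(bad.idxmax())
            raise PanelParseError(
                f"non-numeric value {raw[col][i]!r} in column {col!r} "
                f"at file row {i + 2}")
        if col in _INT_COLS:
            frame[col] = values.astype(np.int64)
        else:
            # python float() is correctly rounded; pandas' fast csv parser
            # can be off by one ulp, breaking bit-exact round-trips
            frame[col] = raw[col].map(float).astype(float)
    return PanelDataset(frame)
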