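"""End-to-end orchestration: flags -> incidence -> index -> decomposition ->
heterogeneity strata -> robustness regressions, from a single RunConfig.

The bundle returned by :func:`run_pipeline` is a plain dict of stage results
(dataclasses and DataFrames) plus a run log recording exclusions, seeds and
settings.  :func:`render_tables` writes the published-table analogues as
delimited text and JSON with fixed numeric formatting (4 decimals for
indices, 2 for percents), so repeated runs with the same seed are
byte-stable.  A stage failure is recorded under its stage name and only its
downstream dependents are skipped.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .che import CheConfig, CheFlagger, incidence
from .decomposition import WagstaffDecomposition, build_design
from .exceptions import ConfigError, StageError
from .inequality import ConcentrationIndex, concentration_curve
from .regressions import CheLogistic, IncomeQuantileRegression
from .synthetic import GeneratorConfig, PanelDataset, generate_panel, read_panel

__all__ = [
    "StratumSpec",
    "RunConfig",
    "builtin_strata",
    "run_pipeline",
    "stratified_analysis",
    "render_tables",
    "bundle_to_jsonable",
]


@dataclass(frozen=True)
class StratumSpec:
    """One side of a heterogeneity split: a name, a row predicate, and the
    covariate group held out of that stratum's decomposition."""

    name: str
    predicate: object  # callable DataFrame -> boolean mask
    drop_family: tuple = ()


def builtin_strata() -> dict:
    """The supported heterogeneity splits, each a pair of complementary
    strata: age at the 65-year threshold, chronic disease, and education."""
    return {
        "age65": (
            StratumSpec("age_ge_65", lambda df: df["age_years"] >= 65, ("age",)),
            StratumSpec("age_lt_65", lambda df: df["age_years"] < 65, ("age",)),
        ),
        "chronic": (
            StratumSpec("chronic_yes", lambda df: df["chronic"] == 1, ("chronic",)),
            StratumSpec("chronic_no", lambda df: df["chronic"] == 0, ("chronic",)),
        ),
        "education": (
            StratumSpec("edu_junior_plus", lambda df: df["edu_junior_plus"] == 1,
                        ("education",)),
            StratumSpec("edu_elementary_below",
                        lambda df: df["edu_junior_plus"] == 0, ("education",)),
        ),
    }


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    Either ``input_path`` (a panel CSV) or ``generator`` must be set.  The
    seed feeds every stochastic method (generation when the generator has no
    explicit seed override, bootstrap intervals).
    """

    generator: GeneratorConfig | None = None
    input_path: str | None = None
    che: CheConfig = field(default_factory=CheConfig)
    rank_mode: str = "midpoint"
    se_method: str = "analytic"
    n_boot: int = 200
    seed: int = 0
    strata: tuple = ("age65", "chronic", "education")
    taus: tuple = (0.25, 0.50, 0.75)
    dummy_families: dict | None = None
    quantile_n_boot: int = 100
    output_dir: str | None = None

    def __post_init__(self):
        if self.generator is None and self.input_path is None:
            self.generator = GeneratorConfig(seed=self.seed)
        known = set(builtin_strata())
        unknown = [s for s in self.strata if s not in known]
        if unknown:
            raise ConfigError(f"unknown strata: {unknown}; choose from "
                              f"{sorted(known)}")
        if self.se_method not in ("analytic", "bootstrap"):
            raise ConfigError(f"unknown se_method: {self.se_method!r}")


def _load_panel(config: RunConfig) -> PanelDataset:
    if config.input_path is not None:
        return read_panel(config.input_path)
    return generate_panel(config.generator)


def stratified_analysis(flagged: pd.DataFrame, config: RunConfig,
                        strata_names) -> dict:
    """Per-stratum, per-wave concentration index and decomposition.

    Income ranks are recomputed *within* each stratum, so a stratum's index
    measures inequality inside that subpopulation; the stratifying variable's
    own dummy family is held out of its decomposition.  Empty strata are
    skipped with a warning naming them.
    """
    catalogue = builtin_strata()
    out = {}
    for split in strata_names:
        if split not in catalogue:
            raise ConfigError(f"unknown stratum: {split!r}")
        out[split] = {}
        for spec in catalogue[split]:
            mask = spec.predicate(flagged)
            sub = flagged[mask]
            if sub["che"].notna().sum() == 0:
                warnings.warn(f"stratum {spec.name!r} is empty; skipped",
                              stacklevel=2)
                continue
            per_wave = {}
            for wave in sorted(sub["wave"].unique()):
                X, y, inc = build_design(sub, wave, drop=spec.drop_family)
                ci = ConcentrationIndex(
                    rank_mode=config.rank_mode, se_method=config.se_method,
                    n_boot=config.n_boot, seed=config.seed,
                ).fit(y.to_numpy(), inc.to_numpy())
                entry = {"n": int(len(y)), "index": ci.result_,
                         "decomposition": None}
                try:
                    dec = WagstaffDecomposition(
                        dummy_families=config.dummy_families,
                        rank_mode=config.rank_mode,
                    ).fit(X, y.to_numpy(), inc.to_numpy(), wave=wave)
                    entry["decomposition"] = dec.result_
                except Exception as exc:
                    warnings.warn(
                        f"decomposition failed in stratum {spec.name!r}, "
                        f"wave {wave}: {exc}", stacklevel=2)
                per_wave[wave] = entry
            out[split][spec.name] = per_wave
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return the report bundle.

    Bundle keys: ``panel`` (the flagged frame), ``incidence``,
    ``concentration``, ``curves``, ``decomposition`` (all keyed or listed by
    wave), ``logistic``, ``quantile``, ``strata``, and ``log``.
    """
    log = {
        "software": {"chequity": __version__},
        "seed": config.seed,
        "settings": {
            "threshold": config.che.threshold,
            "rank_mode": config.rank_mode,
            "se_method": config.se_method,
            "n_boot": config.n_boot,
        },
        "errors": {},
    }
    bundle = {"log": log}

    panel = _load_panel(config)
    flagger = CheFlagger(threshold=config.che.threshold,
                         ctp_definition=config.che.ctp_definition,
                         ci_method=config.che.ci_method)
    flagged = flagger.fit_transform(panel.frame)
    log["exclusions"] = {"ctp_nonpositive": flagger.n_excluded_,
                         "included": int(flagged["che"].notna().sum())}
    bundle["panel"] = flagged
    waves = sorted(flagged["wave"].unique())

    def stage(name, fn, *deps):
        if any(bundle.get(d) is None for d in deps):
            log["errors"].setdefault(name, "skipped: upstream stage failed")
            bundle[name] = None
            return
        try:
            bundle[name] = fn()
        except Exception as exc:
            log["errors"][name] = f"{type(exc).__name__}: {exc}"
            bundle[name] = None

    stage("incidence", lambda: [incidence(flagged, config.che, w)
                                for w in waves])

    def _concentration():
        res = {}
        for w in waves:
            sub = flagged[(flagged["wave"] == w) & flagged["che"].notna()]
            est = ConcentrationIndex(
                rank_mode=config.rank_mode, se_method=config.se_method,
                n_boot=config.n_boot, seed=config.seed)
            est.fit(sub["che"].to_numpy(), sub["income"].to_numpy())
            res[w] = est.result_
        return res

    stage("concentration", _concentration)

    def _curves():
        return {
            w: concentration_curve(
                sub["che"].to_numpy(), sub["income"].to_numpy())
            for w in waves
            for sub in [flagged[(flagged["wave"] == w) & flagged["che"].notna()]]
        }

    stage("curves", _curves, "concentration")

    def _decomposition():
        res = {}
        for w in waves:
            X, y, inc = build_design(flagged, w)
            res[w] = WagstaffDecomposition(
                dummy_families=config.dummy_families,
                rank_mode=config.rank_mode,
            ).fit(X, y.to_numpy(), inc.to_numpy(), wave=w).result_
        return res

    stage("decomposition", _decomposition, "concentration")

    def _logistic():
        X, y, _ = build_design(flagged)
        return CheLogistic().fit(X, y.to_numpy()).result_

    stage("logistic", _logistic)

    def _quantile():
        sub = flagged[flagged["che"].notna()]
        wave_order = {w: i for i, w in enumerate(waves)}
        X = pd.DataFrame({
            "che": sub["che"].to_numpy(),
            "time": sub["wave"].map(wave_order).to_numpy(dtype=float),
            "male": sub["male"], "age_years": sub["age_years"],
            "spouse_else": 1.0 - sub["spouse"], "hh_size": sub["hh_size"],
            "edu_junior_plus": sub["edu_junior_plus"],
            "insured": sub["insured"], "smoke": sub["smoke"],
            "drink": sub["drink"], "disability": sub["disability"],
            "chronic": sub["chronic"], "outpatient": sub["outpatient"],
            "outpatient_times": sub["outpatient_times"],
            "inpatient": sub["inpatient"],
            "inpatient_times": sub["inpatient_times"],
        }).reset_index(drop=True)
        est = IncomeQuantileRegression(
            taus=config.taus, n_boot=config.quantile_n_boot, seed=config.seed)
        est.fit(X, sub["income"].to_numpy(),
                cluster=sub["household_id"].to_numpy())
        return est.fits_

    stage("quantile", _quantile)

    stage("strata",
          lambda: stratified_analysis(flagged, config, config.strata))

    if config.output_dir is not None:
        render_tables(bundle, config.output_dir)
    return bundle


# ----------------------------------------------------------------------
# rendering


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, pd.DataFrame):
        return {str(k): _jsonable(v)
                for k, v in obj.to_dict(orient="index").items()}
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def bundle_to_jsonable(bundle: dict) -> dict:
    """The bundle as plain JSON types (the flagged panel is summarised,
    not embedded)."""
    out = {}
    for key, value in bundle.items():
        if key == "panel":
            out[key] = {"n_rows": int(len(value)),
                        "waves": [int(w) for w in sorted(value["wave"].unique())]}
        else:
            out[key] = _jsonable(value)
    return out


def _fmt_decomposition(result) -> pd.DataFrame:
    rows = result.rows.reset_index()
    out = pd.DataFrame({
        "variable": rows["variable"],
        "elasticity": rows["elasticity"].round(4),
        "cindex": rows["cindex"].round(4),
        "contribution": rows["contribution"].round(4),
        "percent": rows["percent"].round(2),
    })
    tail = pd.DataFrame({
        "variable": ["residual", "total"],
        "elasticity": [np.nan, np.nan],
        "cindex": [np.nan, np.nan],
        "contribution": [round(result.residual, 4), round(result.total, 4)],
        "percent": [round(result.residual_percent, 2), 100.0],
    })
    return pd.concat([out, tail], ignore_index=True)


def render_tables(bundle: dict, outdir, formats=("csv", "json")) -> list[Path]:
    """Write the bundle's published-table analogues under ``outdir``.

    Emits per-wave incidence, concentration index, decomposition (one file
    per wave and per stratum), logistic odds ratios, quantile coefficients,
    curve coordinates, the full bundle as JSON, and the run log.  Indices are
    formatted to 4 decimals and percents to 2, matching the tables mirrored.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, frame: pd.DataFrame):
        if "csv" in formats:
            p = outdir / f"{name}.csv"
            frame.to_csv(p, index=False)
            written.append(p)

    def require(key):
        if bundle.get(key) is None:
            raise StageError(f"cannot render {key!r}: stage output missing")
        return bundle[key]

    inc = require("incidence")
    emit("incidence", pd.DataFrame([{
        "wave": r.wave, "n": r.n, "n_che": r.n_che,
        "incidence": round(r.incidence, 4),
        "ci_low": round(r.ci95[0], 4), "ci_high": round(r.ci95[1], 4),
    } for r in inc]))

    conc = require("concentration")
    emit("concentration_index", pd.DataFrame([{
        "wave": w, "index": round(r.index, 4),
        "ci_low": round(r.ci95[0], 4), "ci_high": round(r.ci95[1], 4),
        "se": round(r.se, 4), "n": r.n,
    } for w, r in conc.items()]))

    if bundle.get("curves") is not None:
        for w, curve in bundle["curves"].items():
            emit(f"concentration_curve_{w}", pd.DataFrame(
                curve.points, columns=["population_share", "outcome_share"]))

    if bundle.get("decomposition") is not None:
        for w, res in bundle["decomposition"].items():
            emit(f"decomposition_{w}", _fmt_decomposition(res))
            emit(f"decomposition_groups_{w}",
                 res.group_totals.round(4).reset_index(names="family"))

    if bundle.get("logistic") is not None:
        emit("logistic_odds_ratios",
             bundle["logistic"].table.round(4).reset_index(names="variable"))

    if bundle.get("quantile") is not None:
        frames = []
        for tau, fit in bundle["quantile"].items():
            f = pd.DataFrame({
                "tau": tau,
                "variable": fit.coefficients.index,
                "coefficient": fit.coefficients.round(4).to_numpy(),
                "ci_low": fit.ci95["ci_low"].round(4).to_numpy(),
                "ci_high": fit.ci95["ci_high"].round(4).to_numpy(),
            })
            frames.append(f)
        emit("quantile_regression", pd.concat(frames, ignore_index=True))

    if bundle.get("strata") is not None:
        idx_rows, dec_written = [], []
        for split, sides in bundle["strata"].items():
            for name, per_wave in sides.items():
                for w, res in per_wave.items():
                    r = res["index"]
                    idx_rows.append({
                        "split": split, "stratum": name, "wave": w,
                        "n": res["n"], "index": round(r.index, 4),
                        "ci_low": round(r.ci95[0], 4),
                        "ci_high": round(r.ci95[1], 4),
                    })
                    if res["decomposition"] is not None:
                        emit(f"decomposition_{name}_{w}",
                             _fmt_decomposition(res["decomposition"]))
                        dec_written.append((name, w))
        emit("strata_index", pd.DataFrame(idx_rows))

    if "json" in formats:
        p = outdir / "bundle.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(bundle_to_jsonable(bundle), fh, indent=1, sort_keys=True)
        written.append(p)
        p = outdir / "run_log.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(_jsonable(bundle["log"]), fh, indent=1, sort_keys=True)
        written.append(p)
    return written
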