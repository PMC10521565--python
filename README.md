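# chequity

Income-related inequality in **catastrophic health expenditure (CHE)** for
household panel surveys: CHE flagging, concentration curves and the
concentration index, a probit-marginal-effects (Wagstaff) decomposition of
the index into determinant contributions, heterogeneity strata, and
logistic/quantile robustness regressions — plus a seeded synthetic
household-panel generator emulating a CHARLS-style rural panel, so the whole
pipeline runs and is tested without restricted survey microdata.

Intended users: health economists and epidemiologists analysing
out-of-pocket spending burdens in survey panels, and anyone who needs a
tested, reproducible implementation of the concentration-index toolkit.

## The statistics in brief

* A household is **catastrophic** when `OOP / CTP >= 0.40`, where OOP is
  out-of-pocket health spending and CTP (capacity to pay) is non-food
  expenditure; the 40% boundary is inclusive.
* The **concentration index** of an outcome `y` against income is
  `C = (2/μ)·cov(y, R)` with `μ = mean(y)` and `R` the weighted midpoint
  fractional income rank; `C < 0` means the outcome is concentrated among
  the poor. The concentration curve satisfies `C = 1 − 2·area`.
* The **decomposition** writes `C = Σ_j (β_j^m x̄_j/μ)·C_j + residual`,
  where `β_j^m` is the probit average marginal effect of determinant `j`
  and `C_j` its own concentration index; contributions are reported per
  determinant and summed over dummy families (economic status, age bands).
* Robustness: pooled logistic odds ratios with wave fixed effects, and
  Koenker quantile regressions of income on the CHE flag at
  τ ∈ {0.25, 0.5, 0.75} with household-cluster bootstrap intervals.

See `docs/methods.md` for conventions, numerics, and generator details.

## Worked example

```python
import chequity as cq
from chequity.che import CheFlagger

panel = cq.generate_panel(cq.GeneratorConfig(n_households=2575, seed=1))
flagger = CheFlagger()
flagged = flagger.fit_transform(panel.frame)

for res in flagger.incidence_by_wave(panel.frame):
    print(f"{res.wave}: incidence {res.incidence:.4f} "
          f"(95% CI {res.ci95[0]:.4f}, {res.ci95[1]:.4f}), n={res.n}")

sub = flagged[(flagged["wave"] == 2013) & flagged["che"].notna()]
ci = cq.concentration_index(sub["che"].to_numpy(), sub["income"].to_numpy())
print(f"2013 concentration index: {ci.index:.4f} "
      f"(95% CI {ci.ci95[0]:.4f}, {ci.ci95[1]:.4f})")

X, y, inc = cq.build_design(flagged, 2013)
dec = cq.decompose_ci(X, y.to_numpy(), inc.to_numpy(), wave=2013)
print(dec.group_totals.round(4))
print(f"residual: {dec.residual:.4f} ({dec.residual_percent:.2f}%)")
```

prints

```
2013: incidence 0.2105 (95% CI 0.1947, 0.2262), n=2575
2015: incidence 0.2047 (95% CI 0.1891, 0.2202), n=2575
2018: incidence 0.2637 (95% CI 0.2467, 0.2807), n=2575
2013 concentration index: -0.1096 (95% CI -0.1530, -0.0661)
                 contribution  percent
age                    0.0024  -2.1555
economic_status       -0.1001  91.3889
residual: -0.0095 (8.69%)
```

Reading it: about 21% of households in the 2013 wave spend catastrophically;
the negative index says catastrophic spending is concentrated among poorer
households (the default generator has a negative income gradient in the OOP
share); and the decomposition attributes almost all of that inequality to
economic status — in synthetic panels the other covariates are drawn
independently of income, so their contributions sit near zero by design.

The same run from the shell:

```sh
chequity generate --n-households 2575 --seed 1 --out panel.csv
chequity run --input panel.csv --seed 1 --out-dir report/
```

writes `incidence.csv`, `concentration_index.csv`, per-wave and per-stratum
`decomposition_*.csv`, `logistic_odds_ratios.csv`, `quantile_regression.csv`,
curve coordinates, and a full `bundle.json` + `run_log.json` (exclusion
counts, seeds, settings). Exit codes: 0 ok, 2 validation error, 3 stage
failure.

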