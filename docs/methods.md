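# Methods

`chequity` measures income-related inequality in catastrophic health
expenditure (CHE) in household panel surveys and attributes that inequality
to household determinants. This note records the model, the estimator
conventions, the synthetic-data generator's assumptions, and the numerical
choices, in the order a user meets them.

## CHE definition

A household-wave is flagged as catastrophic when out-of-pocket health
spending (OOP) reaches a threshold share of capacity to pay (CTP):

    CHE = 1{ OOP / CTP >= z },   z = 0.40 by default.

CTP is household non-food expenditure. The boundary is **inclusive** ("40%
or more"); the flag is monotone in OOP and antitone in CTP. Records with
CTP <= 0 have an undefined ratio: they are excluded rather than errored,
and every run reports the excluded count so the dropped fraction is
visible. Per-wave incidence is the flagged share of includable households,
with a normal-approximation 95% interval clamped to [0, 1] (a Wilson
interval is available via `CheConfig(ci_method="wilson")`; the normal form
is the default because it reproduces the printed-precision intervals of the
survey literature this package mirrors, e.g. 603/2,575 flagged households
gives 0.2342 with an interval rounding to (0.22, 0.25)).

## Concentration index

For outcome `y` (the CHE flag, or any non-negative outcome) and fractional
income rank `R`,

    C = (2 / mu) * cov(y, R),     mu = mean(y).

Negative C means the outcome is concentrated among poorer households.

**Rank convention.** Ranks are weighted *midpoint* ranks: sort by income
ascending and assign `(cumulative weight before i + w_i/2) / W`; ties get
the weighted average of their midpoint ranks. This makes the weighted mean
rank exactly 0.5, so three algebraically equivalent routes coincide to
machine precision (asserted in tests): the covariance form, the equal-weight
direct sum `2/(n mu) * sum(y_i R_i) - 1`, and the "convenient regression"
slope of `2 var(R) y_i / mu` on `R_i`. A `paper` rank mode implementing the
plain `i/N` rank is provided for sensitivity only; its mean is not 0.5 and
it biases the covariance form, so it is never the default.

**Uncertainty.** The analytic standard error is the heteroskedasticity-
robust (HC1) SE of the convenient-regression slope; the alternative is a
seeded percentile bootstrap over households (degenerate resamples with
mu = 0 are redrawn, counted, and warned about). For a binary outcome with
mean mu the plain index is bounded by |C| <= 1 - mu; Wagstaff
(divide by 1 - mu) and Erreygers (multiply by 4 mu) corrections are
available behind explicit flags but are off by default, since the plain
index is what the mirrored tables report.

**Curve.** The concentration curve plots cumulative outcome share against
cumulative population share, poorest first, through (0,0) and (1,1). For
midpoint ranks the trapezoidal area satisfies `C = 1 - 2 * area` exactly at
the data's own resolution; resampling to an `n_points` grid preserves the
identity to ~1e-3 at 10^4 points.

## Decomposition

Because CHE is binary, the determinants model is a probit,
`P(CHE=1|x) = Phi(a + x'b)`, and the index decomposes as

    C = sum_j (beta_j^m * xbar_j / mu) * C_j + residual,

where `beta_j^m` is the **average marginal effect** of determinant j (the
sample mean of `phi(x_i'b) * b_j`; an effects-at-means mode exists for
sensitivity), `C_j` is the concentration index of the determinant computed
by the same code path against the same income ranks, and the elasticity
`beta_j^m xbar_j / mu` scales it. The residual is computed as the remainder
`C - sum of contributions`, which (i) agrees analytically with the
generalised concentration index of the probit residuals over mu and (ii)
guarantees the identity numerically to 1e-10 — it is an accounting
definition, not an estimate. Percent contributions are reported both raw
(summing to 100 minus the residual percent) and rescaled to exclude the
residual, since published tables are ambiguous about which they print.

Dummy families (the four economic-status quintile dummies against the
lowest, the three age bands against <=50) are declared explicitly so group
totals are sums of member rows, exactly — this is also how the package
verifies published table internals (e.g. 2013 economic-status percents
1.36 − 0.05 + 15.41 + 56.78 = 73.50).

**Probit numerics.** Newton iterations to gradient tolerance 1e-8, with a
BFGS fallback (same tolerance) because Newton can cycle under
quasi-separation, e.g. an event-free reference cell in a small stratum.
Fits whose coefficients are non-finite or exceed 10 on the latent scale are
rejected as separated, with the suspect column named; in stratified runs
such a stratum-wave keeps its concentration index and loses only its
decomposition, with a warning.

## Robustness regressions

* **Pooled logistic**: CHE on all determinants with wave fixed effects
  (earliest wave as reference), reported as odds ratios with Wald 95%
  intervals.
* **Quantile regression** at tau in {0.25, 0.50, 0.75} of household
  *income* on the CHE flag and covariates. The direction is deliberately
  reversed from the usual regression — income is the dependent variable —
  because that is the robustness surface being mirrored: a negative CHE
  coefficient growing in magnitude with tau is the quantile-domain
  signature of pro-poor CHE inequality. The solver is statsmodels' IRLS
  smoothing of the check loss (parameter tolerance 1e-8; it interpolates
  noise-free data exactly), and intervals come from a household-cluster
  percentile bootstrap, resampling whole households to respect the panel.

## Heterogeneity

Strata: age of head at the 65-year threshold, chronic disease, education
(junior high and above vs elementary and below). Ranks are recomputed
**within** each stratum, so a stratum's index measures inequality inside
that subpopulation (a global-rank sensitivity is possible by passing
precomputed ranks). Each stratum's decomposition drops the stratifying
variable's own dummy family, which is near-constant within the stratum.
The two sides of a split partition the includable records exactly.

## Synthetic panel generator

The generator emulates a balanced rural household panel in the style of
CHARLS: 2,575 households by default, three waves labelled 2013/2015/2018,
head-of-household covariates drawn once per household at the published 2013
marginal prevalences (male 48.85%, chronic 66.52%, insurance 96.23%, ...),
age drawn as a band with the published band frequencies plus a continuous
age inside the band (so the 65-year split is well defined), and household
size as a clipped rounded normal (mean 1.69, sd 0.46).

Money flows, per wave:

* income: log-normal, `log income ~ N(9.4, 0.8^2)` (roughly 12,000
  currency units/year at the median, right-skewed), with an `N(0, 0.15^2)`
  per-wave log jitter around each household's base draw;
* non-food expenditure (the CTP base): a `N(0.45, 0.15^2)` share of
  income, clamped to (0.05, 0.95); food expenditure analogously with a
  0.30 mean share;
* OOP: zero with probability 0.15, else
  `Gamma(0.8, 800) * (income / exp(9.4)) * exp(g*(log income - 9.4) + covariate effects + wave effect)`.

The income elasticity of OOP is therefore `1 + g`. At `g = 0` the OOP
*share* of capacity to pay is independent of income, so the downstream
concentration index of CHE is null — the generator's key testable
property. The default `g = -0.3` makes poorer households spend a larger
share, producing incidence near 0.21–0.26 across waves and indices near
−0.10 to −0.14, the realistic range for rural household surveys of this
kind. Wave effects {2013: 0, 2015: −0.10, 2018: +0.20} reproduce the
published direction of the wave odds ratios (a dip then a rise). Covariate
effects (chronic +0.35, disability +0.25, outpatient +0.45, inpatient
+0.70, age bands 0/0.15/0.35/0.55 on the log scale) give the logistic
stage realistic determinants.

One `numpy.random.Generator` seeded once drives the whole panel, so
identical config + seed is bit-identical, and the CSV writer emits
shortest round-trip floats so write → read reproduces panels exactly
(parsed with Python's correctly rounded `float`, since fast CSV float
parsers can be one ulp off).

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: sampling weights and attrition, the
screening cascade that produces a real analysis sample, within-household
rosters (covariates are head-of-household only), serial correlation in OOP
beyond the household random effect implicit in time-invariant covariates,
and any correlation between age/education and income (covariates are drawn
independently of income, so their decomposition contributions are near
zero by construction; only economic status, which is derived from income,
carries a large contribution in synthetic runs). Real-survey headline
values are therefore not reproduction targets at desk scale; the test
suite instead pins the estimators to closed-form oracles, algebraic
identities, and known-truth simulations at n = 20,000–50,000.

## Problem sizes and determinism

Default analysis runs use 2,575 households × 3 waves. Recovery experiments
use single-wave panels of 20,000 households (index sign/null calibration,
20 seeds) and simulated designs of 50,000 rows (probit/logistic coefficient
recovery), sizes at which Monte-Carlo error is comfortably smaller than the
3-standard-error acceptance bands. Every stochastic method takes an
explicit seed; a pipeline run with a fixed seed is byte-stable, including
its rendered tables (indices to 4 decimals, percents to 2).

## Known limitations

* The probit separation guard (latent coefficients > 10) is a heuristic;
  genuinely enormous but identified effects would be misclassified, which
  does not arise at the effect sizes of household-survey determinants.
* The analytic index SE treats ranks as fixed; the bootstrap is the
  reference when the sampling design matters.
* Quantile-regression intervals use the percentile bootstrap with a modest
  default replicate count (bias-corrected intervals are out of scope).
* Economic-status quintiles are recomputed within wave from the data at
  hand; with precomputed official quintiles, pass them as covariates
  directly.
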