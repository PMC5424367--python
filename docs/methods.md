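# Methods

## The aggregate model

The package implements the aggregate (all-ages) proximate-determinants
model of fertility. Observed fertility is expressed as the biological
maximum TF attenuated by four multiplicative indices,

TFR = Cm · Cc · Ci · Ca · TF,

each in [0, 1] with 1 meaning "this determinant inhibits nothing".
TF = 15.3 births per woman, the canonical total-fecundity constant
derived from the highest-fertility historical populations. The model's
core assumptions: only women in union are exposed to conception risk
(Cm), contraceptive use and sterility are mutually exclusive (the 1.08
correction in Cc), and the birth interval decomposes additively into
1.5 months minimum postpartum anovulation + 7.5 waiting to conception +
2 intrauterine mortality + 9 gestation, so that absent breastfeeding
and abstinence the interval is 20 months and with them 18.5 + i (Ci).

The identity TFR_predicted = Cm·Cc·Ci·Ca·TF holds *exactly* for every
fitted index set; the predicted and the observed (birth-history) TFR
are both reported and generally differ — under-reporting of births,
misreported behaviours and omitted determinants all land in that gap.

## Estimation choices

**Reference window.** Rates and the current-status estimators share one
window: births 1–36 months before interview (the DHS convention for
published TFRs). Configurable via `window_months` (≥ 12).

**Age attribution.** Completed age, `floor((month − dob)/12)`, at the
event month; 5-year bins [15, 20) … [45, 50). Person-months outside
15–49 are dropped from exposure.

**Cm.** Default is the weighted-sum formula Σ m(a) g(a) / Σ g(a) with
m(a) the weighted proportion currently married at interview and g(a)
the marital fertility schedule; `cm_method: ratio` switches to
TFR/TMFR. The two agree when all fertility is marital and m(a) is flat
over the window; with nonmarital fertility they diverge, which is
exactly the diagnostic the comparison is for. Births are classed as
marital by the mother's *current* status — the standard approximation
when the schema carries no union histories; it misclassifies births
that preceded a dissolution or followed a marriage.

**Cc.** u counts married women using *any* method, traditional
included; e is the use-effectiveness of the users' method mix. The
default effectiveness schedule (sterilization 1.00, IUD 0.95, hormonal
0.90, barrier/LAM 0.70, traditional 0.50) is the standard
use-effectiveness table and is fully overridable in config — the index
is only as good as this table. A negative 1 − 1.08ue is a domain error,
not a clamp.

**Ci.** i defaults to a current-status (prevalence/incidence)
estimator: weighted women currently insusceptible ÷ mean monthly
weighted births over the window. In a stationary process prevalence =
incidence × mean duration, so no duration reporting is needed; the
estimator is biased upward slightly when durations spill past the
window (≈ +0.3 months at i = 11.5 with a 36-month window) and assumes
the birth stream is stationary. `i_estimator: reported_duration`
instead averages an optional reported-duration column. i < 1.5 months
yields Ci > 1; the value is reported with a warning, never clamped —
surfacing inconsistent data beats masking it.

**Ca.** TA defaults to 0 (abortion data are rarely usable where the
model is applied), giving Ca = 1; the full formula with births averted
b = 0.4(1 + u) is implemented and tested for nonzero TA.

**Degenerate inputs.** Zero-exposure age groups get rate 0 plus a flag
rather than an error, so small strata don't abort a decomposition; a
stratum with no married women or no births in the window reports an
undefined-index failure in its own flags and leaves the other strata
intact. Empty stratifier values form an explicit `(missing)` category.
Education is re-binned to {none, primary, secondary+} for decomposition
(the map is config-visible as `education_bins`) while ingest keeps four
levels.

## The synthetic cohort generator

`simulate_cohort` emulates the women's-recode slice the estimators
consume. Per woman: a 5-year age group is drawn (default distribution
follows a young, high-fertility age pyramid), exact age uniform within
the group; current marital status from a per-age-group schedule
(default rising from 0.20 at 15–19 to ~0.80); among married women,
contraceptive use with probability `u_true` and a method from
`method_mix` (default injectable-dominated with a traditional tail).
The reproductive history then runs month by month from exact age 15
through exposed → pregnant (9 months) → postpartum insusceptible →
exposed. Monthly conception probability is `fecundability` (default
0.20) times (1 − e_method) for users, times `nonmarital_exposure_factor`
(default 0 — no premarital or post-union exposure) for currently
unmarried women. Insusceptibility durations are geometric on {1, 2, …}
with mean `insusceptibility_mean` (default 11.5 months) — the simplest
discrete distribution with a controllable mean and the memorylessness
the current-status estimator assumes nothing about; the draw is
per-birth. `insusceptible_now` is the state at interview. Stratifiers
are drawn independently; per-category overrides of `u_true`,
`fecundability` and `insusceptibility_mean` plant socioeconomic
differentials. Everything is deterministic under (seed, params).

What the generator does **not** emulate — and hence what passing
recovery tests do not establish about real survey data: marriage *and*
use are current-status draws applied to the whole history (a woman
currently married/using is treated as married/using since age 15), so
there is no union formation or dissolution timing, no method switching,
no secondary sterility, twinning, mortality or migration, no
age-varying fecundability, and no reporting error (displacement or
omission of births, age heaping). Recovery results therefore validate
the estimators' internal consistency, not their robustness to those
real-data features.

## Problem sizes and tolerances

The recovery experiment uses 20 cohorts of n = 2000 women (u = 0.30,
mean effectiveness 0.95 via an even sterilization/injection mix,
i = 11.5 months, all married): mean absolute errors are ≈ 0.008 for u,
≈ 0.008 for Cc, ≈ 0.008 for Ci and ≈ 0.4 months for i — comfortably
inside the documented bands (0.02 / 0.03 / 0.03 / 1.0). Oracle
comparisons (vectorised schedules vs a per-woman per-month pure-Python
loop) run on 500-woman cohorts and agree to ~1e-13 relative; the
formula/ratio Cm equivalence is checked both algebraically
(f(a) = m(a) g(a) by construction) and on all-married cohorts, to 1e-9.
Rendered tables round half-up: indices to 6 decimals, TFR and percents
to 1.

## Known limitations

* Current-status marital classification of births biases marital
  fertility when unions are unstable.
* The prevalence/incidence estimator of i needs a reasonably stationary
  birth stream; sharp recent fertility change biases it.
* No survey-design variance: all outputs are point estimates. Small
  strata are flagged (`min_stratum_n`, default 100), not corrected.
* The age-specific variant of the model and the pathological-sterility
  index are out of scope.
* Native .dta/.sav recode parsing is out of scope; map exported CSVs
  via `column_map` instead.
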