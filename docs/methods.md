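# Methods

## The problem

Person-level health databases (drug dispensing registers, EHRs, claims
databases) accumulate systematically wrong birthdates: software "zero dates"
substituted for missing values (1899-12-30 from spreadsheet epochs,
1970-01-01 from Unix time), day/month format confusion, self-reported
rounding to January 1st or to a decade year, age/year confusion, and faulty
systems that copy an event date (e.g. a dispensing date) into the birthdate
field. All of these mechanisms concentrate many records on a few calendar
dates, so they are visible as over-represented birthdates.

`birthcheck` detects such dates from the daily birthdate histogram alone.

## Count model

Let `N(d)` be the number of individuals in the register born on calendar day
`d`. Births into the at-risk population are modelled as a non-homogeneous
Poisson point process, so `N(d) ~ Poisson(lambda(d))` independently per day,
where the intensity `lambda(d)` is the expected count. The intensity is
assumed smooth in `d` — demographic forces (wars, depressions, baby booms,
disease-specific age profiles) act over years — except for a systematic
reduction on weekends and public holidays, which has grown over the decades
with hospital births, elective Caesarean sections and induction. The model
is

    log lambda(d) = beta0 + s1(d) + I(d is weekend/holiday) * s2(d)

with `s1` a smooth trend-plus-seasonality term, `s2` a smooth weekend
log-ratio, and `I` the special-day indicator. A negative-binomial variant is
deliberately not offered: per-day overdispersion cannot be assessed in this
setting and the Poisson form keeps the pointwise tail criterion simple.

## Fitting

* **Bases.** Both smooths are penalized regression splines on the day index
  normalized to [0, 1]. The default is cubic B-splines on evenly spaced
  knots with a second-order difference penalty (P-splines); a knot-based
  reduced-rank thin-plate basis (`|x - k|^3` radial terms with the side
  conditions absorbed, plus an unpenalized {1, x} null space) is available
  as `basis_kind="thin_plate_reduced"`. Both expose the same contract: a
  positive semi-definite penalty whose null space contains the linear
  function. Default ranks: `min(2 * years_covered, 200)` for `s1` (two
  basis functions per year track annual seasonality; the cap keeps
  century-long registers tractable) and 10 for `s2` (the weekend ratio
  drifts slowly).
* **Identifiability.** `s1` carries a sum-to-zero constraint over the
  fitting days, absorbed by an orthonormal null-space reparametrization;
  the intercept carries the level. `s2` is *not* centered: its columns
  vanish on ordinary days, so its constant is identified, and centering it
  would make a constant weekend effect unrepresentable.
* **P-IRLS.** The penalized Poisson log-likelihood is maximized by
  iteratively reweighted least squares under the canonical log link,
  initialized from the working response `log(N(d) + 0.5)`. Step halving
  keeps the penalized deviance monotone across accepted iterations.
  Convergence requires both a relative penalized-deviance change below
  1e-8 and the intercept score equation `sum(w * (N - lambda_hat)) = 0` to
  hold to a relative 1e-7 — the latter guarantees the mean-preservation
  identity `sum(lambda_hat) = sum(N)` that the detector relies on. A
  singular working system falls back to a small ridge with a warning;
  divergence raises an error carrying the deviance trace.
* **Smoothing selection.** GCV(rho) = n * D(rho) / (n - tr A(rho))^2, with
  `D` the Poisson deviance and `tr A` the effective degrees of freedom, is
  minimized over the two log10 smoothing parameters by a 5x5 coarse grid on
  [-8, 8] followed by two shrinking 3x3 refinements, each candidate a full
  warm-started P-IRLS fit. The winning fit is then re-polished to the tight
  score tolerance. The GCV profile is retained on the results object.
* **Observation weights** are 0/1 and drop days from the likelihood exactly
  as if deleted, while keeping the covariate grid; this is how flagged days
  are removed on refit.

## Outlier criterion

For each day the detector computes the upper tail probability
`P(K >= N(d) | lambda_hat(d))` through the regularized incomplete gamma
function (`gammainc(n, lambda)`), never by naive summation, and flags days
with tail probability below `c` (default 1e-4, the pointwise 99.99th
percentile; an optional Bonferroni mode divides by the number of days).
Zero counts are never flagged. Flagged days are ranked by ascending tail
probability; because extreme spikes underflow to exactly 0, ties are broken
by the log-space ratio `log N(d) - log lambda_hat(d)` (descending), then by
date. The threshold form `tail < c` is taken as normative; strict
quantile exceedance differs from it only by discreteness at the boundary
and is available through `poisson_quantile`.

Because the criterion is pointwise, sparse range ends behave correctly: at
`lambda = 0.05` a lone individual has `P(K >= 1) ~ 0.049`, far above any
reasonable `c`, so isolated old or young patients are not flagged — in
contrast to both baselines below.

**Masking.** A massive spike biases the fitted intensity upward and can
hide neighbors. `detect()` optionally iterates fit -> flag -> refit with
flagged days given weight zero (default one refit), re-flagging over all
days each time and recording the iteration at which each flag first
appeared; the final report uses the last iteration's intensity.

## Baselines

* **Seasonal ARIMA.** ARIMA(0,1,5)x(0,0,2) with weekly period 7, fitted by
  maximum likelihood (state space, simple differencing, concentrated
  scale). One-step residuals after a deterministic warm-up of
  `d + D*m + max(p + P*m, q + Q*m)` = 20 observations are thresholded at
  median + z(0.9999) * sd, one-sided, with a single global scale — no
  pointwise adaptation. The default scale is the plain residual standard
  deviation (the model's own normality assumption); a robust MAD-based
  scale is available via `robust_scale=True`, but note that on strongly
  heteroscedastic count series it collapses to the sparse-tail noise level
  and floods the detector with flags. The global threshold is the
  documented weakness: large spikes inflate the scale, and moderate fills
  at the sparse range ends fall below it.
* **MAD smoothing.** Sliding-window median of the 2h neighbors (the point
  itself excluded, so single-day spikes are not diluted), spread = median
  absolute deviation from that median, flag when the (one-sided, positive)
  deviation exceeds `z(1e-4) * spread`. When the windowed spread is zero,
  any value unequal to the windowed median is flagged — the degenerate
  policy that makes all-zero windows pathological: in (0,0,0,900,0,1,0)
  both the 900 and the harmless 1 are flagged.

## Synthetic registers

The generator produces the study conditions the detector is evaluated
under, with exact per-day ground truth:

* **Trend**: (decimal year, log-intensity) control points interpolated by a
  monotone shape-preserving cubic (PCHIP) — smooth and overshoot-free, as
  the model assumes of demographic forces. The packaged multi-decade
  scenario spans 1890-2012 (44,925 days) with sparse ends, an early-1930s
  dip and a 1946-1961 plateau, and is normalized so the intensity sums to
  40,000 expected individuals.
* **Seasonality**: annual log-scale sinusoid, amplitude 0.05.
* **Weekend ratio**: PCHIP through control points, drifting from +0.05
  before 1920 to -0.6 by 2010 in the packaged scenario (scenario choices,
  not estimates of any particular register).
* **Counts**: independent Poisson draws per day, seeded.
* **Contamination kinds**: `fill_date`, `newyear_rounding`, `decade_date`,
  `year_age_confusion` add a count (absolute, or a 5x/20x/100x multiple of
  the local intensity); `dispensing_block` spreads a total over a limited
  set of distinct days in a recent window via a seeded multinomial
  (dispensing dates are operational days hit repeatedly, so the
  contamination is spiky rather than a uniform lift — a sustained uniform
  lift at a sparse range end is statistically indistinguishable from
  demographic signal and no histogram-based method can see it);
  `identity_duplication` multiplies one day's count. Overlaps sum; labels
  record every altered day and its kinds; an overall contamination
  fraction (e.g. 1.5% of records) can be targeted by rescaling the
  additive magnitudes.

What the generator does **not** emulate: record-level attributes (names,
addresses, linkage), non-Poisson day-to-day dispersion, holiday calendars
(none by default — real registers should supply one), and contamination
that *removes* records. Passing tests therefore show that the method works
when its distributional assumptions hold and contamination is additive and
date-concentrated; they do not certify behavior under overdispersion or
under record deletion.

## Evaluation

The unit is the calendar date. Confusion counts, sensitivity, specificity,
PPV and FNR are derived with undefined ratios reported as undefined (never
0). AUC uses the rank (Mann-Whitney) statistic with midrank tie handling;
the GAM's anomaly score is `-log` tail probability (with a log-pmf bound
substituted where the tail underflows, preserving order among extreme
spikes), the SARIMA score is the standardized residual (warm-up days ranked
lowest).

## Problem sizes and study conditions

The packaged studies use: 20 clean 44,925-day registers for false-positive
control (expected false flags `c * n ~ 4.5`/run; the check allows 5x); 20
runs of a dense 60-year register (1.5M expected records, mid intensities
up to ~150/day, ends below 0.1/day) for detection power — six 20x mid-range
spikes and four 35-count fills at the sparse ends per run; 10 runs of a
20-year dense register (110,000 records) with a constant -0.5 weekend log
ratio for parameter recovery; and 10 contaminated multi-decade registers
for the GAM-vs-SARIMA AUC ordering. One P-spline fit of the multi-decade
register takes a few seconds on one CPU; the SARIMA baseline dominates the
runtime of the comparative studies.

## Known limitations

* GCV on very flexible bases can track short contamination clusters;
  the refit iteration mitigates but does not eliminate this.
* The Poisson assumption understates day-to-day variance in registers with
  correlated enrolment; flags near the threshold should be treated as a
  ranking, not a verdict.
* Weekend and holiday effects share one indicator and one smooth; a
  register with materially different weekend and holiday behavior would
  need a second indicator term.
* Dates are Gregorian and dialects are limited to ISO/US/UK; two-digit
  year forms are rejected rather than guessed.
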