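# Methods

## The question and the model

Overwintering ectotherms show low metabolic rates. Two mechanisms can
produce this: the passive physicochemical (Arrhenius) slowing of standard
metabolic rate (SMR) with temperature, compounded by inactivity, or an
additional *active* suppression of resting metabolism (metabolic rate
depression, MRD). The two are separated through the thermal sensitivity
quotient

    Q10 = (rate_cold / rate_warm) ** (10 / (T_cold - T_warm)),

computed on SMR — not on raw metabolic rate, which is confounded by
temperature-dependent activity. Passive Arrhenius effects give Q10 ≈ 2–3;
a mean SMR Q10 strictly above 3.5 over a cooling interval is taken to
indicate MRD. The 3.5 threshold is a conservative convention, and the
verdict text always reports the fraction of individuals above it, since
individuals commonly straddle the line.

SMR at each temperature is obtained by controlling for spontaneous
activity in three ways:

1. **Extrapolation.** Within one fish and temperature, paired
   measurements of activity (x) and oxygen uptake (y, mg O₂ kg⁻¹ h⁻¹)
   follow y = a·e^(bx); the intercept a is the oxygen uptake extrapolated
   to zero activity, i.e. SMR. Fitted by unweighted nonlinear least
   squares, initialised from the log-linear regression ln y ~ x, whose
   slope test (two-sided, b = 0) also supplies the significance of the
   activity effect. A pooled fit across fish gives the group SMR.
2. **Lowest-20 subsets.** Mean of the 20 smallest MO₂ values, or of the
   MO₂ values at the 20 lowest activity levels (ties in activity break by
   lower MO₂, then earlier interval). When fewer than 20 points exist,
   all are used and the count is recorded in the estimate's provenance.
3. **Activity-controlled MR.** Mean MO₂ within a narrow activity band
   (e.g. 0.8–1.8 BL min⁻¹) occupied at every compared temperature. The
   band is always caller-specified; `auto_band` suggests one but is never
   applied silently.

When the per-fish exponential fit does not converge or its activity
effect is not significant at α = 0.05 (typically because the activity
spread collapses in the cold), the extrapolated value is replaced by the
lowest-20 MO₂ estimate and the provenance records the fallback. A minimum
of 5 pairs and a positive activity spread are required for fitting at
all. Routine metabolic rate — the plain mean of all MO₂ at a temperature,
with no activity control — is computed for contrast; with activity
declining in the cold it systematically inflates Q10.

Arrhenius plots (ln SMR vs 1/T_K) corroborate the Q10 analysis. At most
one breakpoint is allowed: a continuous one-hinge piecewise line, its
break located by grid search over interior temperatures at 0.1 °C
resolution, is compared against a single line by small-sample-corrected
AIC (AICc), with the SSE floored at n·10⁻²⁰ so noiseless data cannot
drive the likelihood to −∞. Note that data with exactly constant Q10 are
linear in °C, not in 1/T_K, and therefore show slight genuine curvature
on Arrhenius axes; only constant-activation-energy data are exactly
collinear there.

## Respirometry reduction

Intermittent-closed respirometry alternates sealed measurement periods
with flushes. Within each closed period, the oxygen decline is fitted by
ordinary least squares with times rescaled to hours (slope in
mg O₂ L⁻¹ h⁻¹) after excluding the first 300 s as the post-flush
equilibration transient; excluding this window can only reduce the bias
from an exponential transient. Oxygen uptake is

    MO2 = (blank_slope − raw_slope) · V_eff / mass,

with V_eff the chamber volume minus the fish's volume (body density
1 kg L⁻¹ by default) and the blank slope taken from the temporally
nearest blank-chamber interval (ties to the earlier one). Negative
post-correction MO₂ is flagged, never clamped, so QC stays visible. A
configurable minimum r² (default 0.9; flat traces exempt) gates interval
acceptance — the slope-quality cutoff is this package's assumption, as is
the fixed cycle plan (timings are declared in config, not inferred from
the trace).

## Behaviour reduction and dormancy thresholds

Activity is the size-standardised average speed (BL min⁻¹): tracked
distance × calibration / total length / duration, computed within
half-open clock windows (day [09:00, 16:00), night [19:00, 06:00)
wrapping midnight; half-open avoids double counting at boundaries). A
per-fish "inactive control value" — mean apparent movement during
confirmed inactivity — is subtracted with a floor at zero, removing the
tracker noise floor. Sheltering is the invisible-time fraction (movement
inside the opaque shelter counts as zero distance but full time).
Vigilance is the mean of ordinal scores in {0, 0.5, 1}. Feeding is the
consumed fraction of the daily ration.

The dormancy threshold of a metric is the warmest temperature from which
the metric is statistically flat down to the coldest tested temperature.
Each non-coldest temperature is compared against the coldest by a
within-fish paired two-sided test (t by default, Wilcoxon selectable),
Bonferroni-adjusted across the m comparisons; the threshold is the
warmest member of the contiguous non-significant run walking up from the
second-coldest temperature. If even the second-coldest differs
significantly, the steady state comprises only the coldest temperature,
which is then reported. This paired-test engine deliberately replaces a
Gamma-family mixed-model analysis: the inferential target (per-temperature
contrast vs the coldest, each fish its own control) is the same, the
engine is dependency-light, and the comparison function is pluggable so a
mixed model can be swapped in. Bonferroni guarantees that under a global
null the probability of reporting any threshold colder than the warmest
temperature is ≤ α (verified by a 500-replicate simulation in the tests).

Mean inactive/fasting temperatures: per fish, the warmest temperature at
which the metric first reaches ≤ zero_tol *and stays there* at all colder
temperatures (the persistence requirement resolves fish that transiently
hit zero and resume). Fish that never transition count in the denominator
only; when fewer than half transition the population is flagged as not
transitioning. `zero_tol` (default 0) accommodates the tracker noise
floor left after inactive-control correction.

## The synthetic-data generator

The generator is first-class code: it emulates the statistical structure
the analysis assumes, with stored ground truth, so every downstream stage
is testable without animals or downloads.

Per fish i: SMR_ref,i is lognormal around the population SMR_ref
(default 100 mg O₂ kg⁻¹ h⁻¹ at the 14 °C reference) with CV 0.10, and the
coupling exponent b_i is lognormal around 0.2 with CV 0.10 — lognormal
keeps rates positive and variance proportional to the mean. True SMR
follows SMR_ref,i · Q10^((T−T_ref)/10) with Q10 = 2.5; when MRD is
enabled it is multiplied by (1 − suppression) below the threshold
temperature (defaults 0.40 below 8 °C). Interval-level activity is gamma
(shape 2) with mean = diel phase level × logistic((T − 7 °C) · 1 °C⁻¹);
the smooth two-parameter logistic stands in for the observed monotone
decline of activity to a cold steady state. Phase levels default to
1.5 (day) / 3.0 (night) BL min⁻¹ — a nocturnal, mummichog-like cycle.
Measured MO₂ is true SMR × e^(b_i·activity) × lognormal(0, σ = 0.08)
multiplicative noise. The design runs 12 fish through acute steps at 14,
11, 8, 5 and 2.5 °C with 20 intervals per diel phase (40 per condition),
then a cold-acclimated re-measurement at 2.5 °C and an acute rewarming to
14 °C. Acclimation applies no compensation by default (an exposed
multiplier, default 1), matching the finding that SMR is unchanged after
weeks of cold acclimation.

Behaviour trials reuse the same logistic damping at 1 °C steps from the
reference down to 2 °C. Daily activity is a phase-long average, so its
gamma shape is scaled by the number of intervals averaged, and an
additive Gaussian tracker-noise floor (sd 0.1 BL min⁻¹ where enabled,
motivated by real inactive-control magnitudes of ~0.5 BL min⁻¹) is added
before flooring at zero. Shelter fraction is 1 − the logistic scaler plus
small Gaussian jitter, clipped to [0, 1]; feeding is a binomial pellet
count on a 20-pellet ration with success probability equal to the
scaler; vigilance observations are Binomial(2, scaler)/2, giving scores
in {0, 0.5, 1} with mean equal to the scaler.

Oxygen traces decline linearly during closed periods at
MO₂·mass/V_eff + |background| (mg L⁻¹ h⁻¹) with Gaussian sensor noise,
and flushes restore saturation. No equilibration transient, chamber
mixing or chiller hysteresis is simulated, so trace round-trips isolate
the slope/blank arithmetic.

All draws flow from one seeded `numpy.random.Generator`; identical
configs give byte-identical tables.

### What the generator does and does not show

Passing tests show the estimators recover a *correctly specified* world:
exponential activity coupling, lognormal noise, logistic activity
damping, linear closed-period declines. Real data add unmodelled
structure — equilibration transients, activity misclassification, diel
drift in blanks, non-exponential activity costs at burst speeds — so test
recovery bounds are best-case statements about the algorithms, not about
field data. The gamma distribution of interval activity is an assumption,
not an inference from real data.

## Numerical choices and scaled problem sizes

- Exponential fits: `scipy.optimize.curve_fit`, unweighted, maxfev
  10 000; p-values from the log-linear form (a perfect fit reports p = 0).
- Paired tests: `scipy.stats.ttest_rel` / `wilcoxon`; degenerate
  all-equal differences short-circuit to p = 1 (identical) or p = 0
  (constant offset).
- Q10 endpoints use each fish's own measured endpoint temperatures where
  available, nominal ones otherwise; a mean Q10 of exactly 3.5 is
  classified passive (strict inequality).
- Cycle windows are half-open, capped at the next cycle start to guard
  floating-point jitter when the flush duration is ~0.
- Monte-Carlo test sizes (200 replicates for parameter recovery, 500 for
  null calibration, 20 seeds for threshold recovery, 20 replicates for
  the routine-vs-SMR contrast) were chosen to keep the whole suite around
  ten seconds while leaving comfortable margins on the assertions.
- Steady-state recovery tests configure a steep logistic (steepness
  8 °C⁻¹). With the smooth default (1 °C⁻¹) the decline never truly
  flattens, so the statistically flat region genuinely sits colder than
  the midpoint; a plateau-recovery test must configure an actual plateau.

## Known limitations

- The paired-test engine ignores trial-level random effects; with strong
  between-trial heterogeneity a mixed model (pluggable) is preferable.
- Extrapolated SMR inherits the exponential form; if the true
  activity–MO₂ relation is concave, a is biased low.
- The Arrhenius breakpoint search allows at most one break and enforces
  continuity; multi-break thermal responses are out of scope.
- Activity units (BL min⁻¹ vs % time moving) pass through untranslated;
  the exponential model is unit-agnostic but bands are not comparable
  across unit systems.
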