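# Methods

## Signal model and time convention

The analysis treats SpO2 as a continuous curve s(t) reconstructed from
1 Hz samples by piecewise-linear interpolation. Sample k holds the
instantaneous value at t = k seconds from recording start and owns the
half-open interval [k, k+1) for all counting purposes (sleep time,
artifact seconds, time-below-threshold). All integrals are therefore
exact trapezoids on linear segments, and counting quantities are integer
seconds; the two conventions meet in the corrected totals, which are
sample counts, while event areas and boundaries are sub-sample.

Standardization to 1 Hz: rates above 1 Hz are reduced by the arithmetic
mean of valid samples in each second — the mean rather than decimation
because the downstream metric is an integral and the mean preserves
area; rates below 1 Hz are upsampled sample-and-hold. Samples outside
(0, 100] are marked invalid (sensor dropout). This is a documented
package choice: vendor preprocessing of raw oximetry varies and is not
standardized here.

## Event detection

An event is a maximal interval where the interpolant is strictly below
the upper threshold T_u; boundaries are the linear-interpolated crossing
times. Strictness matters: a sample exactly at the threshold is not in
an event, and ties produce zero-length crossings that are ignored. An
excursion already in progress at sleep onset (or unresolved at offset)
is clipped to the window edge rather than dropped, so a night that
starts desaturated is not silently truncated. Invalid samples break the
interpolant: an excursion clipped against an invalid gap is flagged and
excluded (`contains_invalid`) rather than guessed across the gap.

A `sample_snapped` boundary mode (events cover the whole seconds of
their below-threshold samples) exists for sensitivity analysis. Note an
asymmetry users should expect: with interpolated boundaries, the
crossing time depends on the above-threshold neighbor sample, so
perturbing samples near an event edge shifts boundaries sub-sample even
though the set of below-threshold samples is unchanged; in snapped mode
detection is fully determined by that set.

## Areas, weights, normalization

Per event, AAC = ∫ max(T_u − s, 0) dt and AUC = ∫ min(s, T_u) dt with
baseline 0. Defining AUC as the complement T_u·Φ − AAC makes the
conservation identity exact by construction and matches the capped
integral on interpolated events, where s ≤ T_u throughout. The weight is
the event duration (weighted mode) or 1; weighted and unweighted results
carry different units (%·s² vs %·s) and are reported, never rescaled.

Ω = TST90c/TSTc. Sleep runs from the first run of ≥ 3 consecutive
N1/N2/N3 epochs to the end of the last N1/N2/N3/REM epoch; wake epochs
inside the window do not count toward TST (standard total-sleep-time
semantics — the sourcing cohort convention states only start/end, so
this is a documented choice). "Corrected" removes artifact-masked and
invalid seconds from **both** numerator and denominator; the symmetric
correction keeps Ω ≤ 1 and is flagged as a choice since the original
correction is not fully specified. The normalization threshold stays at
90% for every upper threshold by default, so indices across the
92/90/88/86 grid share one denominator; it is configurable for research
use. "Under 90%" is strict: a sample exactly at the threshold does not
count.

Comparators: TST90 = 100·TST90c/TSTc; Min Sat is taken over valid,
non-artifact sleep samples so an artifact dip cannot set the minimum;
AUT90 sums below-90% AAC over non-excluded events divided by recording
duration; HL100 is the mean deficit below 100% over corrected sleep
seconds (1-second rectangles, consistent with sample counting). AUT90
and HL100 are implemented from their one-line published descriptions and
are approximations of the cited originals; the recording-time vs
sleep-time denominators follow those descriptions.

## Synthetic recordings and the analytic oracle

Dips are piecewise-linear (square with 1-s edge ramps, triangle,
trapezoid) with vertices on integer seconds, so the 1 Hz sampled signal
interpolates back to exactly the designed polyline and every crossing,
area and total has a closed form. Ground truth is computed by
line-threshold geometry on the dip polylines and direct sample counting —
independently of the detection/metric code it validates. Noise is
truncated Gaussian clipped into (0, 100], added only after ground truth
is computed; dropouts mark samples invalid. A symmetric 20 s triangle
from 95% to 85% has AAC90 = 25.0 %·s (12.5 per ramp), a value verified
against dense numerical integration.

What the generator does **not** emulate: curved physiologic
resaturation profiles, baseline drift, periodic-breathing oscillations,
or motion artifact that stays above the lower threshold. Passing tests
therefore demonstrate correctness of the detection/integration
machinery on piecewise-linear signals, not robustness to every
real-world oximetry pathology.

## Cohort generator and survival harness

The cohort generator targets the statistical machinery, not
physiological realism: heavy-tailed lognormal severity (the index spans
orders of magnitude in real cohorts), exponential survival with hazard
baseline × exp(log-HR × (quintile − 1)) at default baseline hazard
0.02/year and log-HR 0.5 per quintile step, and covariates drawn
independently of survival (null effects) with prevalences loosely shaped
on a community sleep cohort. Censoring is an **independent** exponential
time whose rate is solved by bisection to hit the requested censored
fraction (default 0.3); an earlier dependent scheme (censoring at a
fraction of the subject's own event time) measurably broke Cox
confidence-interval calibration and was replaced — informative censoring
violates the partial-likelihood variance.

Quintiles are ascending-rank splits into five groups, sizes n/5 with the
remainder to the earlier groups, ties broken by stable input order, Q1
the reference. Model 0 regresses on quintile dummies alone; Model 1 adds
age, gender, race (White/Black/Other), BMI, COPD, smoking, alcohol and
sleep-duration categories plus eight cardiometabolic history flags,
dummy-encoded against the first listed level (the original covariate
coding is not published; these choices are the package's). Zero-variance
covariates are dropped so Model 1 degenerates exactly to Model 0 on a
covariate-free table. Fitting, confidence intervals and survival
prediction delegate to lifelines; Benjamini-Hochberg to statsmodels;
variance-inflation factors above 5 are logged.

## Numerical choices and degenerate inputs

- Event/threshold comparisons are strict (`<`); equality is "not below".
- Zero-duration (degenerate clipped) events contribute zero area and are
  excluded.
- A recording with no run of three consecutive N1/N2/N3 epochs raises
  `NoSleepOnset`; zero corrected sleep time raises `ZeroSleepTime` (the
  index is undefined, not zero).
- EDF fixtures are 16-bit with physical range 0–100%, so round trips are
  exact to one quantization step (100/65535 ≈ 0.0015%).
- Test problem sizes: randomized equivalence checks use 200 recordings
  of 120–500 s against a 1000×-oversampled re-derivation with
  crossing-refined boundaries; cohort recovery uses 20 seeds × 2000
  subjects. These sizes give comfortably stable verdicts for the
  tolerances tested (1e-9 conservation, 1e-6 oracle agreement).

## Known limitations

- Only absolute-threshold events: no relative-drop (ODI-style) 3%/4%
  detection, no AHI/SASHB/DS/4%POD (they need respiratory channels), no
  nonlinear weighting.
- Only the Compumedics Profusion XML dialect and a simple per-epoch CSV
  are parsed for staging; other annotation dialects are out of scope.
- The EDF writer exists to produce test fixtures; it is not a general
  EDF export tool.
- Whether excluded-artifact time should also shorten the event search
  window (rather than only the totals) is untestable against the source
  convention; the package removes artifact seconds from the totals only.
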