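# whi — Weighted Hypoxemia Index for nocturnal oximetry

Nocturnal hypoxemia — low blood-oxygen saturation (SpO2) during sleep —
drives outcomes in obstructive sleep apnea, COPD, heart failure and
pulmonary hypertension, yet the common summaries miss part of the
picture: TST90 (percent of sleep below 90%) ignores depth, minimum
saturation ignores duration, and the apnea-hypopnea index ignores the
oxygen signal almost entirely. The Weighted Hypoxemia Index (WHI) scores
a night by integrating **depth × duration** of every desaturation event,
with configurable thresholds so the same construction transfers across
clinical settings.

This package is for sleep and respiratory researchers who have 1 Hz
oximetry (PSG EDF exports, NSRR-style annotation XML, or plain CSV) and
want the index, its comparator metrics, and the cohort-level survival
machinery used to evaluate such metrics.

## The index

Working on "the curve" — the SpO2 signal standardized to 1 Hz — the index
is built in five steps:

1. **Events.** A desaturation/resaturation event *i* starts when the
   curve crosses from above to below the upper threshold *T_u*
   (default 90%, grid 92/90/88/86) and ends when it crosses back.
   Boundaries are linear-interpolated crossing times.
2. **Artifacts.** Any event dipping below the lower threshold (default
   50%, under the calibration floor of most pulse oximeters) is excluded
   as sensor artifact, as is any event touching invalid samples.
3. **Area and weight.** For each kept event, the area Δᵢ (%·s) is
   computed by the trapezoidal rule — exact on the piecewise-linear
   curve — as either the area **above** the curve below *T_u* (AAC) or
   the area **under** the curve capped at *T_u* (AUC); the weight Φᵢ is
   the event duration in seconds (or 1, unweighted).
4. **Normalization.** Ω = TST90c / TSTc, the corrected fraction of sleep
   spent under 90%: sleep runs from the first three consecutive N1/N2/N3
   epochs to the last N1/N2/N3/REM epoch, and artifact or invalid
   seconds are removed from both totals.
5. **Index.**  WHI = Ω × Σᵢ Δᵢ·Φᵢ  — units %·s² weighted, %·s unweighted.

Comparators computed on the same curve: TST90, minimum sleep saturation,
AUT90 and HL100 (time-normalized area metrics).

## Worked example

`examples/01_single_recording.py` builds a 90-second recording at
baseline 95% with one square dip to 85% over samples 10–19 and three N2
epochs, then prints:

```
--- area mode AAC ---
event: [9.5, 19.5] s, nadir 85%
delta = 47.50 %*s   phi = 10 s   omega = 10/90
WHI-AAC90 = 52.7778 %*s^2
--- area mode AUC ---
delta = 852.50 %*s   phi = 10 s   omega = 10/90
WHI-AUC90 = 947.2222 %*s^2
comparators: {'tst90_pct': 11.1111, 'min_sat_pct': 85.0, 'aut90': 0.5278, 'hl100': 6.1111}
```

Reading the numbers: the 95→85 edges cross the 90% threshold halfway
between samples, so the event spans [9.5, 19.5] and Φ = 10 s. The
area between threshold and curve is 1.25 + 45 + 1.25 = 47.5 %·s (AAC);
its complement under the threshold is 90×10 − 47.5 = 852.5 %·s (AUC).
Ten of ninety sleep seconds sit below 90%, so Ω = 1/9, giving
WHI-AAC90 = 47.5 × 10 × 1/9 ≈ 52.78 %·s².

The other examples cover the 16-variant threshold grid
(`02_threshold_grid.py`), the EDF + Profusion XML round trip
(`03_psg_formats.py`) and the quintile Cox harness with averaged
survival curves (`04_cohort_hazards.py`).

## Command line

```
whi compute --signal night.edf --staging night.xml --out result.json
whi batch --manifest subjects.csv --grid --out metrics.csv
whi simulate --spec spec.yaml --seed 42 --out-dir fixtures/ --edf
whi cohort --table cohort.csv --metric whi_auc90 --model model1 --out hr.csv
```

`compute` writes the full result JSON (index, Ω, per-event table,
comparators; both AUC and AAC variants are always included). Exit codes:
0 success, 1 input error, 2 degenerate recording (no sleep onset or zero
corrected sleep time).

## Scope notes

Event detection is absolute-threshold crossing; relative-drop (3%/4%
ODI-style) detection, AHI, SASHB, DS and 4%POD need respiratory/airflow
annotations and are out of scope, as are nonlinear weighting factors.
Cohort studies on real access-controlled datasets (e.g. the Sleep Heart
Health Study at sleepdata.org) are supported by the CSV cohort contract
but no downloader is included.
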