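"""The Weighted Hypoxemia Index and comparator oximetry metrics.

For each non-excluded desaturation event i the severity contribution is an
area Δi times a weight Φi. Δi is computed on the piecewise-linear curve
s(t) between the event's interpolated boundaries:

    AAC_i = ∫ max(T_u − s(t), 0) dt       (area above the curve, below T_u)
    AUC_i = ∫ min(s(t), T_u) dt           (area under the curve, capped)

so AAC_i + AUC_i = T_u × duration_i exactly. The trapezoidal rule is exact
on the linear segments. Φi is the event duration in seconds (weighted
mode) or 1 (unweighted). The subject-level index is

    WHI = Ω × Σ_i Δi × Φi,   Ω = TST90c / TSTc ∈ [0, 1],

with units %·s² when weighted and %·s when unweighted. Ω uses the same
90% normalization threshold for every upper threshold by default, so
indices at different thresholds share one denominator.

Comparators: TST90 (% of corrected sleep time below 90%), Min Sat
(minimum non-artifact sleep saturation), and time-normalized area metrics
AUT90 (summed AAC below 90% over recording duration) and HL100 (mean
saturation deficit below 100% over sleep) implemented from their standard
one-line definitions as approximations of the cited originals.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .desat_events import DesatEvent, detect_events, flag_artifact_events
from .errors import ExcludedEvent, LowerAboveUpper, ZeroSleepTime
from .oximetry_io import Hypnogram, OximetrySignal, standardize_to_1hz
from .sleep_period import (
    CorrectedTotals,
    SleepPeriod,
    corrected_totals,
    find_sleep_period,
)

AREA_MODES = ("AUC", "AAC")
THRESHOLD_GRID = (92.0, 90.0, 88.0, 86.0)


@dataclass
class WHIConfig:
    """Configuration of the index.

    Defaults are the headline configuration: upper threshold 90%, lower
    (artifact) threshold 50%, area under the curve, duration weighting, and
    sleep-time normalization Ω = TST90c/TSTc at the 90% threshold.
    """

    upper_threshold_pct: float = 90.0
    lower_threshold_pct: float = 50.0
    area_mode: str = "AUC"
    weighted: bool = True
    normalization: str = "tst90c_over_tstc"
    norm_threshold_pct: float = 90.0
    boundary_mode: str = "interpolated"
    window: str = "sleep_period"

    def __post_init__(self):
        if not self.lower_threshold_pct < self.upper_threshold_pct <= 100:
            raise LowerAboveUpper(
                f"need lower < upper <= 100, got lower="
                f"{self.lower_threshold_pct}, upper={self.upper_threshold_pct}"
            )
        if self.norm_threshold_pct > 100:
            raise ValueError("norm_threshold_pct must be <= 100")
        if self.area_mode not in AREA_MODES:
            raise ValueError(f"area_mode must be one of {AREA_MODES}")
        if self.normalization not in ("tst90c_over_tstc", "none"):
            raise ValueError("normalization must be 'tst90c_over_tstc' or 'none'")
        if self.boundary_mode not in ("interpolated", "sample_snapped"):
            raise ValueError("boundary_mode must be 'interpolated' or 'sample_snapped'")
        if self.window not in ("sleep_period", "full_recording"):
            raise ValueError("window must be 'sleep_period' or 'full_recording'")

    @property
    def units(self) -> str:
        return "%*s^2" if self.weighted else "%*s"


@dataclass
class WHIResult:
    """Index value with its decomposition and comparator metrics."""

    whi: float
    omega: float
    per_event: list  # (Δi in %*s, Φi in s) per non-excluded event
    events: list
    totals: CorrectedTotals
    comparators: dict
    config: WHIConfig

    def to_dict(self) -> dict:
        return {
            "whi": self.whi,
            "omega": self.omega,
            "units": self.config.units,
            "config": asdict(self.config),
            "totals": {"tstc_s": self.totals.tstc_s,
                       "tst90c_s": self.totals.tst90c_s},
            "events": [
                {
                    "index": ev.index,
                    "start_s": ev.start_s,
                    "end_s": ev.end_s,
                    "duration_s": ev.duration_s,
                    "nadir_pct": ev.nadir_pct,
                    "excluded": ev.excluded,
                    "reason": ev.reason,
                }
                for ev in self.events
            ],
            "comparators": self.comparators,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _interp(signal: OximetrySignal, t: float) -> float:
    """Value of the piecewise-linear curve at absolute time t (held flat
    past the last sample for window-edge-clipped events)."""
    x = t - signal.t0_s
    k = int(np.floor(x))
    k = max(min(k, len(signal) - 1), 0)
    frac = x - k
    if frac == 0 or k + 1 >= len(signal):
        return float(signal.values[k])
    return float((1 - frac) * signal.values[k] + frac * signal.values[k + 1])


def event_area(
    signal: OximetrySignal,
    event: DesatEvent,
    upper_threshold_pct: float,
    area_mode: str = "AAC",
) -> float:
    """Δi for one event, in %·s, exact on the piecewise-linear segments.

    AAC integrates the deficit below the threshold; AUC integrates the
    curve itself capped at the threshold (baseline 0), so the two are
    exact complements: AAC + AUC = threshold × duration.
    """
    if event.excluded:
        raise ExcludedEvent(f"event {event.index} is excluded ({event.reason})")
    if area_mode not in AREA_MODES:
        raise ValueError(f"area_mode must be one of {AREA_MODES}")
    a, b = event.start_s, event.end_s
    if b <= a:
        return 0.0
    thr = float(upper_threshold_pct)

    # breakpoints: boundaries plus every sample time strictly inside
    first = int(np.floor(a)) + 1
    last = int(np.ceil(b)) - 1
    ts = [a] + [float(k) for k in range(first, last + 1) if a < k < b] + [b]
    vs = [_interp(signal, t) for t in ts]

    aac = 0.0
    for (t1, v1), (t2, v2) in zip(zip(ts, vs), zip(ts[1:], vs[1:])):
        d1, d2 = thr - v1, thr - v2
        if d1 >= 0 and d2 >= 0:
            aac += 0.5 * (d1 + d2) * (t2 - t1)
        elif d1 <= 0 and d2 <= 0:
            continue
        else:  # segment crosses the threshold (sample-snapped boundaries)
            tx = t1 + d1 / (d1 - d2) * (t2 - t1)
            if d1 > 0:
                aac += 0.5 * d1 * (tx - t1)
            else:
                aac += 0.5 * d2 * (t2 - tx)
    if area_mode == "AAC":
        return aac
    return thr * (b - a) - aac


def event_weight(event: DesatEvent, weighted: bool = True) -> float:
    """Φi: the event duration in seconds, or 1 in unweighted mode."""
    if event.excluded:
        raise ExcludedEvent(f"event {event.index} is excluded ({event.reason})")
    return float(event.duration_s) if weighted else 1.0


def normalization_factor(totals: CorrectedTotals) -> float:
    """Ω = TST90c / TSTc; undefined (ZeroSleepTime) when TSTc is zero."""
    if totals.tstc_s == 0:
        raise ZeroSleepTime("corrected total sleep time is zero")
    return totals.tst90c_s / totals.tstc_s


def _full_recording_period(signal: OximetrySignal) -> SleepPeriod:
    n = len(signal)
    offset = int(np.ceil(n / 30)) * 30
    period = object.__new__(SleepPeriod)  # window need not align to epochs
    period.onset_s = 0
    period.offset_s = max(offset, 30)
    period.sleep_mask = np.ones(n, dtype=bool)
    return period


def compute_whi(
    signal: OximetrySignal,
    hypnogram: Hypnogram | None,
    config: WHIConfig | None = None,
) -> WHIResult:
    """Run the full pipeline on one recording.

    Standardizes the signal to 1 Hz, derives the sleep window, detects and
    artifact-filters events, accumulates Ω × Σ Δi·Φi and attaches the
    comparator metrics. Raises NoSleepOnset for unusable hypnograms and
    ZeroSleepTime when the corrected denominator vanishes.
    """
    config = config or WHIConfig()
    signal = standardize_to_1hz(signal)

    if config.window == "sleep_period":
        if hypnogram is None:
            raise ValueError("sleep_period window requires a hypnogram")
        period = find_sleep_period(hypnogram)
    else:
        period = _full_recording_period(signal)

    events = detect_events(
        signal, (period.onset_s, period.offset_s),
        config.upper_threshold_pct, config.boundary_mode,
    )
    events, artifact_mask = flag_artifact_events(
        events, signal, config.lower_threshold_pct
    )
    totals = corrected_totals(period, signal, artifact_mask,
                              config.norm_threshold_pct)
    if config.normalization == "tst90c_over_tstc":
        omega = normalization_factor(totals)
    else:
        omega = 1.0

    per_event = []
    acc = 0.0
    for ev in events:
        if ev.excluded:
            continue
        delta = event_area(signal, ev, config.upper_threshold_pct,
                           config.area_mode)
        phi = event_weight(ev, config.weighted)
        per_event.append((delta, phi))
        acc += delta * phi

    comparators = comparator_metrics(
        signal, period, artifact_mask,
        lower_threshold_pct=config.lower_threshold_pct,
        boundary_mode=config.boundary_mode,
    )
    return WHIResult(
        whi=omega * acc,
        omega=omega,
        per_event=per_event,
        events=events,
        totals=totals,
        comparators=comparators,
        config=config,
    )


def comparator_metrics(
    signal: OximetrySignal,
    period: SleepPeriod,
    artifact_mask: np.ndarray,
    lower_threshold_pct: float = 50.0,
    boundary_mode: str = "interpolated",
) -> dict:
    """Standard oximetry summaries on the same standardized curve.

    tst90_pct: percent of corrected sleep time strictly below 90%.
    min_sat_pct: minimum valid, non-artifact sleep saturation.
    aut90: summed below-90% AAC of non-excluded events per second of
        recording (%·s/s).
    hl100: mean saturation deficit below 100% over corrected sleep (%·s/s).
    """
    artifact_mask = np.asarray(artifact_mask, dtype=bool)
    totals = corrected_totals(period, signal, artifact_mask, 90.0)
    if totals.tstc_s == 0:
        raise ZeroSleepTime("corrected total sleep time is zero")

    n = len(signal)
    sleep = np.zeros(n, dtype=bool)
    m = min(n, len(period.sleep_mask))
    sleep[:m] = period.sleep_mask[:m]
    counted = sleep & ~artifact_mask & signal.valid

    min_sat = float(signal.values[counted].min())

    ev90 = detect_events(signal, (period.onset_s, period.offset_s), 90.0,
                         boundary_mode)
    ev90, _ = flag_artifact_events(ev90, signal, lower_threshold_pct)
    aac_sum = sum(
        event_area(signal, ev, 90.0, "AAC") for ev in ev90 if not ev.excluded
    )

    hl_total = float((100.0 - signal.values[counted]).sum())  # 1-s rectangles

    return {
        "tst90_pct": 100.0 * totals.tst90c_s / totals.tstc_s,
        "min_sat_pct": min_sat,
        "aut90": aac_sum / signal.duration_s,
        "hl100": hl_total / totals.tstc_s,
    }


def metric_name(upper_threshold_pct: float, area_mode: str, weighted: bool) -> str:
    """Canonical column name, e.g. ``whi_auc90`` or ``auc90_unweighted``."""
    base = f"{area_mode.lower()}{int(round(upper_threshold_pct))}"
    return f"whi_{base}" if weighted else f"{base}_unweighted"


def compute_whi_grid(
    signal: OximetrySignal,
    hypnogram: Hypnogram | None,
    base_config: WHIConfig | None = None,
    thresholds=THRESHOLD_GRID,
) -> dict:
    """All 16 variants (4 thresholds × {AUC, AAC} × weighted/unweighted).

    Every variant shares the lower threshold, normalization and window of
    ``base_config``; returns {metric_name: index value}.
    """
    base = base_config or WHIConfig()
    out = {}
    for thr in thresholds:
        for mode in AREA_MODES:
            for weighted in (True, False):
                cfg = WHIConfig(
                    upper_threshold_pct=thr,
                    lower_threshold_pct=base.lower_threshold_pct,
                    area_mode=mode,
                    weighted=weighted,
                    normalization=base.normalization,
                    norm_threshold_pct=base.norm_threshold_pct,
                    boundary_mode=base.boundary_mode,
                    window=base.window,
                )
                res = compute_whi(signal, hypnogram, cfg)
                out[metric_name(thr, mode, weighted)] = res.whi
    return out
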