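"""Desaturation/resaturation event detection and artifact exclusion.

An event starts when the SpO2 curve crosses from above to below the upper
threshold and ends when it crosses back above it. The curve is the
piecewise-linear interpolant of the valid 1 Hz samples, so event
boundaries are sub-sample, linearly interpolated crossing times (a
sample-snapped mode is available for sensitivity analysis). Events whose
nadir drops below the lower threshold — 50% by default, since pulse
oximeters are typically calibrated down to about 70% — are excluded as
sensor artifact, as are events touching invalid samples; their seconds
form the artifact mask that the corrected sleep-time totals remove.

Semantics are strictly-below: a sample exactly at the threshold is not in
an event, and ties produce zero-length crossings that are ignored.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import LowerAboveUpper
from .oximetry_io import OximetrySignal
from .sleep_period import SleepPeriod

REASONS = ("none", "below_lower_threshold", "contains_invalid", "clipped_degenerate")


@dataclass
class DesatEvent:
    """One desaturation event i.

    ``start_s``/``end_s`` are fractional crossing times; ``duration_s`` is
    the candidate weighting factor. ``touches_invalid`` records that a
    boundary was clipped against an invalid-sample gap rather than a true
    threshold crossing.
    """

    index: int
    start_s: float
    end_s: float
    duration_s: float
    nadir_pct: float
    threshold_pct: float
    excluded: bool = False
    reason: str = "none"
    touches_invalid: bool = False

    def __post_init__(self):
        if self.reason not in REASONS:
            raise ValueError(f"unknown exclusion reason {self.reason!r}")


def _crossing(t: float, a: float, b: float, thr: float) -> float:
    """Time in [t, t+1] where the segment from (t, a) to (t+1, b) meets thr."""
    return t + (a - thr) / (a - b)


def detect_events(
    signal: OximetrySignal,
    window: SleepPeriod | tuple,
    upper_threshold_pct: float,
    boundary_mode: str = "interpolated",
) -> list[DesatEvent]:
    """Detect maximal strictly-below-threshold intervals in the window.

    The interpolant of valid samples is scanned over [onset, offset); an
    excursion already in progress at onset (or unresolved at offset) is
    clipped to the window edge. Invalid samples break the interpolant:
    excursions are clipped at the edge of each valid run and flagged
    ``touches_invalid`` (exclusion is applied by
    :func:`flag_artifact_events`). Returns an empty list when the curve
    never drops below the threshold.
    """
    if signal.sample_rate_hz != 1:
        raise ValueError("detect_events requires a 1 Hz signal")
    if boundary_mode not in ("interpolated", "sample_snapped"):
        raise ValueError(f"unknown boundary_mode {boundary_mode!r}")

    if isinstance(window, tuple):
        onset, offset = window
    else:
        onset, offset = window.onset_s, window.offset_s
    t0 = int(round(signal.t0_s))
    # window in sample-index space; sample k owns [k, k+1)
    lo = max(int(np.ceil(onset)) - t0, 0)
    hi = min(int(np.ceil(offset)) - t0, len(signal))
    if hi <= lo:
        return []
    # window edges clamped to the sampled span (sample hi-1 owns [hi-1, hi))
    onset = max(float(onset), float(lo + t0))
    offset = min(float(offset), float(hi + t0))

    v = signal.values
    ok = signal.valid
    thr = float(upper_threshold_pct)
    events: list[DesatEvent] = []

    # maximal runs of consecutive valid samples inside the window
    idx = np.arange(lo, hi)[ok[lo:hi]]
    if idx.size == 0:
        return []
    breaks = np.where(np.diff(idx) > 1)[0]
    run_bounds = zip(np.r_[0, breaks + 1], np.r_[breaks, idx.size - 1])

    for a_i, b_i in run_bounds:
        i0, i1 = int(idx[a_i]), int(idx[b_i])
        run_left_clipped = i0 > lo    # run starts after window start: invalid gap
        run_right_clipped = i1 < hi - 1

        start = None
        start_invalid = False
        for k in range(i0, i1 + 1):
            t = float(k + t0)
            a = v[k]
            if start is None and a < thr:
                if k == i0:
                    # excursion in progress at the run edge
                    start = float(onset) if not run_left_clipped else t
                    start_invalid = run_left_clipped
                # else: crossing was emitted while scanning the previous pair
            if k == i1:
                if start is not None:
                    end = float(offset) if not run_right_clipped else t
                    _emit(events, start, end, thr, v, ok, t0,
                          start_invalid or run_right_clipped)
                break
            b = v[k + 1]
            if start is None:
                if a >= thr and b < thr:
                    start = _crossing(t, a, b, thr)
                    start_invalid = False
            else:
                if b >= thr:
                    end = _crossing(t, a, b, thr) if b > thr else t + 1.0
                    _emit(events, start, end, thr, v, ok, t0, start_invalid)
                    start = None
                    start_invalid = False

    for i, ev in enumerate(events):
        ev.index = i
    if boundary_mode == "sample_snapped":
        events = [_snap(ev, t0, lo, hi) for ev in events]
        events = [ev for ev in events if ev is not None]
        for i, ev in enumerate(events):
            ev.index = i
    return events


def _emit(events, start, end, thr, v, ok, t0, touches_invalid):
    if end <= start:
        return  # zero-length tie at the threshold; ignored
    k0 = max(int(np.ceil(start)) - t0, 0)
    k1 = min(int(np.floor(end)) - t0, len(v) - 1)
    sel = np.arange(k0, k1 + 1)
    sel = sel[ok[sel]] if sel.size else sel
    nadir = float(v[sel].min()) if sel.size else float("nan")
    events.append(
        DesatEvent(
            index=len(events),
            start_s=float(start),
            end_s=float(end),
            duration_s=float(end - start),
            nadir_pct=nadir,
            threshold_pct=thr,
            touches_invalid=bool(touches_invalid),
        )
    )


def _snap(ev: DesatEvent, t0: int, lo: int, hi: int) -> DesatEvent | None:
    """Snap boundaries to the sample grid: the event covers the whole
    seconds owned by its below-threshold samples."""
    k0 = int(np.ceil(ev.start_s))
    k1 = int(np.ceil(ev.end_s))
    k0 = max(k0, lo + t0)
    k1 = min(k1, hi + t0)
    if k1 <= k0:
        return None
    return replace(ev, start_s=float(k0), end_s=float(k1),
                   duration_s=float(k1 - k0))


def flag_artifact_events(
    events: list[DesatEvent],
    signal: OximetrySignal,
    lower_threshold_pct: float,
) -> tuple[list[DesatEvent], np.ndarray]:
    """Apply the lower-threshold artifact rule and build the artifact mask.

    An event whose nadir is strictly below ``lower_threshold_pct``, or that
    touches any invalid sample, is marked excluded. The returned per-second
    mask is true for every second [k, k+1) whose sample lies inside an
    excluded event, plus every invalid-sample second; these seconds are
    removed from the corrected sleep-time totals.
    """
    if events and lower_threshold_pct >= events[0].threshold_pct:
        raise LowerAboveUpper(
            f"lower threshold {lower_threshold_pct} must be below the "
            f"upper threshold {events[0].threshold_pct}"
        )
    t0 = int(round(signal.t0_s))
    mask = ~signal.valid.copy()
    flagged = []
    for ev in events:
        excluded, reason = False, "none"
        if ev.touches_invalid:
            excluded, reason = True, "contains_invalid"
        elif ev.nadir_pct < lower_threshold_pct:
            excluded, reason = True, "below_lower_threshold"
        elif ev.duration_s <= 0:
            excluded, reason = True, "clipped_degenerate"
        if excluded:
            k0 = max(int(np.ceil(ev.start_s)) - t0, 0)
            k1 = min(int(np.floor(ev.end_s)) - t0, len(signal) - 1)
            mask[k0:k1 + 1] = True
        flagged.append(replace(ev, excluded=excluded, reason=reason))
    return flagged, mask


def events_to_frame(events: list[DesatEvent]) -> pd.DataFrame:
    """Tabulate events for CSV export."""
    return pd.DataFrame(
        [
            {
                "index": ev.index,
                "start_s": ev.start_s,
                "end_s": ev.end_s,
                "duration_s": ev.duration_s,
                "nadir_pct": ev.nadir_pct,
                "excluded": ev.excluded,
                "reason": ev.reason,
            }
            for ev in events
        ],
        columns=["index", "start_s", "end_s", "duration_s", "nadir_pct",
                 "excluded", "reason"],
    )
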