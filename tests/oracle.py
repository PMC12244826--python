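"""Independent dense-resampling oracle for the index pipeline.

Re-derives events, areas and totals from first principles: the 1 Hz
samples are oversampled 1000x on a regular grid, events are maximal
strictly-below runs of the oversampled curve with boundaries refined by
solving the local linear segment, areas are trapezoidal sums over the
dense grid clipped exactly at the refined boundaries, and the corrected
totals are direct sample counts. No code from the package's detection or
metric modules is used.
"""
from __future__ import annotations

import numpy as np

DT = 1e-3  # 1000x oversampling of the 1 Hz grid


def dense_pipeline(values, onset, offset, upper_thr, lower_thr=50.0,
                   norm_thr=90.0, sleep_mask=None):
    """Full re-derivation of events, areas, totals and the index.

    ``values`` is a fully valid 1 Hz series; the window [onset, offset) is
    clipped to the sampled span with the last sample held flat to the
    window edge, mirroring the documented clipping convention.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    onset = max(float(onset), 0.0)
    offset = min(float(offset), float(n))
    ts = np.arange(n, dtype=float)

    grid = onset + np.arange(int(round((offset - onset) / DT)) + 1) * DT
    grid = grid[grid <= offset + 1e-12]
    y = np.interp(grid, ts, values)  # flat hold beyond the last sample

    below = y < upper_thr
    events = []
    i = 0
    while i < len(grid):
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(grid) and below[j + 1]:
            j += 1
        if i == 0:
            start = onset
        else:
            y0, y1 = y[i - 1], y[i]
            start = grid[i - 1] + (y0 - upper_thr) / (y0 - y1) * DT
        if j == len(grid) - 1:
            end = offset
        else:
            y0, y1 = y[j], y[j + 1]
            end = grid[j] + (y0 - upper_thr) / (y0 - y1) * DT
        if end > start:
            inner = grid[(grid > start) & (grid < end)]
            pts = np.concatenate(([start], inner, [end]))
            vals = np.interp(pts, ts, values)
            aac = np.trapezoid(upper_thr - vals, pts)
            k0, k1 = int(np.ceil(start)), int(np.floor(end))
            nadir = values[k0:min(k1, n - 1) + 1].min()
            events.append({
                "start": start, "end": end, "duration": end - start,
                "nadir": nadir, "aac": aac,
                "auc": upper_thr * (end - start) - aac,
                "excluded": bool(nadir < lower_thr),
            })
        i = j + 1

    artifact = np.zeros(n, dtype=bool)
    for ev in events:
        if ev["excluded"]:
            k0 = max(int(np.ceil(ev["start"])), 0)
            k1 = min(int(np.floor(ev["end"])), n - 1)
            artifact[k0:k1 + 1] = True

    if sleep_mask is None:
        sleep = (ts >= onset) & (ts < offset)
    else:
        sleep = np.zeros(n, dtype=bool)
        m = min(n, len(sleep_mask))
        sleep[:m] = np.asarray(sleep_mask[:m], dtype=bool)
    counted = sleep & ~artifact
    tstc = int(counted.sum())
    tst90c = int((counted & (values < norm_thr)).sum())
    omega = tst90c / tstc if tstc else float("nan")

    out = {"events": events, "tstc": tstc, "tst90c": tst90c, "omega": omega}
    for mode in ("aac", "auc"):
        for weighted in (True, False):
            acc = sum(
                ev[mode] * (ev["duration"] if weighted else 1.0)
                for ev in events if not ev["excluded"]
            )
            key = f"whi_{mode}" + ("" if weighted else "_unweighted")
            out[key] = omega * acc
    return out


def random_recording(rng, min_len=120, max_len=500):
    """A random piecewise-linear 1 Hz SpO2-like series (all valid)."""
    n = int(rng.integers(min_len, max_len + 1))
    values = np.empty(n)
    x = 0.0  # AR(1) deviation below a 96% baseline
    for k in range(n):
        x = 0.9 * x + rng.normal(0, 2.5)
        if rng.uniform() < 0.01:  # occasional artifact-depth plunge
            x -= rng.uniform(20, 45)
        values[k] = 96 + x
    return np.clip(values, 35.0, 100.0)
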