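"""Score one night of oximetry: events, areas, weights, normalization.

Builds a small synthetic recording with a single desaturation to 85% and
walks through the index decomposition: the event's interpolated
boundaries, its area below the 90% threshold (AAC and AUC variants), its
duration weight, and the sleep-time normalization factor.
"""
from whi import Dip, SyntheticSpec, WHIConfig, compute_whi, generate_recording

spec = SyntheticSpec(
    duration_s=90,
    baseline_pct=95.0,
    dips=[Dip(onset_s=10, duration_s=10, nadir_pct=85.0)],
    hypnogram_pattern=[("N2", 3)],
)
signal, hypnogram, truth = generate_recording(spec)

for mode in ("AAC", "AUC"):
    res = compute_whi(signal, hypnogram, WHIConfig(area_mode=mode))
    ev = res.events[0]
    delta, phi = res.per_event[0]
    print(f"--- area mode {mode} ---")
    print(f"event: [{ev.start_s:.1f}, {ev.end_s:.1f}] s, "
          f"nadir {ev.nadir_pct:.0f}%")
    print(f"delta = {delta:.2f} %*s   phi = {phi:.0f} s   "
          f"omega = {res.totals.tst90c_s}/{res.totals.tstc_s}")
    print(f"WHI-{mode}90 = {res.whi:.4f} %*s^2 "
          f"(analytic ground truth available for synthetic input)")

# The comparators summarize the same curve with the classic one-number
# metrics: percent of sleep below 90%, the minimum saturation, and two
# time-normalized area measures.
print("comparators:", {k: round(v, 4) for k, v in res.comparators.items()})
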