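"""The full configuration grid on one synthetic night.

Computes all 16 index variants — upper thresholds 92/90/88/86, area under
vs above the curve, duration-weighted vs unweighted — on an 8-hour
recording with recurring desaturations. Weighted values carry units %*s^2,
unweighted %*s; all share the TST90c/TSTc normalization.
"""
from whi import Dip, SyntheticSpec, compute_whi_grid, generate_recording

dips = [Dip(onset_s=1200 + 90 * i, duration_s=30, nadir_pct=84.0,
            shape="trapezoid", ramp_s=8) for i in range(40)]
spec = SyntheticSpec(duration_s=28800, dips=dips,
                     hypnogram_pattern=[("W", 20), ("N1", 10), ("N2", 400),
                                        ("N3", 200), ("REM", 300), ("W", 30)])
signal, hypnogram, _ = generate_recording(spec)

grid = compute_whi_grid(signal, hypnogram)
print(f"{'metric':<22}{'value':>14}")
for name, value in sorted(grid.items()):
    print(f"{name:<22}{value:>14.2f}")
print("\nHigher upper thresholds capture more (shallower) desaturation,")
print("so values grow with the threshold; weighting multiplies each event")
print("by its duration, inflating long events quadratically.")
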