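"""Analysis window and corrected sleep-time denominators.

Sleep onset is the start of the first run of at least three consecutive
epochs staged N1, N2 or N3; sleep offset is the end of the last epoch
staged N1, N2, N3 or REM. The normalization factor of the index is built
from two corrected totals counted at 1-second resolution inside that
window: TSTc, the corrected total sleep time, and TST90c, the corrected
sleep time spent strictly below the normalization threshold (90% by
default). "Corrected" means artifact-masked and invalid seconds are
removed from both counts, which keeps their ratio in [0, 1].
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LengthMismatch, NoSleepOnset
from .oximetry_io import Hypnogram, OximetrySignal

SLEEP_ONSET_STAGES = frozenset({"N1", "N2", "N3"})
SLEEP_STAGES = frozenset({"N1", "N2", "N3", "REM"})


@dataclass
class SleepPeriod:
    """The analysis window [onset_s, offset_s) with a per-second sleep mask.

    The mask is true exactly for the seconds of sleep-staged epochs inside
    the window; wake epochs inside the window stay false (standard TST
    semantics).
    """

    onset_s: int
    offset_s: int
    sleep_mask: np.ndarray

    def __post_init__(self):
        if not self.onset_s < self.offset_s:
            raise ValueError("onset must precede offset")
        if self.onset_s % 30 or self.offset_s % 30:
            raise ValueError("onset/offset must lie on the 30-s epoch grid")
        self.sleep_mask = np.asarray(self.sleep_mask, dtype=bool)


@dataclass
class CorrectedTotals:
    """Corrected sleep-time totals in seconds: 0 <= tst90c_s <= tstc_s."""

    tstc_s: int
    tst90c_s: int

    def __post_init__(self):
        if not 0 <= self.tst90c_s <= self.tstc_s:
            raise ValueError("totals must satisfy 0 <= tst90c_s <= tstc_s")


def find_sleep_period(hypnogram: Hypnogram) -> SleepPeriod:
    """Locate the sleep window in a hypnogram.

    Onset is where the first run of >= 3 consecutive N1/N2/N3 epochs begins;
    offset is the end of the last N1/N2/N3/REM epoch. Raises
    :class:`NoSleepOnset` when no qualifying run exists (unusable recording).
    """
    stages = hypnogram.stages
    el = hypnogram.epoch_len_s

    onset_epoch = None
    run = 0
    for i, s in enumerate(stages):
        run = run + 1 if s in SLEEP_ONSET_STAGES else 0
        if run == 3:
            onset_epoch = i - 2
            break
    if onset_epoch is None:
        raise NoSleepOnset("no run of three consecutive N1/N2/N3 epochs")

    last_sleep = max(i for i, s in enumerate(stages) if s in SLEEP_STAGES)
    onset_s = onset_epoch * el
    offset_s = (last_sleep + 1) * el

    mask = np.zeros(hypnogram.duration_s, dtype=bool)
    for i, s in enumerate(stages):
        if onset_epoch <= i <= last_sleep and s in SLEEP_STAGES:
            mask[i * el:(i + 1) * el] = True
    return SleepPeriod(onset_s=onset_s, offset_s=offset_s, sleep_mask=mask)


def corrected_totals(
    period: SleepPeriod,
    signal: OximetrySignal,
    artifact_mask: np.ndarray,
    norm_threshold_pct: float = 90.0,
) -> CorrectedTotals:
    """Count TSTc and TST90c over a 1 Hz signal.

    tstc_s counts seconds that are asleep, artifact-free and valid; tst90c_s
    is the subset of those with saturation strictly below
    ``norm_threshold_pct`` (a sample exactly at the threshold does not
    count).
    """
    if signal.sample_rate_hz != 1:
        raise ValueError("corrected_totals requires a 1 Hz signal")
    artifact_mask = np.asarray(artifact_mask, dtype=bool)
    n = len(signal)
    if len(artifact_mask) != n:
        raise LengthMismatch(
            f"signal ({n} s) and artifact mask ({len(artifact_mask)} s) "
            f"must align at 1 Hz"
        )
    # the epoch grid may overhang a signal that is not a multiple of 30 s
    sleep = np.zeros(n, dtype=bool)
    m = min(n, len(period.sleep_mask))
    sleep[:m] = period.sleep_mask[:m]

    counted = sleep & ~artifact_mask & signal.valid
    below = counted & (signal.values < norm_threshold_pct)
    return CorrectedTotals(tstc_s=int(counted.sum()), tst90c_s=int(below.sum()))
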