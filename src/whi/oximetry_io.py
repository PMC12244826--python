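"""Reading and standardizing oximetry and sleep-staging data.

The analysis operates on "the curve": an SpO2 series standardized to 1 Hz
with a per-sample validity mask. Sources are the oximetry channel of a PSG
in EDF/EDF+, a generic two-column CSV (time_s, spo2_pct), and sleep staging
in NSRR Compumedics Profusion XML or a one-column per-epoch CSV.

Time convention: continuous seconds from recording start. After
standardization, sample k holds the value at t = k and owns the half-open
interval [k, k+1) for all counting purposes.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .errors import (
    ChannelNotFound,
    EmptySignal,
    FileUnreadable,
    MalformedAnnotation,
    NonUniformSampling,
)

logger = logging.getLogger(__name__)

#: Sleep-stage vocabulary. UNSCORED marks epochs with unknown annotation codes.
STAGES = ("W", "N1", "N2", "N3", "REM", "UNSCORED")

#: Compumedics Profusion integer stage codes; any other code (including the
#: legacy R&K stage 4) maps to UNSCORED with a warning.
PROFUSION_CODES = {0: "W", 1: "N1", 2: "N2", 3: "N3", 5: "REM"}

#: EDF channel labels tried, in order, when no hint is given.
DEFAULT_SPO2_LABELS = ("SaO2", "SpO2", "OSAT")


@dataclass
class OximetrySignal:
    """An SpO2 series with a validity mask.

    Parameters
    ----------
    values : ndarray of float
        Saturation per sample in percent.
    sample_rate_hz : float
        Nominal sampling rate; exactly 1 after :func:`standardize_to_1hz`.
    valid : ndarray of bool
        Per-sample validity; ``False`` marks missing or non-physiologic
        samples (outside the interval (0, 100]).
    t0_s : float
        Offset of the first sample from recording start, in seconds.
    """

    values: np.ndarray
    sample_rate_hz: float
    valid: np.ndarray = None
    t0_s: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must have equal length")

    def __len__(self):
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.sample_rate_hz

    def times(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return self.t0_s + np.arange(len(self.values)) / self.sample_rate_hz


@dataclass
class Hypnogram:
    """Per-epoch sleep stages on the fixed 30-s epoch grid."""

    stages: list
    epoch_len_s: int = 30

    def __post_init__(self):
        self.stages = list(self.stages)
        if not self.stages:
            raise MalformedAnnotation("hypnogram has no epochs")
        if self.epoch_len_s != 30:
            raise ValueError("epoch_len_s must be 30")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")

    def __len__(self):
        return len(self.stages)

    @property
    def duration_s(self) -> int:
        return len(self.stages) * self.epoch_len_s


def read_edf_spo2(path, channel_hint: str | None = None) -> OximetrySignal:
    """Read the oximetry channel of an EDF/EDF+ file at its native rate.

    The channel whose label case-insensitively matches ``channel_hint`` is
    returned (without resampling, validity all true). With no hint, the
    labels ``SaO2``, ``SpO2`` and ``OSAT`` are tried in order.

    Raises
    ------
    FileUnreadable
        If the file is missing or not parseable as EDF.
    ChannelNotFound
        If no label matches; the error lists the available labels.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileUnreadable(f"no such file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    except Exception as exc:  # mne raises assorted types for bad files
        raise FileUnreadable(f"cannot parse {path} as EDF: {exc}") from exc

    labels = list(raw.ch_names)
    hints = (channel_hint,) if channel_hint else DEFAULT_SPO2_LABELS
    name = None
    for hint in hints:
        for lab in labels:
            if lab.strip().lower() == hint.strip().lower():
                name = lab
                break
        if name:
            break
    if name is None:
        raise ChannelNotFound(channel_hint or "/".join(DEFAULT_SPO2_LABELS), labels)

    raw = raw.pick([name]).load_data(verbose="error")
    values = raw.get_data()[0]
    return OximetrySignal(values=values, sample_rate_hz=float(raw.info["sfreq"]))


def read_staging_profusion(path) -> Hypnogram:
    """Parse sleep stages from a Compumedics Profusion XML annotation file.

    Stage codes follow the Profusion convention (0=W, 1=N1, 2=N2, 3=N3,
    5=REM). Unknown codes become UNSCORED with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileUnreadable(f"no such file: {path}")
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise MalformedAnnotation(f"{path} is not well-formed XML: {exc}") from exc

    nodes = tree.findall(".//SleepStages/SleepStage")
    if not nodes:
        nodes = tree.findall(".//SleepStage")
    if not nodes:
        raise MalformedAnnotation(f"{path}: no SleepStage entries found")

    stages = []
    for i, node in enumerate(nodes):
        text = (node.text or "").strip()
        try:
            code = int(text)
        except ValueError:
            code = -1
        if code not in PROFUSION_CODES:
            logger.warning("epoch %d: unknown stage code %r -> UNSCORED", i, text)
            stages.append("UNSCORED")
        else:
            stages.append(PROFUSION_CODES[code])
    return Hypnogram(stages=stages)


def read_staging_csv(path) -> Hypnogram:
    """Read per-epoch staging from a CSV with a ``stage`` column."""
    path = Path(path)
    if not path.exists():
        raise FileUnreadable(f"no such file: {path}")
    df = pd.read_csv(path)
    if "stage" not in df.columns:
        raise MalformedAnnotation(f"{path}: no 'stage' column")
    stages = []
    for i, s in enumerate(df["stage"].astype(str).str.strip()):
        if s not in STAGES:
            logger.warning("epoch %d: unknown stage %r -> UNSCORED", i, s)
            s = "UNSCORED"
        stages.append(s)
    return Hypnogram(stages=stages)


def read_signal_csv(path) -> OximetrySignal:
    """Read a generic SpO2 CSV with columns ``time_s`` and ``spo2_pct``.

    The sampling rate is inferred from the (required uniform) time spacing;
    blank or non-numeric saturation entries become invalid samples. A header
    row is optional.
    """
    path = Path(path)
    if not path.exists():
        raise FileUnreadable(f"no such file: {path}")
    df = pd.read_csv(path, header=None, skip_blank_lines=True)
    if df.shape[1] < 2:
        raise FileUnreadable(f"{path}: expected two columns (time_s, spo2_pct)")
    # Drop a header row if the first cell is not numeric.
    try:
        float(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    if df.empty:
        raise EmptySignal(f"{path}: no samples")

    t = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy(dtype=float)
    v = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(dtype=float)

    if len(t) < 2:
        rate = 1.0
    else:
        dt = np.diff(t)
        dt0 = dt.mean()
        if dt0 <= 0 or np.any(np.abs(dt - dt0) > 1e-6 * max(abs(dt0), 1.0)):
            raise NonUniformSampling(f"{path}: sample spacing varies")
        rate = 1.0 / dt0

    valid = np.isfinite(v)
    v = np.where(valid, v, 0.0)
    return OximetrySignal(values=v, sample_rate_hz=rate, valid=valid, t0_s=float(t[0]))


def standardize_to_1hz(signal: OximetrySignal) -> OximetrySignal:
    """Resample an oximetry signal to exactly 1 Hz.

    Rates above 1 Hz are reduced by the arithmetic mean of valid samples in
    each second [t, t+1) — the mean, not decimation, because the downstream
    metric is an integral and the mean preserves area. Rates below 1 Hz are
    upsampled sample-and-hold. A second with no valid native sample is
    invalid. Finally, samples outside (0, 100] are marked invalid
    (sensor-dropout rule; artifact exclusion proper happens at event level).
    """
    if len(signal) == 0:
        raise EmptySignal("cannot standardize an empty signal")
    rate = float(signal.sample_rate_hz)
    if rate <= 0:
        raise ValueError("sample_rate_hz must be positive")

    if rate == 1.0:
        values = signal.values.copy()
        valid = signal.valid.copy()
    else:
        n_out = int(np.ceil(len(signal) / rate))
        values = np.zeros(n_out)
        valid = np.zeros(n_out, dtype=bool)
        if rate > 1.0:
            owner = np.floor(np.arange(len(signal)) / rate).astype(int)
            for k in range(n_out):
                sel = (owner == k) & signal.valid
                if sel.any():
                    values[k] = signal.values[sel].mean()
                    valid[k] = True
        else:
            src = np.floor(np.arange(n_out) * rate).astype(int)
            values = signal.values[src].copy()
            valid = signal.valid[src].copy()

    physio = (values > 0.0) & (values <= 100.0)
    valid &= physio
    return OximetrySignal(values=values, sample_rate_hz=1.0, valid=valid,
                          t0_s=signal.t0_s)
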