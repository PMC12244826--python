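"""Synthetic 1 Hz oximetry recordings, hypnograms and cohorts with exact
analytic ground truth.

Recordings are a stable baseline with piecewise-linear desaturation dips
(square, triangle or trapezoid), optional sub-lower-threshold artifact
dips, missing-sample dropouts, truncated-Gaussian noise and a 30-s-epoch
hypnogram. Dip vertices sit on integer seconds, so the 1 Hz sampled
signal interpolates back to exactly the designed polyline and every event
boundary, area and corrected total has a closed form. Ground truth is
computed for the noise-free signal by line-threshold geometry on the dip
polylines — independently of the event-detection and area code it is used
to test.

The cohort generator targets the statistical machinery (quintiles, Cox
models, multiplicity correction), not physiological realism: heavy-tailed
severity values, exponential survival with a per-quintile-step log-hazard,
independent censoring, and null covariates.
"""
from __future__ import annotations

import struct
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import OverlappingDips, UnsupportedShape
from .oximetry_io import Hypnogram, OximetrySignal, PROFUSION_CODES
from .whi_metrics import WHIConfig

SHAPES = ("square", "triangle", "trapezoid")
_STAGE_TO_CODE = {v: k for k, v in PROFUSION_CODES.items()}
_STAGE_TO_CODE["UNSCORED"] = 9


@dataclass
class Dip:
    """One desaturation excursion.

    ``square`` holds the nadir for ``duration_s`` samples with 1-s edge
    ramps to the flanking baseline samples; ``triangle`` descends for half
    the duration and ascends back (duration must be even); ``trapezoid``
    ramps down over ``ramp_s``, holds, and ramps up.
    """

    onset_s: int
    duration_s: int
    nadir_pct: float
    shape: str = "square"
    ramp_s: int = 2

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise UnsupportedShape(f"unknown dip shape {self.shape!r}")
        if self.shape == "triangle" and self.duration_s % 2:
            raise ValueError("triangle dips need an even duration_s")
        if self.shape == "trapezoid" and 2 * self.ramp_s >= self.duration_s:
            raise ValueError("trapezoid ramps must fit inside the duration")

    def vertices(self, baseline: float) -> list[tuple[float, float]]:
        """Polyline (t, SpO2) of the excursion including flanking baseline."""
        o, w, n = self.onset_s, self.duration_s, self.nadir_pct
        if self.shape == "square":
            return [(o - 1, baseline), (o, n), (o + w - 1, n), (o + w, baseline)]
        if self.shape == "triangle":
            return [(o, baseline), (o + w // 2, n), (o + w, baseline)]
        r = self.ramp_s
        return [(o, baseline), (o + r, n), (o + w - r, n), (o + w, baseline)]

    @property
    def support(self) -> tuple[int, int]:
        """Closed time span [lo, hi] the dip touches, incl. square flanks."""
        if self.shape == "square":
            return self.onset_s - 1, self.onset_s + self.duration_s
        return self.onset_s, self.onset_s + self.duration_s


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic recording."""

    duration_s: int = 28800  # 8 h, a typical full-night PSG
    baseline_pct: float = 95.0
    dips: list = field(default_factory=list)
    artifact_dips: list = field(default_factory=list)
    dropout_spans: list = field(default_factory=list)  # (start_s, len_s)
    noise_sd_pct: float = 0.0
    hypnogram_pattern: list = None  # run-length encoded [(stage, n_epochs)]
    seed: int = 0

    def __post_init__(self):
        self.dips = [d if isinstance(d, Dip) else Dip(**d) for d in self.dips]
        self.artifact_dips = [
            d if isinstance(d, Dip) else Dip(**d) for d in self.artifact_dips
        ]
        if self.hypnogram_pattern is None:
            n_epochs = max(int(np.ceil(self.duration_s / 30)), 1)
            self.hypnogram_pattern = [("N2", n_epochs)]
        spans = sorted(d.support for d in self.dips + self.artifact_dips)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 <= a1:
                raise OverlappingDips(f"dips at {a0}-{a1} and {b0}-{b1} overlap")
        for d in self.dips + self.artifact_dips:
            if not 0 < d.nadir_pct <= self.baseline_pct <= 100:
                raise ValueError("need 0 < nadir <= baseline <= 100")
            lo, hi = d.support
            if lo < 0 or hi >= self.duration_s:
                raise ValueError("dip extends outside the recording")

    def all_dips(self) -> list[Dip]:
        return sorted(self.dips + self.artifact_dips, key=lambda d: d.onset_s)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        doc = yaml.safe_load(Path(path).read_text())
        doc["dropout_spans"] = [tuple(x) for x in doc.get("dropout_spans", [])]
        if doc.get("hypnogram_pattern"):
            doc["hypnogram_pattern"] = [tuple(x) for x in doc["hypnogram_pattern"]]
        return cls(**doc)


@dataclass
class GroundTruth:
    """Exact noise-free expectations for one spec under one config."""

    per_dip: list  # {onset_s, event, start_s, end_s, phi_s, aac, auc, excluded}
    tstc_s: int
    tst90c_s: int
    omega: float
    whi: float


# --- closed-form geometry on dip polylines ---------------------------------

def _below_interval(verts, thr):
    """(t_in, t_out) where the polyline is strictly below thr, or None.

    Dip polylines are unimodal (down then up), so the below-threshold set
    is a single interval.
    """
    t_in = t_out = None
    for (t1, v1), (t2, v2) in zip(verts, verts[1:]):
        if t_in is None and v1 >= thr and v2 < thr:
            t_in = t1 + (v1 - thr) / (v1 - v2) * (t2 - t1)
        if t_in is not None and v1 < thr and v2 >= thr:
            t_out = t1 + (v1 - thr) / (v1 - v2) * (t2 - t1)
            break
    if t_in is None or t_out is None:
        return None
    return t_in, t_out


def _area_below(verts, thr, t_in, t_out):
    """∫(thr − s) over [t_in, t_out] by exact per-segment integration."""
    area = 0.0
    for (t1, v1), (t2, v2) in zip(verts, verts[1:]):
        a, b = max(t1, t_in), min(t2, t_out)
        if b <= a:
            continue
        slope = (v2 - v1) / (t2 - t1)
        va = v1 + slope * (a - t1)
        vb = v1 + slope * (b - t1)
        area += 0.5 * ((thr - va) + (thr - vb)) * (b - a)
    return area


def _sleep_mask_from_pattern(pattern, duration_s):
    """Per-second sleep mask + epoch stages, using the onset/offset rules
    (first run of 3 consecutive N1/N2/N3; last N1/N2/N3/REM epoch)."""
    stages = []
    for stage, n in pattern:
        stages.extend([stage] * int(n))
    core = {"N1", "N2", "N3"}
    sleep = {"N1", "N2", "N3", "REM"}
    onset_epoch = None
    run = 0
    for i, s in enumerate(stages):
        run = run + 1 if s in core else 0
        if run == 3:
            onset_epoch = i - 2
            break
    mask = np.zeros(duration_s, dtype=bool)
    if onset_epoch is None:
        return stages, mask
    last = max(i for i, s in enumerate(stages) if s in sleep)
    for i, s in enumerate(stages):
        if onset_epoch <= i <= last and s in sleep:
            mask[i * 30:min((i + 1) * 30, duration_s)] = True
    return stages, mask


def analytic_ground_truth(
    spec: SyntheticSpec, config: WHIConfig | None = None
) -> GroundTruth:
    """Closed-form expectations for the noise-free recording.

    Event boundaries are line-threshold intersections on the dip vertex
    polylines; areas are exact trapezoids on those segments; corrected
    totals are direct sample counts on the noise-free signal. Serves as
    the independent oracle for the detection and metric code.
    """
    config = config or WHIConfig()
    thr = config.upper_threshold_pct
    lower = config.lower_threshold_pct
    b = spec.baseline_pct

    values, valid = _clean_samples(spec)
    stages, sleep_mask = _sleep_mask_from_pattern(
        spec.hypnogram_pattern, spec.duration_s
    )

    per_dip = []
    artifact_seconds = np.zeros(spec.duration_s, dtype=bool)
    for dip in spec.all_dips():
        verts = dip.vertices(b)
        hit = _below_interval(verts, thr)
        if hit is None:
            per_dip.append({"onset_s": dip.onset_s, "event": False,
                            "excluded": False, "phi_s": 0.0,
                            "aac": 0.0, "auc": 0.0})
            continue
        t_in, t_out = hit
        excluded = dip.nadir_pct < lower
        aac = _area_below(verts, thr, t_in, t_out)
        phi = t_out - t_in
        per_dip.append({
            "onset_s": dip.onset_s, "event": True, "excluded": excluded,
            "start_s": t_in, "end_s": t_out, "phi_s": phi,
            "aac": aac, "auc": thr * phi - aac,
        })
        if excluded:
            k0, k1 = int(np.ceil(t_in)), int(np.floor(t_out))
            artifact_seconds[k0:k1 + 1] = True

    counted = sleep_mask & valid & ~artifact_seconds
    tstc = int(counted.sum())
    tst90c = int((counted & (values < config.norm_threshold_pct)).sum())

    if config.normalization == "tst90c_over_tstc":
        omega = tst90c / tstc if tstc else float("nan")
    else:
        omega = 1.0
    acc = 0.0
    for d in per_dip:
        if d["event"] and not d["excluded"]:
            delta = d["aac"] if config.area_mode == "AAC" else d["auc"]
            phi = d["phi_s"] if config.weighted else 1.0
            acc += delta * phi
    return GroundTruth(per_dip=per_dip, tstc_s=tstc, tst90c_s=tst90c,
                       omega=omega, whi=omega * acc)


# --- recording construction -------------------------------------------------

def _clean_samples(spec: SyntheticSpec):
    values = np.full(spec.duration_s, spec.baseline_pct, dtype=float)
    for dip in spec.all_dips():
        verts = dip.vertices(spec.baseline_pct)
        ts = np.array([t for t, _ in verts], dtype=float)
        vs = np.array([v for _, v in verts], dtype=float)
        lo, hi = dip.support
        k = np.arange(max(lo, 0), min(hi, spec.duration_s - 1) + 1)
        values[k] = np.interp(k, ts, vs)
    valid = np.ones(spec.duration_s, dtype=bool)
    for start, length in spec.dropout_spans:
        valid[int(start):int(start) + int(length)] = False
    return values, valid


def generate_recording(
    spec: SyntheticSpec, config: WHIConfig | None = None
) -> tuple[OximetrySignal, Hypnogram, GroundTruth]:
    """Build the 1 Hz recording, its hypnogram and the analytic truth.

    Deterministic given ``spec.seed``. Noise (truncated Gaussian, clipped
    into (0, 100]) is added after the ground truth is computed, so the
    truth describes the noise-free curve. Dropout spans are marked invalid.
    """
    truth = analytic_ground_truth(spec, config)
    values, valid = _clean_samples(spec)
    if spec.noise_sd_pct > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd_pct, size=values.shape)
        values = np.clip(values, 1e-3, 100.0)
    stages = []
    for stage, n in spec.hypnogram_pattern:
        stages.extend([stage] * int(n))
    signal = OximetrySignal(values=values, sample_rate_hz=1.0, valid=valid)
    return signal, Hypnogram(stages=stages), truth


# --- fixture writers --------------------------------------------------------

def write_edf(path, signal: OximetrySignal, label: str = "SaO2") -> None:
    """Write a minimal single-channel EDF fixture (16-bit, 0–100%)."""
    rate = int(round(signal.sample_rate_hz))
    if rate < 1 or abs(rate - signal.sample_rate_hz) > 1e-9:
        raise ValueError("EDF fixture writer needs an integer sample rate")
    v = np.asarray(signal.values, dtype=float)
    nrec = int(np.ceil(len(v) / rate))
    v = np.concatenate([v, np.full(nrec * rate - len(v), v[-1])])
    pmin, pmax, dmin, dmax = 0.0, 100.0, -32768, 32767
    dig = np.round((v - pmin) / (pmax - pmin) * (dmax - dmin) + dmin)
    dig = np.clip(dig, dmin, dmax).astype("<i2")

    def f(s, n):
        return str(s)[:n].ljust(n).encode("ascii")

    header = b"".join([
        f("0", 8), f("X X X X", 80), f("Startdate X X X X", 80),
        f("01.01.00", 8), f("00.00.00", 8), f(256 * 2, 8),
        f("EDF+C", 44), f(nrec, 8), f("1", 8), f("1", 4),
        f(label, 16), f("", 80), f("%", 8), f(pmin, 8), f(pmax, 8),
        f(dmin, 8), f(dmax, 8), f("", 80), f(rate, 8), f("", 32),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(dig.tobytes())


def write_profusion_xml(path, hypnogram: Hypnogram) -> None:
    """Write a Compumedics Profusion-style staging fixture."""
    lines = ["<CMPStudyConfig>", "<SleepStages>"]
    for s in hypnogram.stages:
        lines.append(f"<SleepStage>{_STAGE_TO_CODE[s]}</SleepStage>")
    lines += ["</SleepStages>", "</CMPStudyConfig>"]
    Path(path).write_text("\n".join(lines))


def write_signal_csv(path, signal: OximetrySignal) -> None:
    """Two-column CSV (time_s, spo2_pct); invalid samples left blank."""
    t = signal.times()
    with open(path, "w") as fh:
        fh.write("time_s,spo2_pct\n")
        for ti, vi, ok in zip(t, signal.values, signal.valid):
            fh.write(f"{ti:g},{vi:.6g}\n" if ok else f"{ti:g},\n")


def write_staging_csv(path, hypnogram: Hypnogram) -> None:
    pd.DataFrame({"stage": hypnogram.stages}).to_csv(path, index=False)


# --- cohort generator -------------------------------------------------------

def generate_cohort(
    n_subjects: int,
    severity_grid=None,
    hazard_spec: dict | None = None,
    censor_rate: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject severity + survival + null covariates for the Cox harness.

    Severity is drawn from ``severity_grid`` (any 1-D array, sampled with
    replacement) or a heavy-tailed lognormal mimicking the many-orders-of-
    magnitude spread of the index. Survival is exponential with hazard
    ``baseline_hazard × exp(log_hr_per_quintile × (quintile − 1))`` where
    quintiles are ranks of the severity. Censoring is an independent
    exponential time whose rate is solved so the expected censored
    fraction equals ``censor_rate`` (independence keeps the Cox
    partial-likelihood variance valid). Covariates are drawn independently
    of survival (null effects).
    """
    if n_subjects < 50:
        raise ValueError("need n_subjects >= 50")
    hs = {"baseline_hazard": 0.02, "log_hr_per_quintile": 0.5}
    hs.update(hazard_spec or {})
    rng = np.random.default_rng(seed)

    if severity_grid is not None:
        grid = np.asarray(severity_grid, dtype=float)
        severity = rng.choice(grid, size=n_subjects, replace=True)
    else:
        severity = np.exp(rng.normal(3.0, 2.5, size=n_subjects))

    order = np.argsort(severity, kind="stable")
    quintile = np.empty(n_subjects, dtype=int)
    sizes = [n_subjects // 5 + (1 if i < n_subjects % 5 else 0) for i in range(5)]
    start = 0
    for q, size in enumerate(sizes, start=1):
        quintile[order[start:start + size]] = q
        start += size

    hazard = hs["baseline_hazard"] * np.exp(
        hs["log_hr_per_quintile"] * (quintile - 1)
    )
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate >= 1.0:
        time = rng.uniform(0.1, 10.0, size=n_subjects)
        censored = np.ones(n_subjects, dtype=bool)
    elif censor_rate <= 0.0:
        time = t_event
        censored = np.zeros(n_subjects, dtype=bool)
    else:
        # independent exponential censoring; P(censored | hazard h) = c/(c+h),
        # solve the rate c so the expected censored fraction matches
        lo, hi = 1e-10, 1e10
        for _ in range(200):
            c = np.sqrt(lo * hi)
            if np.mean(c / (c + hazard)) < censor_rate:
                lo = c
            else:
                hi = c
        t_cens = rng.exponential(1.0 / c, size=n_subjects)
        censored = t_cens < t_event
        time = np.minimum(t_event, t_cens)
    time = np.maximum(time, 1e-6)

    df = pd.DataFrame({
        "subject_id": [f"S{i:05d}" for i in range(n_subjects)],
        "whi_auc90": severity,
        "tst90": np.clip(severity ** 0.3 + rng.normal(0, 1, n_subjects), 0, 100),
        "min_sat": np.clip(92 - np.log1p(severity)
                           + rng.normal(0, 2, n_subjects), 40, 100),
        "survival_time": time,
        "event_indicator": (~censored).astype(int),
        "age": rng.normal(63, 10, n_subjects).round(1),
        "gender": rng.choice(["Female", "Male"], n_subjects),
        "race": rng.choice(["White", "Black", "Other"], n_subjects,
                           p=[0.85, 0.08, 0.07]),
        "bmi": rng.normal(28, 5, n_subjects).clip(16, 55).round(1),
        "copd": rng.binomial(1, 0.02, n_subjects),
        "smoking": rng.choice(["never", "former", "current"], n_subjects,
                              p=[0.47, 0.10, 0.43]),
        "alcohol": rng.choice(["<1", "1-12", ">=13"], n_subjects,
                              p=[0.58, 0.36, 0.06]),
        "sleep_duration": rng.choice(["<=5h", "5-8h", ">=8h"], n_subjects,
                                     p=[0.09, 0.82, 0.09]),
        "diabetes": rng.binomial(1, 0.08, n_subjects),
        "hypertension": rng.binomial(1, 0.41, n_subjects),
        "chf": rng.binomial(1, 0.03, n_subjects),
        "angina": rng.binomial(1, 0.05, n_subjects),
        "mi": rng.binomial(1, 0.07, n_subjects),
        "revascularization": rng.binomial(1, 0.06, n_subjects),
        "stroke": rng.binomial(1, 0.04, n_subjects),
        "lipid_med": rng.binomial(1, 0.13, n_subjects),
    })
    return df
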