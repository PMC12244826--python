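import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from whi import Dip, Hypnogram, OximetrySignal, SyntheticSpec, WHIConfig


@pytest.fixture
def r1_spec():
    """Recording R1: 90 s, baseline 95, square dip to 85 over samples 10-19,
    three N2 epochs."""
    return SyntheticSpec(
        duration_s=90,
        baseline_pct=95.0,
        dips=[Dip(onset_s=10, duration_s=10, nadir_pct=85.0)],
        hypnogram_pattern=[("N2", 3)],
    )


@pytest.fixture
def r2_spec():
    """R2 = R1 plus an artifact dip to 45% over samples 50-54."""
    return SyntheticSpec(
        duration_s=90,
        baseline_pct=95.0,
        dips=[Dip(onset_s=10, duration_s=10, nadir_pct=85.0)],
        artifact_dips=[Dip(onset_s=50, duration_s=5, nadir_pct=45.0)],
        hypnogram_pattern=[("N2", 3)],
    )


@pytest.fixture
def r1(r1_spec):
    from whi import generate_recording

    sig, hyp, _ = generate_recording(r1_spec)
    return sig, hyp


@pytest.fixture
def r2(r2_spec):
    from whi import generate_recording

    sig, hyp, _ = generate_recording(r2_spec)
    return sig, hyp


def make_signal(values, valid=None, rate=1.0):
    return OximetrySignal(values=np.asarray(values, float),
                          sample_rate_hz=rate, valid=valid)


def all_n2(n_seconds):
    return Hypnogram(["N2"] * int(np.ceil(n_seconds / 30)))
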