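"""Shared fixtures: small synthetic cohorts and representative windows."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import signal as sps

from ehgpred.synth import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort (10 imminent / 20 control, 10-min recordings)."""
    cfg = SynthConfig(n_imminent=10, n_control=20, duration_s=600.0, seed=42)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def ehg_like_window(rng):
    """A band-limited (0.1-4 Hz at 20 Hz) noise window of 2400 samples."""
    sos = sps.butter(4, [0.1, 4.0], btype="bandpass", fs=20.0, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(3600))[1200:]
    return x


@pytest.fixture(scope="session")
def short_windows(rng):
    """100 random 300-sample windows mixing noise and band-limited signals."""
    sos = sps.butter(4, [0.1, 4.0], btype="bandpass", fs=20.0, output="sos")
    windows = []
    for i in range(100):
        if i % 2 == 0:
            windows.append(rng.standard_normal(300))
        else:
            w = sps.sosfilt(sos, rng.standard_normal(900))[600:]
            windows.append(w / np.std(w))
    return windows
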