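"""Shared fixtures: small synthetic subjects and audio snippets.

Everything is generated at test time from fixed seeds; nothing is read from
disk.  The session-scoped cohort fixtures are shared between the acceptance
tests and the slower property tests so the audio pipeline runs once.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import cpet_acoustics as ca

ACCEPTANCE_SEED = 1
ACCEPTANCE_N = 24


@pytest.fixture(scope="session")
def default_subject():
    """One mid-cohort subject with the default study conditions."""
    cfg = ca.SimulationConfig()
    return ca.simulate_subject(cfg, seed=12345)


@pytest.fixture(scope="session")
def default_record(default_subject):
    return ca.simulate_record(default_subject, with_audio=True)


@pytest.fixture(scope="session")
def noiseless_record(default_subject):
    """Same subject with every noise source disabled (ground-truth limit)."""
    subj = dataclasses.replace(
        default_subject,
        breath_cv=0.0,
        channel_cv=0.0,
        snr_db=np.inf,
        spike_rate_per_min=0.0,
    )
    return ca.simulate_record(subj, with_audio=True)


@pytest.fixture(scope="session")
def acceptance_cohort():
    """The 24-subject cohort at the default study conditions (seed fixed)."""
    return ca.simulate_cohort(
        ca.SimulationConfig(n_subjects=ACCEPTANCE_N, seed=ACCEPTANCE_SEED)
    )


@pytest.fixture(scope="session")
def acceptance_at_result(acceptance_cohort):
    """Intensity-based AT study on the acceptance cohort (runs the full audio chain)."""
    return ca.evaluate_cohort_at(acceptance_cohort, feature="intensity")


def make_burst_audio(
    rate=6000.0,
    n_bursts=30,
    burst_s=1.0,
    gap_s=1.0,
    amp=0.2,
    seed=0,
    noise_sigma=0.0,
):
    """Periodic band-limited bursts: the canonical segmentation input."""
    from scipy import signal

    rng = np.random.default_rng(seed)
    period = burst_s + gap_s
    n = int(rate * (n_bursts * period + gap_s))
    sos = signal.butter(4, [100.0, min(2900.0, rate / 2 - 100)], btype="bandpass", fs=rate, output="sos")
    carrier = signal.sosfilt(sos, rng.standard_normal(n))
    carrier /= np.sqrt(np.mean(carrier**2))
    env = np.zeros(n)
    for k in range(n_bursts):
        i0 = int((gap_s + k * period) * rate)
        i1 = i0 + int(burst_s * rate)
        env[i0:i1] = amp * signal.windows.tukey(i1 - i0, 0.2)
    x = carrier * env
    if noise_sigma > 0:
        x = x + noise_sigma * rng.standard_normal(n)
    return ca.AudioRecording(samples=np.clip(x, -1, 1), rate=rate)
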