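"""Breath-phase detection and breath-cycle assembly from the sound envelope.

Respiratory sound bursts (inspiratory and expiratory) are detected with a
dual-threshold hysteresis on the log-power envelope, referenced to a rolling
low-percentile baseline so that the rising sound floor across exercise
stages does not inflate the thresholds.  Because the baseline adapts, the
segmentation is invariant to a global gain change of the audio.

Detected sound-burst phases are grouped into breath cycles.  Within a breath
the inspiratory/expiratory pause is shorter than the pause separating
breaths, so two consecutive phases are paired into one cycle when their gap
is no longer than the following inter-phase gap; otherwise the phase stands
alone as a single-phase cycle (this keeps the pairing in register when one
phase of a breath is missed).  Cycle onset-to-onset intervals define the
instantaneous breath duration used for the respiratory-rate feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .audio import AudioRecording

_ENV_EPS = 1e-12


@dataclass(frozen=True)
class EnvelopeSeries:
    """Uniform short-time log-power envelope (dB re full scale)."""

    times: np.ndarray     # frame centers, s
    values: np.ndarray    # dB
    frame_s: float
    hop_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.size != v.size or t.size < 2:
            raise ValueError("times/values must be equal-length with >= 2 frames")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.isfinite(v).all():
            raise ValueError("envelope values must be finite")


@dataclass(frozen=True)
class BreathPhase:
    onset: float
    offset: float
    kind: str = "sound-burst"

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("phase offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class BreathCycle:
    """One breath: 1-2 sound-burst phases spanning [onset, offset)."""

    onset: float
    offset: float
    phases: tuple = field(default=())

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("cycle offset must exceed onset")
        if not (1 <= len(self.phases) <= 2):
            raise ValueError("a cycle must contain 1-2 phases")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.onset + self.offset)


def compute_envelope(
    rec: AudioRecording, frame_s: float = 0.05, hop_s: float = 0.025
) -> EnvelopeSeries:
    """Short-time log-power envelope: ``10 log10(mean(x^2) + eps)`` per frame."""
    if not (0 < hop_s <= frame_s < rec.duration):
        raise ValueError("need 0 < hop <= frame < duration")
    win = max(1, int(round(frame_s * rec.rate)))
    hop = max(1, int(round(hop_s * rec.rate)))
    x = rec.samples
    csum = np.concatenate(([0.0], np.cumsum(np.square(x))))
    starts = np.arange(0, max(1, x.size - win + 1), hop)
    mean_sq = (csum[starts + win] - csum[starts]) / win
    values = 10.0 * np.log10(mean_sq + _ENV_EPS)
    times = rec.t0 + (starts + win / 2) / rec.rate
    return EnvelopeSeries(times=times, values=values, frame_s=frame_s, hop_s=hop * 1.0 / rec.rate)


@dataclass(frozen=True)
class SegmentationParams:
    """Hysteresis segmentation thresholds (dB margins over a rolling baseline)."""

    baseline_window_s: float = 15.0
    baseline_percentile: float = 20.0
    high_margin_db: float = 6.0
    low_margin_db: float = 3.0
    min_phase_s: float = 0.15
    min_gap_s: float = 0.10
    min_breath_s: float = 0.4


def _hysteresis_segments(values, baseline, high_db, low_db):
    """Index spans where values rise above baseline+high until below baseline+low."""
    above_high = values > baseline + high_db
    above_low = values > baseline + low_db
    segments = []
    open_i = None
    for i in range(values.size):
        if open_i is None:
            if above_high[i]:
                open_i = i
        elif not above_low[i]:
            segments.append((open_i, i))
            open_i = None
    if open_i is not None:
        segments.append((open_i, values.size))
    return segments


def detect_breath_phases(
    env: EnvelopeSeries, params: SegmentationParams | None = None
) -> list[BreathPhase]:
    """Sound-burst phases from adaptive dual-threshold hysteresis."""
    params = params or SegmentationParams()
    nb = max(3, int(round(params.baseline_window_s / env.hop_s)) | 1)
    baseline = ndimage.percentile_filter(
        env.values, params.baseline_percentile, size=nb, mode="nearest"
    )
    spans = _hysteresis_segments(
        env.values, baseline, params.high_margin_db, params.low_margin_db
    )
    # convert to times (frame centers), then merge short gaps and drop short phases
    intervals = [
        (env.times[a], env.times[min(b, env.times.size - 1)]) for a, b in spans if b > a
    ]
    merged: list[list[float]] = []
    for on, off in intervals:
        if merged and on - merged[-1][1] < params.min_gap_s:
            merged[-1][1] = off
        else:
            merged.append([on, off])
    return [
        BreathPhase(onset=on, offset=off)
        for on, off in merged
        if off - on >= params.min_phase_s
    ]


def pair_phases_into_cycles(
    phases: list[BreathPhase], params: SegmentationParams | None = None
) -> list[BreathCycle]:
    """Group sound-burst phases into breath cycles by relative gap length."""
    params = params or SegmentationParams()
    n = len(phases)
    if n == 0:
        return []
    gaps = [phases[i + 1].onset - phases[i].offset for i in range(n - 1)]
    cycles: list[BreathCycle] = []
    i = 0
    while i < n:
        pair = False
        if i + 1 < n:
            nxt = gaps[i + 1] if i + 1 < len(gaps) else np.inf
            # min_gap_s as a tie tolerance: measured gaps are quantized to
            # the envelope hop, so exact equality cannot be relied on
            pair = gaps[i] <= nxt + params.min_gap_s
        if pair:
            cyc_phases = (phases[i], phases[i + 1])
            i += 2
        else:
            cyc_phases = (phases[i],)
            i += 1
        onset = cyc_phases[0].onset
        offset = cyc_phases[-1].offset
        if offset - onset >= params.min_breath_s:
            cycles.append(BreathCycle(onset=onset, offset=offset, phases=cyc_phases))
    return cycles


def detect_breath_cycles(
    env: EnvelopeSeries, params: SegmentationParams | None = None
) -> list[BreathCycle]:
    """Detect breath cycles on an envelope covering at least ~10 s.

    Returns an empty list (not an exception) when no phase is found, so
    downstream code can flag missing respiratory rate instead of failing.
    """
    params = params or SegmentationParams()
    if env.times[-1] - env.times[0] < 10.0:
        raise ValueError("envelope must cover at least 10 s")
    phases = detect_breath_phases(env, params)
    return pair_phases_into_cycles(phases, params)


def cycles_to_array(cycles: list[BreathCycle]) -> np.ndarray:
    """(n, 3) array of onset, offset, duration - the CSV export layout."""
    return np.array([(c.onset, c.offset, c.duration) for c in cycles]).reshape(-1, 3)
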