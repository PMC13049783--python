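"""Breath-wise acoustic features on a uniform protocol-clock grid.

Four features are extracted from the cleaned respiratory sound:

* **sound energy** - per-breath sum of squared amplitude (unitless, the
  device gain being uncalibrated);
* **sound intensity** - energy divided by breath duration, i.e. the average
  acoustic power of the breath (per second);
* **respiratory rate** - 60 / (cycle onset-to-onset interval), breaths/min;
* **acoustic ventilation** - respiratory rate x sound intensity, the
  acoustic analogue of minute ventilation (rate x "volume per breath").

Per-breath values are median-smoothed over a few breaths (local peaks from
irregular breaths otherwise dominate the energy trace) and linearly
interpolated onto a uniform grid labeled with the protocol stage.  Grid
points farther than a gap tolerance from any breath are flagged missing
rather than silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio import AudioRecording
from .protocol import ProtocolSpec
from .segmentation import BreathCycle


@dataclass(frozen=True)
class FeatureSeries:
    """Uniform-grid acoustic feature traces aligned to the protocol clock."""

    times: np.ndarray
    energy: np.ndarray
    intensity: np.ndarray
    rr: np.ndarray                   # breaths/min
    acoustic_ventilation: np.ndarray
    stage: np.ndarray                # protocol stage index per grid point
    missing: np.ndarray              # bool: no breath within the gap tolerance

    def __post_init__(self) -> None:
        n = self.times.size
        for name in ("energy", "intensity", "rr", "acoustic_ventilation", "stage", "missing"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name} length mismatch")
        steps = np.diff(self.times)
        if n > 1 and not np.allclose(steps, steps[0]):
            raise ValueError("grid must be uniform")

    def channel(self, name: str) -> np.ndarray:
        if name not in ("energy", "intensity", "rr", "acoustic_ventilation"):
            raise KeyError(f"unknown feature channel {name!r}")
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "energy": self.energy,
                "intensity": self.intensity,
                "rr_bpm": self.rr,
                "acoustic_ventilation": self.acoustic_ventilation,
                "stage": self.stage,
                "missing": self.missing,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureSeries":
        return cls(
            times=df["time_s"].to_numpy(float),
            energy=df["energy"].to_numpy(float),
            intensity=df["intensity"].to_numpy(float),
            rr=df["rr_bpm"].to_numpy(float),
            acoustic_ventilation=df["acoustic_ventilation"].to_numpy(float),
            stage=df["stage"].to_numpy(int),
            missing=df["missing"].to_numpy(bool),
        )


def per_breath_features(rec: AudioRecording, cycles: list[BreathCycle]) -> pd.DataFrame:
    """Per-breath energy / intensity / duration table.

    Each breath's span runs from its cycle onset to the next cycle's onset
    (the last cycle ends at its own offset), so every sample belongs to
    exactly one breath and the integration window does not depend on how
    deeply the detector's thresholds cut into the burst ramps.  Energy is
    the sum of squared samples over the span; breath duration is the
    onset-to-onset interval; intensity is energy per second of duration
    (the breath's mean acoustic power); the row's time stamp is the span
    midpoint.
    """
    t_start, t_end = rec.t0, rec.t0 + rec.duration
    rows = []
    for b, c in enumerate(cycles):
        if c.duration <= 0:
            raise ValueError("zero-duration cycle")
        if c.onset < t_start - 1e-9 or c.offset > t_end + 1e-9:
            raise ValueError(
                f"cycle [{c.onset}, {c.offset}] outside recording span [{t_start}, {t_end}]"
            )
        span_end = cycles[b + 1].onset if b + 1 < len(cycles) else c.offset
        span_end = min(span_end, t_end)
        duration = span_end - c.onset
        i0 = int(round((c.onset - rec.t0) * rec.rate))
        i1 = int(round((span_end - rec.t0) * rec.rate))
        energy = float(np.sum(np.square(rec.samples[i0:i1])))
        rows.append(
            {
                "time_s": 0.5 * (c.onset + span_end),
                "onset_s": c.onset,
                "offset_s": c.offset,
                "duration_s": duration,
                "energy": energy,
                "intensity": energy / duration,
            }
        )
    return pd.DataFrame(
        rows, columns=["time_s", "onset_s", "offset_s", "duration_s", "energy", "intensity"]
    )


def build_feature_series(
    breaths: pd.DataFrame,
    protocol: ProtocolSpec,
    grid_step_s: float = 1.0,
    smooth_breaths: int = 5,
    gap_tolerance_s: float = 10.0,
    log_energy: bool = False,
) -> FeatureSeries:
    """Interpolate per-breath features onto a uniform protocol-clock grid.

    Instantaneous respiratory rate is 60 / (onset-to-onset interval) placed
    at the midpoint of the interval; energy, intensity and rate are smoothed
    with a centered ``smooth_breaths`` rolling median before interpolation.
    The intensity denominator is the median-smoothed breath duration rather
    than each breath's raw one: detected onsets jitter by a few tens of
    milliseconds (threshold crossings on a noisy envelope), and dividing by
    the raw duration would inject that jitter straight into the intensity
    while true breath durations change only smoothly.  In the noiseless
    limit the two definitions coincide.  Acoustic ventilation is computed
    pointwise on the grid as rr x intensity so the defining identity holds
    exactly wherever both factors are defined.
    """
    if breaths.empty:
        raise ValueError("no breaths to build a feature series from")
    if grid_step_s <= 0:
        raise ValueError("grid step must be positive")
    b = breaths.sort_values("time_s").reset_index(drop=True)

    onsets = b["onset_s"].to_numpy(float)
    intervals = np.diff(onsets)
    if np.any(intervals <= 0):
        raise ValueError("cycle onsets must be strictly increasing")
    rr_times = 0.5 * (onsets[:-1] + onsets[1:])
    rr_vals = 60.0 / intervals

    k = max(1, int(smooth_breaths))
    energy_raw = b["energy"].to_numpy(float)
    duration_sm = b["duration_s"].rolling(k, center=True, min_periods=1).median().to_numpy()
    intensity_pb = energy_raw / duration_sm
    energy = b["energy"].rolling(k, center=True, min_periods=1).median().to_numpy()
    intensity = (
        pd.Series(intensity_pb).rolling(k, center=True, min_periods=1).median().to_numpy()
    )
    if log_energy:
        energy = np.log10(energy + 1e-12)
    rr_s = pd.Series(rr_vals).rolling(k, center=True, min_periods=1).median().to_numpy()

    t_lo = max(0.0, float(b["time_s"].iloc[0]) - gap_tolerance_s)
    t_hi = min(protocol.end_s - 1e-9, float(b["time_s"].iloc[-1]) + gap_tolerance_s)
    if t_hi <= t_lo:
        raise ValueError("grid would not overlap both the data and the protocol")
    grid = np.arange(np.ceil(t_lo / grid_step_s), np.floor(t_hi / grid_step_s) + 1) * grid_step_s

    g_energy = np.interp(grid, b["time_s"], energy)
    g_intensity = np.interp(grid, b["time_s"], intensity)
    if rr_times.size:
        g_rr = np.interp(grid, rr_times, rr_s)
    else:
        g_rr = np.full(grid.size, np.nan)

    breath_times = b["time_s"].to_numpy(float)
    idx = np.searchsorted(breath_times, grid)
    prev_d = np.where(idx > 0, grid - breath_times[np.maximum(idx - 1, 0)], np.inf)
    next_d = np.where(
        idx < breath_times.size, breath_times[np.minimum(idx, breath_times.size - 1)] - grid, np.inf
    )
    missing = np.minimum(prev_d, next_d) > gap_tolerance_s
    missing |= ~np.isfinite(g_rr)

    stage = np.array([protocol.stage_at_time(t)[0] for t in grid], dtype=int)
    av = g_rr * g_intensity
    for arr in (g_energy, g_intensity, g_rr, av):
        arr[missing] = np.nan
    return FeatureSeries(
        times=grid,
        energy=g_energy,
        intensity=g_intensity,
        rr=g_rr,
        acoustic_ventilation=av,
        stage=stage,
        missing=missing,
    )


def extract_features(
    rec: AudioRecording,
    cycles: list[BreathCycle],
    protocol: ProtocolSpec,
    **kwargs,
) -> FeatureSeries:
    """Convenience wrapper: per-breath table then uniform feature series."""
    return build_feature_series(per_breath_features(rec, cycles), protocol, **kwargs)
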