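"""Anaerobic-threshold detection from acoustic features and gas exchange.

The acoustic AT estimate is the breakpoint of a two-segment continuous
piecewise-linear fit to a feature trace (sound energy or intensity) over the
exercise phase: at the AT, lactic-acid buffering produces excess CO2, minute
ventilation rises non-linearly, and - because tracheal sound tracks airflow -
the acoustic trace shows the same slope break.  The reference AT is the nadir
of the ventilatory equivalent VE/VO2, validated by VE/VCO2 still being flat
or decreasing there (the classic ventilatory-equivalents criterion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureSeries
from .protocol import ProtocolSpec


@dataclass(frozen=True)
class GasExchangeSeries:
    """Breath-by-breath gas exchange plus a (possibly separate) HR series.

    Ventilatory equivalents are derived on access so they can never go
    stale: VE/VO2 = VE [L/min] / (VO2 [mL/min] / 1000), likewise VE/VCO2.
    """

    times: np.ndarray      # s, breath times
    vo2: np.ndarray        # mL/min
    vco2: np.ndarray       # mL/min
    ve: np.ndarray         # L/min
    vt: np.ndarray         # L
    hr_times: np.ndarray   # s
    hr: np.ndarray         # beats/min

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("breath times must be strictly increasing")
        for name in ("vo2", "vco2", "ve"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be positive where present")

    @property
    def ve_vo2(self) -> np.ndarray:
        return self.ve / (self.vo2 / 1000.0)

    @property
    def ve_vco2(self) -> np.ndarray:
        return self.ve / (self.vco2 / 1000.0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_s": self.times,
                "vo2_ml_min": self.vo2,
                "vco2_ml_min": self.vco2,
                "ve_l_min": self.ve,
                "vt_l": self.vt,
            }
        )
        df["hr_bpm"] = np.interp(self.times, self.hr_times, self.hr)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GasExchangeSeries":
        t = df["time_s"].to_numpy(float)
        return cls(
            times=t,
            vo2=df["vo2_ml_min"].to_numpy(float),
            vco2=df["vco2_ml_min"].to_numpy(float),
            ve=df["ve_l_min"].to_numpy(float),
            vt=df["vt_l"].to_numpy(float),
            hr_times=t,
            hr=df["hr_bpm"].to_numpy(float),
        )


def vo2_10s_average_at(gas: GasExchangeSeries, t: float, window_s: float = 10.0) -> float:
    """Mean breath-by-breath VO2 within a centered 10-s window around ``t``."""
    mask = (gas.times >= t - window_s / 2) & (gas.times <= t + window_s / 2)
    if not mask.any():
        i = int(np.argmin(np.abs(gas.times - t)))
        return float(gas.vo2[i])
    return float(np.mean(gas.vo2[mask]))


@dataclass(frozen=True)
class BreakpointFit:
    """Continuous two-segment least-squares fit and its single-line baseline."""

    breakpoint_time: float
    slope_before: float
    slope_after: float
    value_at_break: float
    sse_two_segment: float
    sse_single_line: float
    ss_total: float = 0.0  # variance around the mean, for degeneracy guards

    @property
    def improvement_ratio(self) -> float:
        # a single line that already explains essentially all variance leaves
        # only numerical noise in both SSEs; the ratio is then meaningless
        if self.sse_single_line <= 1e-12 * max(self.ss_total, 1e-300):
            return 0.0
        return 1.0 - self.sse_two_segment / self.sse_single_line


def fit_two_segment(times, values, end_margin_samples: int = 3) -> BreakpointFit:
    """Exhaustive continuous two-segment fit over candidate breakpoints.

    Every sample (excluding ``end_margin_samples`` at each end) is tried as
    the breakpoint of a hinge model ``a + b*(t-tb) + c*max(t-tb, 0)``; the
    candidate minimizing the SSE wins, ties broken toward the earliest time.
    The hinge parameterization makes the two segments share their value at
    the breakpoint, so the fitted trace is continuous.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size or t.size < 8:
        raise ValueError("need at least 8 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    # single-line baseline
    A1 = np.column_stack([np.ones_like(t), t])
    coef1, *_ = np.linalg.lstsq(A1, y, rcond=None)
    sse1 = float(np.sum((y - A1 @ coef1) ** 2))

    m = max(1, int(end_margin_samples))
    best = None
    ones = np.ones_like(t)
    for j in range(m, t.size - m):
        tb = t[j]
        dt = t - tb
        A = np.column_stack([ones, dt, np.maximum(dt, 0.0)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse = float(np.sum((y - A @ coef) ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, tb, coef)
    sse2, tb, coef = best
    a, b, c = coef
    return BreakpointFit(
        breakpoint_time=float(tb),
        slope_before=float(b),
        slope_after=float(b + c),
        value_at_break=float(a),
        sse_two_segment=min(sse2, sse1),
        sse_single_line=sse1,
        ss_total=float(np.sum((y - y.mean()) ** 2)),
    )


@dataclass(frozen=True)
class ATDetectionParams:
    """Validity rules for declaring an acoustic breakpoint a detected AT.

    ``fit_tail_trim_s`` excludes the last seconds of the exercise phase from
    the fit: around test termination the subject settles into the final
    steady state, which flattens the trace and would otherwise drag the
    fitted breakpoint early.
    """

    improvement_threshold: float = 0.2
    end_margin_s: float = 60.0
    fit_tail_trim_s: float = 15.0
    smooth_breaths: int = 5  # recorded for provenance; smoothing applied upstream


@dataclass(frozen=True)
class ATDetection:
    detected: bool
    time_s: float | None
    stage: int | None
    workload_w: float | None
    feature: str
    fit: BreakpointFit | None

    def as_dict(self) -> dict:
        return {
            "detected": self.detected,
            "time_s": self.time_s,
            "stage": self.stage,
            "workload_w": self.workload_w,
            "feature": self.feature,
            "improvement_ratio": self.fit.improvement_ratio if self.fit else None,
        }


def detect_at_acoustic(
    series: FeatureSeries,
    feature: str,
    protocol: ProtocolSpec,
    params: ATDetectionParams | None = None,
) -> ATDetection:
    """Acoustic AT: breakpoint of the chosen feature over the exercise phase.

    A detection is valid only if (a) the two-segment fit improves on a single
    line by at least the improvement threshold, (b) the slope increases at
    the breakpoint (ventilation accelerates at AT, never the reverse), and
    (c) the breakpoint is not within the end margins of the exercise phase.
    """
    params = params or ATDetectionParams()
    y_all = series.channel(feature)
    mask = (
        (series.times >= protocol.exercise_start_s)
        & (series.times < protocol.exercise_end_s - params.fit_tail_trim_s)
        & ~series.missing
        & np.isfinite(y_all)
    )
    t = series.times[mask]
    y = y_all[mask]
    if t.size < 8:
        return ATDetection(False, None, None, None, feature, None)
    fit = fit_two_segment(t, y)
    valid = (
        fit.improvement_ratio >= params.improvement_threshold
        and fit.slope_after > fit.slope_before
        and (fit.breakpoint_time - t[0]) >= params.end_margin_s
        and (t[-1] - fit.breakpoint_time) >= params.end_margin_s
    )
    if not valid:
        return ATDetection(False, None, None, None, feature, fit)
    stage, load = protocol.stage_at_time(fit.breakpoint_time)
    return ATDetection(True, fit.breakpoint_time, stage, load, feature, fit)


@dataclass(frozen=True)
class ReferenceAT:
    determined: bool
    time_s: float | None
    stage: int | None
    workload_w: float | None
    vo2_at_at: float | None  # mL/kg/min when mass supplied, else mL/min


def _local_slope(times, values, t, half_window_s=15.0):
    mask = (times >= t - half_window_s) & (times <= t + half_window_s)
    if mask.sum() < 3:
        return 0.0
    return float(np.polyfit(times[mask], values[mask], 1)[0])


def reference_at_ventilatory(
    gas: GasExchangeSeries,
    protocol: ProtocolSpec,
    mass_kg: float | None = None,
    smooth_breaths: int = 15,
    slope_tol: float = 1e-3,
    refine_window_s: float = 120.0,
    snap_breaths: int = 3,
) -> ReferenceAT:
    """Reference AT from the nadir of VE/VO2 over the exercise phase.

    VE/VO2 is median-smoothed over ``smooth_breaths``; its global minimum is
    accepted if VE/VCO2 is still flat or decreasing there.  The coarse nadir
    is then localized precisely by a continuous two-segment (V-shape) fit of
    the raw ratio within ``refine_window_s`` around it - pooling every
    breath in the window beats picking a single noisy minimum sample - and
    finally snapped to the raw-sample minimum within ``snap_breaths``
    breaths of the fitted vertex, so the noise-free nadir is recovered
    exactly at breath resolution.  A nadir on the phase boundary is
    rejected; if no interior minimum passes the VE/VCO2 check the reference
    is returned undetermined.
    """
    mask = (gas.times >= protocol.exercise_start_s) & (gas.times < protocol.exercise_end_s)
    t = gas.times[mask]
    ratio = gas.ve_vo2[mask]
    ratio_co2 = gas.ve_vco2[mask]
    if t.size < max(5, smooth_breaths):
        return ReferenceAT(False, None, None, None, None)
    k = max(1, int(smooth_breaths))
    smoothed = pd.Series(ratio).rolling(k, center=True, min_periods=1).median().to_numpy()
    smoothed_co2 = pd.Series(ratio_co2).rolling(k, center=True, min_periods=1).median().to_numpy()

    order = np.argsort(smoothed, kind="stable")
    candidates = [int(order[0])]
    # fallback pool: interior local minima of the smoothed trace, earliest first
    interior = np.arange(1, t.size - 1)
    local_min = interior[
        (smoothed[interior] <= smoothed[interior - 1])
        & (smoothed[interior] <= smoothed[interior + 1])
    ]
    candidates += [int(i) for i in local_min if int(i) != candidates[0]]

    for idx in candidates:
        if idx == 0 or idx == t.size - 1:
            continue  # boundary nadir: AT was not crossed inside the phase
        if _local_slope(t, smoothed_co2, t[idx]) > slope_tol:
            continue
        t_vertex = t[idx]
        win = (t >= t_vertex - refine_window_s) & (t <= t_vertex + refine_window_s)
        if win.sum() >= 8:
            vfit = fit_two_segment(t[win], ratio[win])
            if vfit.slope_before < 0 < vfit.slope_after:
                t_vertex = vfit.breakpoint_time
        j = int(np.argmin(np.abs(t - t_vertex)))
        lo, hi = max(0, j - snap_breaths), min(t.size, j + snap_breaths + 1)
        idx_raw = lo + int(np.argmin(ratio[lo:hi]))
        at_time = float(t[idx_raw])
        stage, load = protocol.stage_at_time(at_time)
        vo2 = vo2_10s_average_at(gas, at_time)
        if mass_kg:
            vo2 = vo2 / mass_kg
        return ReferenceAT(True, at_time, stage, load, vo2)
    return ReferenceAT(False, None, None, None, None)


def vslope_at(gas: GasExchangeSeries, protocol: ProtocolSpec) -> BreakpointFit:
    """Optional V-slope cross-check: breakpoint of VCO2 against VO2.

    Uses the same two-segment fit, on the exercise-phase breaths ordered by
    VO2.  Returned as a raw fit (the breakpoint abscissa is a VO2 value, not
    a time); intended as a diagnostic companion to the ventilatory-
    equivalents reference, not a replacement.
    """
    mask = (gas.times >= protocol.exercise_start_s) & (gas.times < protocol.exercise_end_s)
    vo2 = gas.vo2[mask]
    vco2 = gas.vco2[mask]
    order = np.argsort(vo2)
    vo2_sorted = vo2[order]
    # strictly increasing abscissa required by the fitter
    keep = np.concatenate(([True], np.diff(vo2_sorted) > 0))
    return fit_two_segment(vo2_sorted[keep], vco2[order][keep])


@dataclass(frozen=True)
class ATAgreement:
    """Agreement between the acoustic estimate and the ventilatory reference."""

    detected: bool
    same_stage: bool
    time_diff_s: float | None  # estimate - reference; None if undetected
    within_20s: bool
    vo2_rel_error: float | None

    def as_dict(self) -> dict:
        return {
            "detected": self.detected,
            "same_stage": self.same_stage,
            "time_diff_s": self.time_diff_s,
            "within_20s": self.within_20s,
            "vo2_rel_error": self.vo2_rel_error,
        }


def evaluate_at_agreement(
    est: ATDetection,
    ref: ReferenceAT,
    gas: GasExchangeSeries,
    protocol: ProtocolSpec,
    tolerance_s: float = 20.0,
) -> ATAgreement:
    """Same-stage flag, signed time difference, within-20-s flag, VO2 error."""
    if not ref.determined:
        raise ValueError("reference AT is undetermined")
    if not est.detected:
        return ATAgreement(False, False, None, False, None)
    diff = est.time_s - ref.time_s
    vo2_ref = vo2_10s_average_at(gas, ref.time_s)
    vo2_est = vo2_10s_average_at(gas, est.time_s)
    return ATAgreement(
        detected=True,
        same_stage=(est.stage == ref.stage),
        time_diff_s=float(diff),
        within_20s=bool(abs(diff) <= tolerance_s),
        vo2_rel_error=float(abs(vo2_est - vo2_ref) / vo2_ref),
    )
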