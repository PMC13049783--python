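"""Anaerobic-threshold detection: breakpoint fit, reference nadir, agreement."""

import dataclasses

import numpy as np
import pytest

import cpet_acoustics as ca
from cpet_acoustics.at import (
    ATDetection,
    ATDetectionParams,
    GasExchangeSeries,
    evaluate_at_agreement,
    fit_two_segment,
    detect_at_acoustic,
    reference_at_ventilatory,
    vslope_at,
)
from cpet_acoustics.features import FeatureSeries
from cpet_acoustics.protocol import ProtocolSpec


def piecewise(times, knee, s1, s2, y0=1.0):
    t = np.asarray(times, dtype=float)
    return y0 + np.where(t < knee, s1 * (t - t[0]), s1 * (knee - t[0]) + s2 * (t - knee))


def brute_force_fit(times, values, margin=3):
    """Independent oracle: per-candidate constrained two-line closed form."""
    t, y = np.asarray(times, float), np.asarray(values, float)
    best = None
    for j in range(margin, t.size - margin):
        dt = t - t[j]
        A = np.column_stack([np.ones_like(dt), dt, np.where(dt > 0, dt, 0.0)])
        coef = np.linalg.pinv(A) @ y
        sse = float(np.sum((y - A @ coef) ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, t[j])
    return best[1]


def make_series(times, values, protocol):
    n = times.size
    return FeatureSeries(
        times=times,
        energy=values.copy(),
        intensity=values.copy(),
        rr=np.full(n, 20.0),
        acoustic_ventilation=20.0 * values,
        stage=np.array([protocol.stage_at_time(t)[0] for t in times]),
        missing=np.zeros(n, dtype=bool),
    )


class TestFitTwoSegment:
    def test_noiseless_knee_recovered_exactly(self):
        t = np.arange(180.0, 700.0, 10.0)
        y = piecewise(t, 340.0, 0.01, 0.05)
        fit = fit_two_segment(t, y)
        assert fit.breakpoint_time == 340.0
        assert fit.sse_two_segment < 1e-16
        assert fit.slope_before == pytest.approx(0.01, abs=1e-9)
        assert fit.slope_after == pytest.approx(0.05, abs=1e-9)

    def test_single_line_has_no_improvement(self):
        t = np.arange(0.0, 100.0, 2.0)
        fit = fit_two_segment(t, 3.0 + 0.2 * t)
        assert fit.improvement_ratio < 0.05

    def test_noisy_knee_within_20s_and_matches_brute_force(self):
        rng = np.random.default_rng(42)
        t = np.arange(180.0, 700.0, 1.0)
        y = piecewise(t, 340.0, 0.01, 0.05)
        y = y + 0.1 * np.ptp(y) * rng.standard_normal(t.size)
        fit = fit_two_segment(t, y)
        assert abs(fit.breakpoint_time - 340.0) <= 20.0
        assert fit.breakpoint_time == brute_force_fit(t, y)

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        t = np.cumsum(rng.uniform(0.5, 2.0, n)) + 100.0
        y = piecewise(t, t[n // 2], 0.02, 0.07) + 0.05 * rng.standard_normal(n)
        fit = fit_two_segment(t, y)
        assert fit.breakpoint_time == brute_force_fit(t, y)

    def test_sse_invariants(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 60.0, 1.0)
        y = rng.standard_normal(t.size)
        fit = fit_two_segment(t, y)
        assert fit.sse_two_segment <= fit.sse_single_line
        assert t[3] <= fit.breakpoint_time <= t[-4]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="8 samples"):
            fit_two_segment(np.arange(5.0), np.arange(5.0))


class TestDetectAcoustic:
    protocol = ProtocolSpec(warmup_s=180.0, stage_s=120.0, increment_w=25.0, n_stages=4)

    def grid(self):
        return np.arange(0.0, self.protocol.end_s - 1.0, 1.0)

    def test_programmed_knee_detected_at_right_stage(self):
        t = self.grid()
        y = piecewise(t, 430.0, 0.002, 0.008, y0=1.0)
        det = detect_at_acoustic(make_series(t, y, self.protocol), "intensity", self.protocol)
        assert det.detected
        assert abs(det.time_s - 430.0) <= 5.0
        assert det.stage == 3
        assert det.workload_w == 75.0

    def test_straight_line_is_not_a_detection(self):
        t = self.grid()
        det = detect_at_acoustic(
            make_series(t, 1.0 + 0.004 * t, self.protocol), "intensity", self.protocol
        )
        assert not det.detected

    def test_decelerating_trace_is_not_a_detection(self):
        t = self.grid()
        y = piecewise(t, 430.0, 0.008, 0.002)
        det = detect_at_acoustic(make_series(t, y, self.protocol), "intensity", self.protocol)
        assert not det.detected

    def test_knee_inside_end_margin_rejected(self):
        t = self.grid()
        y = piecewise(t, 215.0, 0.001, 0.009)
        det = detect_at_acoustic(make_series(t, y, self.protocol), "intensity", self.protocol)
        assert not det.detected

    def test_detection_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(11)
        t = self.grid()
        y = piecewise(t, 470.0, 0.002, 0.009) + 0.01 * rng.standard_normal(t.size)
        d1 = detect_at_acoustic(make_series(t, y, self.protocol), "intensity", self.protocol)
        d2 = detect_at_acoustic(
            make_series(t, 7.5 * y + 3.0, self.protocol), "intensity", self.protocol
        )
        assert d1.detected and d2.detected
        assert d1.time_s == d2.time_s
        assert d1.stage == d2.stage

    def test_simulator_subject_detected_within_20s(self, default_record):
        _, _, series = ca.process_record(default_record)
        det = detect_at_acoustic(series, "intensity", default_record.protocol)
        assert det.detected
        assert abs(det.time_s - default_record.subject.at_time_s) <= 20.0

    def test_unknown_feature_rejected(self):
        t = self.grid()
        series = make_series(t, 1.0 + 0.004 * t, self.protocol)
        with pytest.raises(KeyError):
            detect_at_acoustic(series, "loudness", self.protocol)


class TestReference:
    def test_constructed_nadir_at_340s(self):
        # VE/VO2 with a unique minimum at 340 s, VE/VCO2 still decreasing
        protocol = ProtocolSpec(warmup_s=180.0, stage_s=120.0, increment_w=25.0, n_stages=3)
        t = np.arange(185.0, protocol.exercise_end_s, 2.5)
        vo2 = 600.0 + 2.4 * (t - 180.0)
        vco2 = np.where(t < 340.0, 0.85 * vo2, 0.85 * (600 + 2.4 * 160) + 1.3 * (vo2 - (600 + 2.4 * 160)))
        ve = 0.025 * vco2 + 5.0
        gas = GasExchangeSeries(
            times=t, vo2=vo2, vco2=vco2, ve=ve, vt=ve / 20.0, hr_times=t, hr=np.full(t.size, 120.0)
        )
        ref = reference_at_ventilatory(gas, protocol, mass_kg=70.0)
        assert ref.determined
        assert abs(ref.time_s - 340.0) <= 2.5  # breath resolution

    def test_boundary_nadir_rejected(self):
        protocol = ProtocolSpec(warmup_s=180.0, stage_s=120.0, increment_w=25.0, n_stages=3)
        t = np.arange(185.0, protocol.exercise_end_s, 2.5)
        vo2 = 600.0 + 2.4 * (t - 180.0)
        ve = 30.0 - 0.02 * (t - 180.0)  # strictly decreasing ratio
        gas = GasExchangeSeries(
            times=t, vo2=vo2, vco2=0.85 * vo2, ve=ve, vt=ve / 20.0, hr_times=t, hr=np.full(t.size, 120.0)
        )
        ref = reference_at_ventilatory(gas, protocol, mass_kg=70.0)
        assert not ref.determined

    def test_simulator_reference_within_10s_of_truth(self, default_record):
        rec = default_record
        ref = reference_at_ventilatory(rec.gas, rec.protocol, mass_kg=rec.subject.profile.weight_kg)
        assert ref.determined
        assert abs(ref.time_s - rec.subject.at_time_s) <= 10.0

    def test_noiseless_reference_exact(self, noiseless_record):
        rec = noiseless_record
        ref = reference_at_ventilatory(rec.gas, rec.protocol, mass_kg=rec.subject.profile.weight_kg)
        assert ref.determined
        assert ref.time_s == pytest.approx(rec.subject.at_time_s, abs=1e-9)

    def test_vslope_crosscheck_close_to_programmed_vo2_at_threshold(self, noiseless_record):
        rec = noiseless_record
        fit = vslope_at(rec.gas, rec.protocol)
        assert fit.slope_after > fit.slope_before
        vo2_at_truth = rec.physiology.vo2_at
        assert abs(fit.breakpoint_time - vo2_at_truth) / vo2_at_truth < 0.05


class TestAgreement:
    protocol = ProtocolSpec(warmup_s=180.0, stage_s=120.0, increment_w=25.0, n_stages=4)

    def _gas(self):
        t = np.arange(0.0, self.protocol.end_s - 1, 2.0)
        vo2 = 600 + 2.0 * t
        return GasExchangeSeries(
            times=t, vo2=vo2, vco2=0.9 * vo2, ve=0.025 * vo2, vt=np.full(t.size, 1.0),
            hr_times=t, hr=np.full(t.size, 130.0),
        )

    def _ref(self, time):
        from cpet_acoustics.at import ReferenceAT

        stage, load = self.protocol.stage_at_time(time)
        return ReferenceAT(True, time, stage, load, 20.0)

    def _det(self, time):
        stage, load = self.protocol.stage_at_time(time)
        return ATDetection(True, time, stage, load, "intensity", None)

    def test_same_stage_within_20s(self):
        agr = evaluate_at_agreement(self._det(350.0), self._ref(340.0), self._gas(), self.protocol)
        assert agr.same_stage
        assert agr.time_diff_s == pytest.approx(10.0)
        assert agr.within_20s

    def test_40s_difference_fails_20s_rule(self):
        agr = evaluate_at_agreement(self._det(380.0), self._ref(340.0), self._gas(), self.protocol)
        assert agr.time_diff_s == pytest.approx(40.0)
        assert not agr.within_20s

    def test_undetected_estimate_flagged(self):
        undet = ATDetection(False, None, None, None, "intensity", None)
        agr = evaluate_at_agreement(undet, self._ref(340.0), self._gas(), self.protocol)
        assert not agr.detected
        assert not agr.same_stage
        assert agr.time_diff_s is None

    def test_vo2_relative_error_uses_10s_averages(self):
        agr = evaluate_at_agreement(self._det(360.0), self._ref(340.0), self._gas(), self.protocol)
        vo2_ref = 600 + 2.0 * 340
        vo2_est = 600 + 2.0 * 360
        assert agr.vo2_rel_error == pytest.approx(abs(vo2_est - vo2_ref) / vo2_ref, rel=1e-6)
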