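"""Synthetic CPET generator: ground-truth physiology plus matching audio.

The generator encodes the physiological relationships that make acoustic AT
detection possible in the first place:

* VO2 rises linearly with the stepped workload to the subject's peak (with a
  short steady-state plateau at the end of the last stage);
* VCO2 follows VO2 with a steeper slope above the anaerobic threshold
  (buffering of lactic acid produces excess CO2);
* minute ventilation is proportional to VCO2 plus a dead-space offset, which
  yields the classic VE/VO2 nadir exactly at the AT while VE/VCO2 is still
  decreasing;
* heart rate ramps to 85% of (220 - age) at the end of exercise (the
  submaximal termination criterion);
* tracheal sound bursts (one inspiratory, one expiratory per breath) carry
  acoustic power proportional to instantaneous VE - the linear
  intensity-airflow coupling that makes the ventilatory breakpoint appear in
  the sound - so burst amplitude goes as the square root of VE; stationary
  ambient noise is added at a configured segmental SNR plus sparse
  high-amplitude motion spikes.

Breath-by-breath variability of the gas-exchange channels is modeled as a
multiplicative breath-size factor shared by VO2, VCO2 and VE (gas volumes
scale together with breath size, so the derived ventilatory equivalents
stay comparatively clean, as they do on real metabolic carts); an optional
independent per-channel sensor noise (off by default) is available as a
robustness stress knob.  Audio noise enters through the ambient SNR and
the motion spikes.  All draws are reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .at import GasExchangeSeries
from .audio import AudioRecording
from .features import FeatureSeries
from .protocol import ProtocolSpec, SubjectProfile, build_protocol, predicted_hr_max

# physiology constants of the generator
AEROBIC_EFFICIENCY = 10.0  # mL/min of VO2 per Watt - tight across humans
RQ_BELOW_AT = 0.85        # VCO2/VO2 slope below threshold
SLOPE_ABOVE_AT = 1.25     # VCO2 gain per VO2 above threshold (excess CO2)
VE_PER_VCO2 = 0.025       # L/min of VE per mL/min of VCO2
VE_DEADSPACE = 5.0        # L/min ventilation offset (dead space)
PLATEAU_S = 15.0          # steady-state plateau at the end of the last stage
HR_REST = 90.0            # beats/min at test start
INSP_FRAC = 0.35          # inspiratory burst fraction of the breath period
EXP_START_FRAC = 0.45
EXP_END_FRAC = 0.75
EXP_REL_AMP = 0.8
SPIKE_DURATION_S = 0.03


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generator settings (defaults are the study conditions)."""

    n_subjects: int = 24
    seed: int = 0
    snr_db: float = 10.0          # segmental SNR of ambient noise
    breath_cv: float = 0.05       # CV of the shared breath-size factor
    channel_cv: float = 0.0       # extra per-channel sensor noise (stress knob)
    spike_rate_per_min: float = 2.0
    audio_rate: float = 15277.0
    female_fraction: float = 0.75
    n_stages: int | None = None   # None: drawn per subject (4-6)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("cohort size must be >= 1")


@dataclass(frozen=True)
class SyntheticSubject:
    """Ground-truth physiology of one simulated participant."""

    profile: SubjectProfile
    n_stages: int
    at_time_s: float              # true anaerobic threshold on the protocol clock
    vo2peak_ml_kg_min: float
    rr_start: float               # breaths/min at warmup
    rr_end: float                 # breaths/min at end of exercise
    amp_coupling: float           # sound amplitude per sqrt(L/min) of VE
    snr_db: float
    breath_cv: float
    channel_cv: float
    spike_rate_per_min: float
    audio_rate: float
    seed: int

    def __post_init__(self) -> None:
        if not (15.0 <= self.vo2peak_ml_kg_min <= 60.0):
            raise ValueError("VO2peak outside the physiologic 15-60 mL/kg/min band")
        if self.rr_end <= self.rr_start:
            raise ValueError("respiratory rate must rise across the test")

    def as_dict(self) -> dict:
        return {
            "age": self.profile.age,
            "sex": self.profile.sex,
            "height_cm": self.profile.height_cm,
            "weight_kg": self.profile.weight_kg,
            "n_stages": self.n_stages,
            "at_time_s": self.at_time_s,
            "vo2peak_ml_kg_min": self.vo2peak_ml_kg_min,
            "rr_start": self.rr_start,
            "rr_end": self.rr_end,
            "amp_coupling": self.amp_coupling,
            "snr_db": self.snr_db,
            "seed": self.seed,
        }


class SubjectPhysiology:
    """Noise-free physiological trajectories of a subject on its protocol."""

    def __init__(self, subject: SyntheticSubject, protocol: ProtocolSpec):
        self.subject = subject
        self.protocol = protocol
        wt = subject.profile.weight_kg
        self.vo2_base = 150.0 + 6.0 * wt
        self.vo2_peak_abs = subject.vo2peak_ml_kg_min * wt
        self.ramp_end = protocol.exercise_end_s - PLATEAU_S
        if not (protocol.exercise_start_s < subject.at_time_s < self.ramp_end):
            raise ValueError("AT time must lie inside the exercise ramp")
        self.vo2_at = self.vo2(np.array([subject.at_time_s]))[0]

    def vo2(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        p = self.protocol
        ws, re_, ee = p.exercise_start_s, self.ramp_end, p.exercise_end_s
        frac = np.clip((t - ws) / (re_ - ws), 0.0, 1.0)
        out = self.vo2_base + frac * (self.vo2_peak_abs - self.vo2_base)
        rec = t >= ee
        if np.any(rec):
            rec_frac = np.clip((t[rec] - ee) / p.recovery_s, 0.0, 1.0)
            out[rec] = self.vo2_peak_abs + rec_frac * (self.vo2_base - self.vo2_peak_abs)
        return out

    def vco2(self, t) -> np.ndarray:
        v = self.vo2(t)
        below = RQ_BELOW_AT * v
        above = RQ_BELOW_AT * self.vo2_at + SLOPE_ABOVE_AT * (v - self.vo2_at)
        past_at = np.atleast_1d(np.asarray(t, dtype=float)) >= self.subject.at_time_s
        return np.where(past_at & (v > self.vo2_at), above, below)

    def ve(self, t) -> np.ndarray:
        return VE_PER_VCO2 * self.vco2(t) + VE_DEADSPACE

    def hr(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        p = self.protocol
        hr_end = 0.85 * predicted_hr_max(self.subject.profile)
        frac = np.clip(t / p.exercise_end_s, 0.0, 1.0)
        out = HR_REST + frac * (hr_end - HR_REST)
        rec = t >= p.exercise_end_s
        if np.any(rec):
            rec_frac = np.clip((t[rec] - p.exercise_end_s) / p.recovery_s, 0.0, 1.0)
            out[rec] = hr_end - 25.0 * rec_frac
        return out

    def rr(self, t) -> np.ndarray:
        """Programmed instantaneous respiratory rate (breaths/min)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        s = self.subject
        p = self.protocol
        frac = np.clip(
            (t - p.exercise_start_s) / (p.exercise_end_s - p.exercise_start_s), 0.0, 1.0
        )
        out = s.rr_start + frac * (s.rr_end - s.rr_start)
        rec = t >= p.exercise_end_s
        if np.any(rec):
            rec_frac = np.clip((t[rec] - p.exercise_end_s) / p.recovery_s, 0.0, 1.0)
            out[rec] = s.rr_end + rec_frac * (s.rr_start - s.rr_end)
        return out

    def breath_times(self) -> np.ndarray:
        """Deterministic breath onsets from the rate trajectory.

        The breath nearest the true AT is snapped onto it so the threshold is
        identifiable at breath resolution in the noise-free limit.
        """
        p = self.protocol
        times = []
        t = 30.0 / float(self.rr(0.0)[0])
        while t < p.end_s:
            times.append(t)
            t += 60.0 / float(self.rr(t)[0])
        times = np.asarray(times)
        i = int(np.argmin(np.abs(times - self.subject.at_time_s)))
        times[i] = self.subject.at_time_s
        return np.sort(times)


def _breath_size_factors(subject: SyntheticSubject, n: int) -> np.ndarray:
    """Shared per-breath lognormal size factors (same stream for gas and audio)."""
    if subject.breath_cv <= 0:
        return np.ones(n)
    rng = np.random.default_rng([subject.seed, 10])
    sigma = np.sqrt(np.log1p(subject.breath_cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=n)


def _channel_noise(rng, cv: float, n: int) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=n)


def simulate_subject(cfg: SimulationConfig, seed: int) -> SyntheticSubject:
    """Draw one subject whose demographics match the cohort moments."""
    rng = np.random.default_rng(seed)
    age = float(np.clip(rng.normal(31.0, 9.1), 18.0, 65.0))
    sex = "F" if rng.random() < cfg.female_fraction else "M"
    height = float(rng.normal(164.0, 6.0) if sex == "F" else rng.normal(177.0, 7.0))
    bmi = float(np.clip(rng.normal(23.5, 3.3), 18.0, 32.0))
    weight = bmi * (height / 100.0) ** 2
    profile = SubjectProfile(age=age, sex=sex, height_cm=height, weight_kg=weight)
    vo2peak = float(np.clip(rng.normal(27.1, 6.7), 15.0, 60.0))
    if cfg.n_stages is not None:
        n_stages = int(cfg.n_stages)
    else:
        # stage count follows from the universal ~10 mL/min/W aerobic
        # efficiency: the subject tops out when the stepped workload demands
        # their VO2peak, which also ties workload and HR to VO2 across
        # subjects the way real incremental tests do.  Clipped to 4-6 stages
        # (8-12 min of incremental exercise), the duration the Wasserman
        # increment individualization is designed to produce.
        from .protocol import workload_increment

        inc = workload_increment(profile)
        vo2_reserve = vo2peak * weight - (150.0 + 6.0 * weight)
        n_stages = int(np.clip(round(vo2_reserve / (AEROBIC_EFFICIENCY * inc)), 4, 6))
    at_frac = float(rng.uniform(0.45, 0.70))
    at_time = 180.0 + at_frac * n_stages * 120.0
    rr_start = float(rng.uniform(12.0, 16.0))
    rr_end = float(rng.uniform(28.0, 35.0))

    # acoustic power ~ VE (the linear intensity-airflow law), so amplitude
    # ~ sqrt(VE); the coupling is scaled so the peak burst ENVELOPE lands in
    # (0.12, 0.24) - the noise carrier has a crest factor near 4, so this
    # keeps sample peaks inside [-1, 1] (no saturation distortion) while
    # giving realistic between-subject coupling variation.
    vo2_base = 150.0 + 6.0 * weight
    vo2_peak_abs = vo2peak * weight
    vo2_at = vo2_base + at_frac * (vo2_peak_abs - vo2_base)  # approx: frac of ramp
    vco2_peak = RQ_BELOW_AT * vo2_at + SLOPE_ABOVE_AT * (vo2_peak_abs - vo2_at)
    ve_peak = VE_PER_VCO2 * vco2_peak + VE_DEADSPACE
    # +/-15% between-subject coupling spread: subject-independent VO2
    # regression from acoustic features alone only works when intensity
    # scales are comparable across subjects, which is the regime real
    # same-device suprasternal recordings sit in.
    amp_peak = 0.18 * (1.0 + float(rng.uniform(-0.15, 0.15)))
    amp_coupling = amp_peak / np.sqrt(ve_peak)
    return SyntheticSubject(
        profile=profile,
        n_stages=n_stages,
        at_time_s=at_time,
        vo2peak_ml_kg_min=vo2peak,
        rr_start=rr_start,
        rr_end=rr_end,
        amp_coupling=amp_coupling,
        snr_db=cfg.snr_db,
        breath_cv=cfg.breath_cv,
        channel_cv=cfg.channel_cv,
        spike_rate_per_min=cfg.spike_rate_per_min,
        audio_rate=cfg.audio_rate,
        seed=int(seed),
    )


def subject_protocol(subject: SyntheticSubject) -> ProtocolSpec:
    return build_protocol(subject.profile, n_stages=subject.n_stages)


def simulate_gas_exchange(
    subject: SyntheticSubject, protocol: ProtocolSpec
) -> GasExchangeSeries:
    """Breath-by-breath gas exchange with the programmed AT structure."""
    phys = SubjectPhysiology(subject, protocol)
    t = phys.breath_times()
    size = _breath_size_factors(subject, t.size)
    rng = np.random.default_rng([subject.seed, 11])
    vo2 = phys.vo2(t) * size * _channel_noise(rng, subject.channel_cv, t.size)
    vco2 = phys.vco2(t) * size * _channel_noise(rng, subject.channel_cv, t.size)
    ve = phys.ve(t) * size * _channel_noise(rng, subject.channel_cv, t.size)
    rr_inst = phys.rr(t)
    vt = ve / rr_inst
    hr_times = np.arange(0.0, protocol.end_s, 1.0)
    hr = phys.hr(hr_times)
    if subject.channel_cv > 0:
        hr = hr + rng.normal(0.0, 50.0 * subject.channel_cv, hr_times.size)
    return GasExchangeSeries(
        times=t, vo2=vo2, vco2=vco2, ve=ve, vt=vt, hr_times=hr_times, hr=hr
    )


def _burst_envelope(n: int, rate: float, breath_times, periods, amps) -> np.ndarray:
    env = np.zeros(n)
    for t0, period, amp in zip(breath_times, periods, amps):
        for f0, f1, a in (
            (0.0, INSP_FRAC, amp),
            (EXP_START_FRAC, EXP_END_FRAC, EXP_REL_AMP * amp),
        ):
            i0 = int(round((t0 + f0 * period) * rate))
            i1 = min(n, int(round((t0 + f1 * period) * rate)))
            if i1 - i0 < 8:
                continue
            env[i0:i1] = np.maximum(env[i0:i1], a * signal.windows.tukey(i1 - i0, 0.4))
    return env


def synthesize_audio(
    subject: SyntheticSubject,
    protocol: ProtocolSpec,
    return_parts: bool = False,
):
    """Tracheal-sound audio matching the subject's gas exchange.

    Each breath contributes an inspiratory and an expiratory burst of
    100-3000 Hz band-limited noise whose amplitude is
    ``amp_coupling * sqrt(VE(t))`` - acoustic power linear in airflow.
    Stationary white ambient noise is added at the
    configured segmental SNR (measured against the mean within-burst clean
    power), and sparse motion spikes at the configured rate.  Native sample
    rate defaults to the device's 15,277 Hz.
    """
    phys = SubjectPhysiology(subject, protocol)
    rate = subject.audio_rate
    n = int(round(protocol.end_s * rate))
    rng = np.random.default_rng([subject.seed, 12])

    sos = signal.butter(4, [100.0, 3000.0], btype="bandpass", fs=rate, output="sos")
    carrier = signal.sosfilt(sos, rng.standard_normal(n))
    carrier /= np.sqrt(np.mean(carrier**2))

    t_b = phys.breath_times()
    periods = np.diff(np.append(t_b, protocol.end_s))
    amps = subject.amp_coupling * np.sqrt(phys.ve(t_b))
    env = _burst_envelope(n, rate, t_b, periods, amps)
    clean = carrier * env

    active = env > 0
    p_clean = float(np.mean(clean[active] ** 2)) if active.any() else 0.0
    if np.isfinite(subject.snr_db) and p_clean > 0:
        sigma = np.sqrt(p_clean / 10.0 ** (subject.snr_db / 10.0))
    else:
        sigma = 0.0
    ambient = sigma * rng.standard_normal(n) if sigma > 0 else np.zeros(n)

    spikes = np.zeros(n)
    n_spikes = rng.poisson(subject.spike_rate_per_min * protocol.end_s / 60.0)
    spike_len = int(round(SPIKE_DURATION_S * rate))
    spike_amp = min(0.98, 4.0 * float(amps.max(initial=0.1)))
    for t_s in rng.uniform(0.0, protocol.end_s - SPIKE_DURATION_S, n_spikes):
        i0 = int(round(t_s * rate))
        pulse = signal.windows.tukey(spike_len, 0.8) * rng.standard_normal(spike_len)
        pulse *= spike_amp / max(np.abs(pulse).max(), 1e-12)
        spikes[i0 : i0 + spike_len] += pulse

    total = np.clip(clean + ambient + spikes, -1.0, 1.0)
    rec = AudioRecording(samples=total, rate=rate, t0=0.0)
    if return_parts:
        return rec, {"clean": clean, "ambient": ambient, "spikes": spikes}
    return rec


def segmental_snr(
    clean: np.ndarray, residual: np.ndarray, rate: float, frame_s: float = 0.25
) -> float:
    """Mean per-frame SNR (dB) of clean signal against a residual, over active frames."""
    win = max(1, int(round(frame_s * rate)))
    n = min(clean.size, residual.size) // win * win
    c = clean[:n].reshape(-1, win)
    r = residual[:n].reshape(-1, win)
    pc = np.mean(c**2, axis=1)
    pr = np.mean(r**2, axis=1)
    active = pc > 1e-3 * pc.max()
    if not active.any():
        raise ValueError("no active frames in the clean reference")
    return float(np.mean(10.0 * np.log10(pc[active] / np.maximum(pr[active], 1e-20))))


@dataclass(frozen=True)
class SubjectRecord:
    """One simulated participant: truth, protocol, gas exchange, audio."""

    subject: SyntheticSubject
    protocol: ProtocolSpec
    gas: GasExchangeSeries
    audio: AudioRecording | None = None
    physiology: SubjectPhysiology = field(default=None, compare=False)


def simulate_record(
    subject: SyntheticSubject, with_audio: bool = True
) -> SubjectRecord:
    protocol = subject_protocol(subject)
    gas = simulate_gas_exchange(subject, protocol)
    audio = synthesize_audio(subject, protocol) if with_audio else None
    return SubjectRecord(
        subject=subject,
        protocol=protocol,
        gas=gas,
        audio=audio,
        physiology=SubjectPhysiology(subject, protocol),
    )


def simulate_cohort(cfg: SimulationConfig, with_audio: bool = True) -> list[SubjectRecord]:
    """Independent subjects from one master seed (child seeds < 2**31)."""
    master = np.random.default_rng(cfg.seed)
    records = []
    for _ in range(cfg.n_subjects):
        child_seed = int(master.integers(2**31))
        subject = simulate_subject(cfg, child_seed)
        records.append(simulate_record(subject, with_audio=with_audio))
    return records


def simulate_feature_series(
    subject: SyntheticSubject,
    protocol: ProtocolSpec,
    grid_step_s: float = 1.0,
) -> FeatureSeries:
    """Programmed acoustic features directly from the generator's laws.

    A fast stand-in for the audio pipeline (intensity proportional to the
    squared breath amplitude, energy = intensity x breath duration, with a
    small multiplicative measurement noise standing in for the audio
    chain's residual error), used where an experiment needs many cohorts of
    feature traces and the audio stage itself is not under test.
    """
    phys = SubjectPhysiology(subject, protocol)
    grid = np.arange(0.0, protocol.end_s - 1e-9, grid_step_s)
    rng = np.random.default_rng([subject.seed, 13])
    noise = _channel_noise(rng, 0.02, grid.size)
    rr = phys.rr(grid)
    intensity = 0.5 * subject.amp_coupling**2 * phys.ve(grid) * noise
    energy = intensity * (60.0 / rr)
    stage = np.array([protocol.stage_at_time(t)[0] for t in grid], dtype=int)
    return FeatureSeries(
        times=grid,
        energy=energy,
        intensity=intensity,
        rr=rr,
        acoustic_ventilation=rr * intensity,
        stage=stage,
        missing=np.zeros(grid.size, dtype=bool),
    )
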