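"""Stepwise cycle-ergometer exercise protocol model.

The test is a submaximal incremental protocol: a 3-minute unloaded warmup,
2-minute exercise stages whose workload increases by a per-subject increment
derived from Wasserman's predicted-VO2 formulas (doubled, because the
classic ramp rate is stated per minute and the stages here last two), and a
2-minute active recovery.  Stage indexing is 1-based for exercise stages;
warmup is stage 0 and recovery is the sentinel ``RECOVERY_STAGE``.  All
stage intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import yaml

RECOVERY_STAGE = -1


@dataclass(frozen=True)
class SubjectProfile:
    """Demographics needed to individualize the protocol."""

    age: float          # years
    sex: str            # 'F' or 'M'
    height_cm: float
    weight_kg: float

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise ValueError("height and weight must be positive")
        if not (18 <= self.age <= 65):
            warnings.warn(
                f"age {self.age} outside the 18-65 y inclusion range",
                stacklevel=2,
            )


@dataclass(frozen=True)
class WassermanCoefficients:
    """Coefficients of the standard sedentary predicted-VO2 formulas.

    Unloaded VO2 (mL/min) = ``unloaded_intercept + unloaded_slope * weight``.
    Predicted peak VO2 (mL/min):

    * men:   ``weight * (male_a - male_b * age)``
    * women: ``(weight + female_w) * (female_a - female_b * age)``

    Every coefficient is exposed so an alternative parameterization can be
    dropped in without touching the protocol logic.
    """

    unloaded_intercept: float = 150.0
    unloaded_slope: float = 6.0
    male_a: float = 50.72
    male_b: float = 0.372
    female_w: float = 43.0
    female_a: float = 22.78
    female_b: float = 0.17

    def unloaded_vo2(self, profile: SubjectProfile) -> float:
        return self.unloaded_intercept + self.unloaded_slope * profile.weight_kg

    def predicted_peak_vo2(self, profile: SubjectProfile) -> float:
        if profile.sex == "M":
            return profile.weight_kg * (self.male_a - self.male_b * profile.age)
        return (profile.weight_kg + self.female_w) * (
            self.female_a - self.female_b * profile.age
        )


def predicted_hr_max(profile: SubjectProfile) -> float:
    """Age-predicted maximal heart rate, 220 minus age (beats/min)."""
    return 220.0 - profile.age


def hr_termination_threshold(profile: SubjectProfile, fraction: float = 0.85) -> float:
    """Submaximal termination threshold: 85% of predicted HRmax by default."""
    return fraction * predicted_hr_max(profile)


def workload_increment(
    profile: SubjectProfile,
    coefficients: WassermanCoefficients | None = None,
    round_to: float | None = 5.0,
) -> float:
    """Per-stage workload increment (W) for 2-minute stages.

    The Wasserman ramp rate is ``(predicted peak VO2 - unloaded VO2) / 100``
    watts per minute; with 2-minute stages the per-stage increment is twice
    that, optionally rounded to the nearest ``round_to`` watts.
    """
    coeffs = coefficients or WassermanCoefficients()
    per_minute = (coeffs.predicted_peak_vo2(profile) - coeffs.unloaded_vo2(profile)) / 100.0
    if per_minute <= 0:
        raise ValueError(
            f"non-positive Wasserman ramp rate ({per_minute:.2f} W/min) for {profile}"
        )
    increment = 2.0 * per_minute
    if round_to:
        increment = max(round_to, round(increment / round_to) * round_to)
    return increment


@dataclass(frozen=True)
class ProtocolSpec:
    """Realized protocol: warmup, exercise stages, recovery.

    ``boundaries`` lists ``(start_s, end_s, stage_index, workload_w)`` rows
    covering the whole test contiguously, warmup first (stage 0, baseline
    workload) and recovery last (sentinel stage).
    """

    warmup_s: float = 180.0
    stage_s: float = 120.0
    increment_w: float = 25.0
    n_stages: int = 5
    recovery_s: float = 120.0
    baseline_w: float = 0.0
    boundaries: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        rows = [(0.0, self.warmup_s, 0, self.baseline_w)]
        for k in range(1, self.n_stages + 1):
            start = self.warmup_s + (k - 1) * self.stage_s
            rows.append((start, start + self.stage_s, k, self.baseline_w + k * self.increment_w))
        rec_start = self.warmup_s + self.n_stages * self.stage_s
        rows.append((rec_start, rec_start + self.recovery_s, RECOVERY_STAGE, self.baseline_w))
        object.__setattr__(self, "boundaries", tuple(rows))

    @property
    def exercise_start_s(self) -> float:
        return self.warmup_s

    @property
    def exercise_end_s(self) -> float:
        return self.warmup_s + self.n_stages * self.stage_s

    @property
    def end_s(self) -> float:
        return self.exercise_end_s + self.recovery_s

    def stage_at_time(self, t: float) -> tuple[int, float]:
        """Stage index and workload at time ``t`` (half-open intervals)."""
        if not (0 <= t < self.end_s):
            raise ValueError(f"t={t} outside protocol span [0, {self.end_s})")
        for start, end, stage, load in self.boundaries:
            if start <= t < end:
                return stage, load
        raise AssertionError("unreachable: boundaries are contiguous")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "warmup_s": self.warmup_s,
                    "stage_s": self.stage_s,
                    "increment_w": self.increment_w,
                    "n_stages": self.n_stages,
                    "recovery_s": self.recovery_s,
                    "baseline_w": self.baseline_w,
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "ProtocolSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def build_protocol(
    profile: SubjectProfile,
    n_stages: int,
    warmup_s: float = 180.0,
    stage_s: float = 120.0,
    recovery_s: float = 120.0,
    increment_w: float | None = None,
    coefficients: WassermanCoefficients | None = None,
) -> ProtocolSpec:
    """Individualized protocol for a subject (increment from Wasserman unless given)."""
    if increment_w is None:
        increment_w = workload_increment(profile, coefficients)
    return ProtocolSpec(
        warmup_s=warmup_s,
        stage_s=stage_s,
        increment_w=increment_w,
        n_stages=n_stages,
        recovery_s=recovery_s,
    )


def stage_at_time(protocol: ProtocolSpec, t: float) -> tuple[int, float]:
    """Functional alias for :meth:`ProtocolSpec.stage_at_time`."""
    return protocol.stage_at_time(t)
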