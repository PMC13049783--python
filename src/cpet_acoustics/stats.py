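"""Agreement statistics: Bland-Altman, Pearson correlation, cohort summaries.

Bland-Altman limits of agreement use the sample (n-1) standard deviation and
a fixed 1.96 multiplier; both choices are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    n: int

    def as_dict(self) -> dict:
        return {
            "bias": self.bias,
            "sd": self.sd,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "n": self.n,
        }


def bland_altman(
    reference,
    estimate,
    ddof: int = 1,
    multiplier: float = 1.96,
) -> BlandAltmanResult:
    """Bland-Altman agreement between paired measurements.

    Differences are ``estimate - reference``; limits of agreement are
    ``bias -/+ multiplier * SD``.
    """
    x = np.asarray(reference, dtype=float)
    y = np.asarray(estimate, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("reference and estimate must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be pairwise finite")
    d = y - x
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=ddof)) if d.size > 1 else 0.0
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa_lower=bias - multiplier * sd,
        loa_upper=bias + multiplier * sd,
        n=int(d.size),
    )


def limits_from_moments(bias: float, sd: float, multiplier: float = 1.96) -> tuple[float, float]:
    """Limits of agreement recomputed from a stored bias/SD pair."""
    return bias - multiplier * sd, bias + multiplier * sd


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D arrays with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level AT agreement summary.

    ``within20_rate_all`` uses all subjects as the denominator;
    ``within20_rate_detected`` only subjects with a valid acoustic detection.
    Workload accuracy is the same-stage fraction among detected subjects.
    """

    n: int
    n_detected: int
    n_same_stage: int
    n_within_20s: int
    detection_rate: float
    workload_accuracy: float
    within20_rate_all: float
    within20_rate_detected: float

    def as_dict(self) -> dict:
        d = {
            "n": self.n,
            "n_detected": self.n_detected,
            "n_same_stage": self.n_same_stage,
            "n_within_20s": self.n_within_20s,
            "detection_rate": self.detection_rate,
            "workload_accuracy": self.workload_accuracy,
            "within20_rate_all": self.within20_rate_all,
            "within20_rate_detected": self.within20_rate_detected,
        }
        d["detection_rate_pct"] = round(100 * self.detection_rate, 2)
        d["workload_accuracy_pct"] = round(100 * self.workload_accuracy, 2)
        d["within20_rate_all_pct"] = round(100 * self.within20_rate_all, 2)
        d["within20_rate_detected_pct"] = round(100 * self.within20_rate_detected, 2)
        return d

    def markdown_table(self, label: str = "feature") -> str:
        return "\n".join(
            [
                f"| metric ({label}) | value |",
                "| --- | --- |",
                f"| Successful detection | {100 * self.detection_rate:.0f}% |",
                f"| Accuracy of workload | {100 * self.workload_accuracy:.0f}% |",
                f"| Time difference < 20 s | {100 * self.within20_rate_all:.2f}% |",
            ]
        )


def summarize_at_cohort(agreements) -> CohortSummary:
    """Summarize per-subject AT agreement records into cohort rates.

    ``agreements`` is an iterable of :class:`~cpet_acoustics.at.ATAgreement`.
    """
    agreements = list(agreements)
    if not agreements:
        raise ValueError("no agreement records")
    n = len(agreements)
    detected = [a for a in agreements if a.detected]
    n_det = len(detected)
    n_same = sum(1 for a in detected if a.same_stage)
    n_within = sum(1 for a in detected if a.within_20s)
    return CohortSummary(
        n=n,
        n_detected=n_det,
        n_same_stage=n_same,
        n_within_20s=n_within,
        detection_rate=n_det / n,
        workload_accuracy=(n_same / n_det) if n_det else 0.0,
        within20_rate_all=n_within / n,
        within20_rate_detected=(n_within / n_det) if n_det else 0.0,
    )
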