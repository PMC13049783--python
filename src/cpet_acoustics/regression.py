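"""VO2 and VO2peak estimation from acoustic features.

Two validation schemes mirror how a wearable would be deployed:

* **subject-specific**: each subject's own time series is split into five
  contiguous blocks; each block is predicted by a model trained on the other
  four (contiguous blocks rather than random rows, so temporal
  autocorrelation cannot leak across the split);
* **subject-independent**: leave-one-subject-out - each subject's whole
  trace is predicted by a model trained on everyone else.

Predicted VO2peak is the maximum of the predicted trace; the reference is
the peak 10-s-averaged measured VO2.  Backends: random-forest regression
and ordinary least squares, both mass-normalized (mL/kg/min).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .at import GasExchangeSeries
from .features import FeatureSeries
from .protocol import ProtocolSpec

FEATURE_SETS = {
    "respiratory": ("rr_bpm", "energy", "acoustic_ventilation"),
    "resp_hr_wl": ("rr_bpm", "energy", "acoustic_ventilation", "hr_bpm", "workload_w"),
    "all_acoustic": ("energy", "intensity", "rr_bpm", "acoustic_ventilation"),
}


@dataclass(frozen=True)
class RegressionConfig:
    model: str = "random-forest"         # or "multiple-linear"
    feature_set: str = "all_acoustic"
    n_trees: int = 500
    seed: int = 0
    n_folds: int = 5
    fold_assignment: str = "temporal"    # or "random"

    def __post_init__(self) -> None:
        if self.model not in ("random-forest", "multiple-linear"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        if self.n_folds < 2:
            raise ValueError("fold count must be >= 2")

    @property
    def predictors(self) -> tuple:
        return FEATURE_SETS[self.feature_set]


def smooth_vo2(gas: GasExchangeSeries, step_s: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Breath-by-breath VO2 binned to a uniform grid (bin means, gaps interpolated)."""
    if gas.times.size == 0:
        raise ValueError("empty gas series")
    t0 = np.floor(gas.times[0] / step_s) * step_s
    edges = np.arange(t0, gas.times[-1] + step_s, step_s)
    idx = np.digitize(gas.times, edges) - 1
    n_bins = edges.size - 1
    sums = np.bincount(idx, weights=gas.vo2, minlength=n_bins)[:n_bins]
    counts = np.bincount(idx, minlength=n_bins)[:n_bins]
    centers = edges[:-1] + step_s / 2
    filled = counts > 0
    values = np.empty(n_bins)
    values[filled] = sums[filled] / counts[filled]
    if not filled.all():
        values[~filled] = np.interp(centers[~filled], centers[filled], values[filled])
    return centers, values


def reference_vo2peak(gas: GasExchangeSeries, mass_kg: float, window_s: float = 10.0) -> float:
    """Peak 10-s-averaged VO2, mass-normalized (mL/kg/min)."""
    if gas.times[-1] - gas.times[0] < window_s:
        raise ValueError("gas series must span at least one averaging window")
    edges = np.arange(0.0, gas.times[-1] + window_s, window_s)
    idx = np.digitize(gas.times, edges) - 1
    n_bins = edges.size - 1
    sums = np.bincount(idx, weights=gas.vo2, minlength=n_bins)[:n_bins]
    counts = np.bincount(idx, minlength=n_bins)[:n_bins]
    means = sums[counts > 0] / counts[counts > 0]
    return float(means.max() / mass_kg)


def build_design_matrix(
    features: FeatureSeries,
    gas: GasExchangeSeries,
    cfg: RegressionConfig,
    mass_kg: float,
    protocol: ProtocolSpec | None = None,
) -> pd.DataFrame:
    """Time-aligned predictor rows with the 1-s-smoothed VO2 target (mL/kg/min).

    Rows with any missing value are dropped (their count is stored in
    ``df.attrs['n_dropped']``).  The HR+workload set needs ``protocol`` for
    the workload channel and a usable HR series.
    """
    df = features.to_frame()
    vo2_t, vo2_v = smooth_vo2(gas)
    lo = max(df["time_s"].iloc[0], vo2_t[0])
    hi = min(df["time_s"].iloc[-1], vo2_t[-1])
    df = df[(df["time_s"] >= lo) & (df["time_s"] <= hi)].copy()
    if df.empty:
        raise ValueError("feature and gas time supports do not overlap")
    df["vo2_ml_kg_min"] = np.interp(df["time_s"], vo2_t, vo2_v) / mass_kg
    cols = list(cfg.predictors)
    if "hr_bpm" in cols:
        if gas.hr.size == 0 or not np.isfinite(gas.hr).any():
            raise ValueError("feature set requires HR but the HR series is unusable")
        df["hr_bpm"] = np.interp(df["time_s"], gas.hr_times, gas.hr)
    if "workload_w" in cols:
        if protocol is None:
            raise ValueError("feature set requires workload; pass the protocol")
        df["workload_w"] = [protocol.stage_at_time(t)[1] for t in df["time_s"]]
    out = df[["time_s", *cols, "vo2_ml_kg_min"]]
    kept = out.dropna()
    kept = kept.reset_index(drop=True)
    kept.attrs["n_dropped"] = len(out) - len(kept)
    kept.attrs["predictors"] = cols
    return kept


def fit_predict(train: pd.DataFrame, test: pd.DataFrame, cfg: RegressionConfig) -> np.ndarray:
    """Train on ``train`` rows, predict the target for ``test`` rows."""
    if train.empty:
        raise ValueError("empty training set")
    cols = [c for c in train.columns if c not in ("time_s", "vo2_ml_kg_min")]
    if list(cols) != [c for c in test.columns if c not in ("time_s", "vo2_ml_kg_min")]:
        raise ValueError("train/test schemas differ")
    X, y = train[cols].to_numpy(float), train["vo2_ml_kg_min"].to_numpy(float)
    Xt = test[cols].to_numpy(float)
    if cfg.model == "random-forest":
        model = RandomForestRegressor(
            n_estimators=cfg.n_trees, random_state=cfg.seed, n_jobs=1
        )
        model.fit(X, y)
        return model.predict(Xt)
    # ordinary least squares with an intercept
    A = np.column_stack([np.ones(len(X)), X])
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"singular design matrix (condition number {cond:.3g})"
        )
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return np.column_stack([np.ones(len(Xt)), Xt]) @ coef


@dataclass(frozen=True)
class VO2Prediction:
    subject_id: str
    scheme: str                          # 'subject-specific' | 'subject-independent'
    times: np.ndarray = field(compare=False)
    vo2_pred: np.ndarray = field(compare=False)
    vo2peak_pred: float = 0.0
    vo2peak_ref: float = 0.0

    @staticmethod
    def from_trace(subject_id, scheme, times, pred, ref_peak) -> "VO2Prediction":
        return VO2Prediction(
            subject_id=subject_id,
            scheme=scheme,
            times=np.asarray(times),
            vo2_pred=np.asarray(pred),
            vo2peak_pred=float(np.max(pred)),
            vo2peak_ref=float(ref_peak),
        )


def fold_indices(n_rows: int, cfg: RegressionConfig) -> list[np.ndarray]:
    """Fold assignment: contiguous time blocks (default) or seeded random rows."""
    if n_rows < cfg.n_folds:
        raise ValueError("fewer rows than folds")
    if cfg.fold_assignment == "temporal":
        return list(np.array_split(np.arange(n_rows), cfg.n_folds))
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n_rows)
    return [np.sort(p) for p in np.array_split(perm, cfg.n_folds)]


def cv_subject_specific(
    df: pd.DataFrame, cfg: RegressionConfig, ref_peak: float, subject_id: str = "subject"
) -> VO2Prediction:
    """Five-fold within-subject cross-validated VO2 trace and its peak."""
    folds = fold_indices(len(df), cfg)
    pred = np.empty(len(df))
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(len(df)), test_idx)
        pred[test_idx] = fit_predict(df.iloc[train_idx], df.iloc[test_idx], cfg)
    return VO2Prediction.from_trace(
        subject_id, "subject-specific", df["time_s"].to_numpy(), pred, ref_peak
    )


def cv_loso(
    cohort: dict[str, tuple[pd.DataFrame, float]], cfg: RegressionConfig
) -> list[VO2Prediction]:
    """Leave-one-subject-out predictions, one per subject (sorted by id)."""
    if len(cohort) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    ids = sorted(cohort)
    out = []
    for sid in ids:
        test_df, ref_peak = cohort[sid]
        train_df = pd.concat(
            [cohort[other][0] for other in ids if other != sid], ignore_index=True
        )
        pred = fit_predict(train_df, test_df, cfg)
        out.append(
            VO2Prediction.from_trace(
                sid, "subject-independent", test_df["time_s"].to_numpy(), pred, ref_peak
            )
        )
    return out
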