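"""Waveform agreement metrics for predicted vs. measured GRF/GRM.

Agreement is quantified per component by Pearson's correlation coefficient
(rho), the root-mean-square error (RMSE), and the relative RMSE (rRMSE), which
normalises the RMSE by the mean of the two waveforms' peak-to-peak amplitudes
and is expressed in percent.  Correlations are categorised with the standard
bands: rho <= 0.35 weak, 0.35 < rho <= 0.67 moderate, 0.67 < rho <= 0.9 strong,
rho > 0.9 excellent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimator import GroundReactionRecord
from .io import ForcePlateRecord

__all__ = [
    "ComponentAgreement",
    "AgreementReport",
    "pearson_rho",
    "rmse",
    "rrmse",
    "classify_rho",
    "align_and_report",
    "normalize_cycle",
]

COMPONENTS = ("Fx", "Fy", "Fz", "Mx", "My", "Mz")


def pearson_rho(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if a.size < 3:
        raise ValueError(f"need at least 3 samples, got {a.size}")
    da, db = a - a.mean(), b - b.mean()
    na, nb = np.sqrt((da * da).sum()), np.sqrt((db * db).sum())
    if na == 0.0 or nb == 0.0:
        raise ValueError("correlation undefined for a constant series")
    return float((da * db).sum() / (na * nb))


def rmse(pred: np.ndarray, meas: np.ndarray) -> float:
    """Root-mean-square error between two equal-length series."""
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if pred.shape != meas.shape:
        raise ValueError("series must have equal length")
    if pred.size == 0:
        raise ValueError("cannot compute RMSE of empty series")
    return float(np.sqrt(np.mean((pred - meas) ** 2)))


def rrmse(pred: np.ndarray, meas: np.ndarray) -> float:
    """Relative RMSE in percent: RMSE normalised by the average of the two
    series' peak-to-peak amplitudes."""
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    amp = 0.5 * (np.ptp(pred) + np.ptp(meas))
    if amp == 0.0:
        raise ValueError("rRMSE undefined: both series have zero "
                         "peak-to-peak amplitude")
    return 100.0 * rmse(pred, meas) / amp


def classify_rho(rho: float) -> str:
    """Correlation category; boundary values fall in the lower category."""
    if not -1.0 - 1e-12 <= rho <= 1.0 + 1e-12:
        raise ValueError(f"correlation must lie in [-1, 1], got {rho}")
    if rho <= 0.35:
        return "weak"
    if rho <= 0.67:
        return "moderate"
    if rho <= 0.9:
        return "strong"
    return "excellent"


@dataclass
class ComponentAgreement:
    rho: float
    rmse: float
    rrmse: float
    category: str


@dataclass
class AgreementReport:
    """Per-component agreement metrics plus the comparison window used."""

    components: dict[str, ComponentAgreement]
    window: str
    n_samples: int

    def __getitem__(self, comp: str) -> ComponentAgreement:
        return self.components[comp]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"component": c, "rho": m.rho, "rmse": m.rmse,
                 "rrmse_pct": m.rrmse, "category": m.category}
                for c, m in self.components.items()]
        return pd.DataFrame(rows)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str) -> None:
        payload = {"window": self.window, "n_samples": self.n_samples,
                   "components": {c: vars(m) for c, m in self.components.items()}}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _resample(series: np.ndarray, t_src: np.ndarray, t_dst: np.ndarray) -> np.ndarray:
    out = np.empty((t_dst.size, series.shape[1]))
    for j in range(series.shape[1]):
        out[:, j] = np.interp(t_dst, t_src, series[:, j])
    return out


def normalize_cycle(series: np.ndarray, n_points: int = 101) -> np.ndarray:
    """Time-normalise a series to 0-100% (n_points samples) by linear
    interpolation, for figure-style gait-cycle output."""
    series = np.asarray(series, dtype=float)
    s = np.linspace(0.0, 1.0, n_points)
    t = np.linspace(0.0, 1.0, series.shape[0])
    if series.ndim == 1:
        return np.interp(s, t, series)
    return np.stack([np.interp(s, t, series[:, j])
                     for j in range(series.shape[1])], axis=1)


def align_and_report(pred: GroundReactionRecord, meas: ForcePlateRecord,
                     window: str = "stance",
                     stance_threshold: float = 20.0) -> AgreementReport:
    """Compare a predicted record's total GRF/GRM with a force-plate record.

    The measurement is linearly resampled onto the prediction's time base over
    the overlapping range; ``window="stance"`` restricts the comparison to
    frames where the measured vertical force exceeds ``stance_threshold`` (N),
    ``window="cycle"`` uses the full overlap.  The plate record must already be
    expressed in the canonical axes about the same (lab-origin) moment
    reference as the prediction.
    """
    if window not in ("stance", "cycle"):
        raise ValueError(f"window must be 'stance' or 'cycle', got {window!r}")
    t_pred, t_meas = pred.time, meas.time
    t0, t1 = max(t_pred[0], t_meas[0]), min(t_pred[-1], t_meas[-1])
    if t1 <= t0:
        raise ValueError("prediction and measurement time ranges do not overlap")
    keep = (t_pred >= t0) & (t_pred <= t1)
    t = t_pred[keep]
    meas_f = _resample(meas.force, t_meas, t)
    meas_m = _resample(meas.moment, t_meas, t)
    pred_f = pred.total.force[keep]
    pred_m = pred.total.moment[keep]
    if window == "stance":
        mask = meas_f[:, 2] > stance_threshold
        if not mask.any():
            raise ValueError(f"no stance detected: measured Fz never exceeds "
                             f"{stance_threshold} N in the overlap")
    else:
        mask = np.ones(t.size, dtype=bool)
    pred_all = np.hstack([pred_f, pred_m])[mask]
    meas_all = np.hstack([meas_f, meas_m])[mask]
    comps = {}
    for j, name in enumerate(COMPONENTS):
        r = pearson_rho(pred_all[:, j], meas_all[:, j])
        comps[name] = ComponentAgreement(
            rho=r, rmse=rmse(pred_all[:, j], meas_all[:, j]),
            rrmse=rrmse(pred_all[:, j], meas_all[:, j]),
            category=classify_rho(r))
    return AgreementReport(comps, window, int(mask.sum()))
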