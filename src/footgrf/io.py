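"""Marker-trajectory and force-plate file IO, gap filling, and low-pass filtering.

All in-memory data live in the canonical laboratory frame: x anterior (walking
direction), y to the participant's left, z up, metres, newtons.  Readers convert
units (mm -> m) and axis conventions (Y-up TRC -> Z-up) on the way in, so every
downstream module can assume the canonical frame.

Supported marker formats are TRC (the OpenSim dialect) and the package's CSV
interchange dialect (first column ``time`` in seconds, then ``<label>_x``,
``<label>_y``, ``<label>_z`` in metres, header row mandatory).  Force-plate data
are read from CSV with columns ``time, Fx, Fy, Fz, Mx, My, Mz``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "MarkerTrajectorySet",
    "ForcePlateRecord",
    "read_markers",
    "write_markers",
    "read_forceplate",
    "write_forceplate",
    "lowpass",
    "filter_markers",
]

#: Rotation Y-up (TRC convention: X forward, Y up, Z right) -> canonical Z-up.
_YUP_TO_ZUP = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])


@dataclass
class MarkerTrajectorySet:
    """Labeled 3-D marker positions over time.

    positions has shape (n_frames, n_markers, 3), metres, canonical frame.
    """

    labels: list[str]
    positions: np.ndarray
    rate_hz: float
    up_axis: str = "z"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate marker labels: {dupes}")
        if self.positions.ndim != 3 or self.positions.shape[1] != len(self.labels) \
                or self.positions.shape[2] != 3:
            raise ValueError(
                f"positions must have shape (n_frames, {len(self.labels)}, 3), "
                f"got {self.positions.shape}")
        if not self.rate_hz > 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.up_axis != "z":
            raise ValueError("in-memory marker sets must be canonical (up_axis='z'); "
                             "axis conversion happens in read_markers")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return len(self.labels)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate_hz

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"marker {label!r} not in trajectory set "
                           f"({self.n_markers} labels)") from None

    def get(self, label: str) -> np.ndarray:
        """Trajectory of one marker, shape (n_frames, 3)."""
        return self.positions[:, self.index(label), :]

    def subset(self, labels: list[str]) -> "MarkerTrajectorySet":
        idx = [self.index(l) for l in labels]
        return MarkerTrajectorySet(list(labels), self.positions[:, idx, :], self.rate_hz)

    def mean_pose(self) -> np.ndarray:
        """Time-averaged marker positions, shape (n_markers, 3)."""
        return np.nanmean(self.positions, axis=0)


@dataclass
class ForcePlateRecord:
    """Measured ground reaction: force (N), moment about the plate origin (N*m),
    COP (m, NaN where the vertical force is below the contact threshold)."""

    force: np.ndarray
    moment: np.ndarray
    cop: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        self.moment = np.asarray(self.moment, dtype=float)
        self.cop = np.asarray(self.cop, dtype=float)
        n = self.force.shape[0]
        if self.moment.shape[0] != n or self.cop.shape[0] != n:
            raise ValueError("force, moment and cop series must have equal length")
        if not self.rate_hz > 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")

    @property
    def n_frames(self) -> int:
        return self.force.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate_hz


# ---------------------------------------------------------------------------
# filtering


def _butter_sos(cutoff_hz: float, rate_hz: float, order: int, zero_phase: bool):
    if order <= 0 or order % 2:
        raise ValueError(f"filter order must be even and positive, got {order}")
    if not rate_hz > 2.0 * cutoff_hz:
        raise ValueError(f"sampling rate {rate_hz} Hz must exceed twice the "
                         f"cutoff {cutoff_hz} Hz")
    if zero_phase:
        # Forward-backward filtering squares the magnitude response, so the
        # per-pass corner is widened to keep the *net* response at -3 dB at the
        # requested cutoff: fc' = fc / (2^(1/2) - 1)^(1/(2n)) with n the
        # per-pass order (order/2 per pass, full order net).
        n_pass = order // 2
        fc = cutoff_hz / (np.sqrt(2.0) - 1.0) ** (1.0 / (2.0 * n_pass))
        return signal.butter(n_pass, fc, btype="low", fs=rate_hz, output="sos")
    return signal.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")


def lowpass(series: np.ndarray, cutoff_hz: float, rate_hz: float,
            order: int = 4, zero_phase: bool = True) -> np.ndarray:
    """Low-pass Butterworth filter along the time (first) axis.

    By default zero-phase (forward-backward) with the per-pass corner adjusted
    so the net magnitude is -3 dB at ``cutoff_hz``; ``zero_phase=False`` gives
    a causal single-pass filter of the full order at the nominal cutoff.
    """
    x = np.asarray(series, dtype=float)
    sos = _butter_sos(cutoff_hz, rate_hz, order, zero_phase)
    if zero_phase:
        padlen = 3 * (2 * sos.shape[0] + 1)
        if x.shape[0] <= padlen:
            raise ValueError(f"series of length {x.shape[0]} is shorter than the "
                             f"filter warm-up; need more than {padlen} samples")
        return signal.sosfiltfilt(sos, x, axis=0, padlen=padlen)
    if x.shape[0] < 2 * order:
        raise ValueError(f"series of length {x.shape[0]} is shorter than the "
                         f"filter warm-up; need at least {2 * order} samples")
    return signal.sosfilt(sos, x, axis=0)


def filter_markers(markers: MarkerTrajectorySet, cutoff_hz: float = 6.0,
                   order: int = 4, zero_phase: bool = True) -> MarkerTrajectorySet:
    """Return a copy of the trajectory set low-pass filtered at ``cutoff_hz``."""
    filtered = lowpass(markers.positions, cutoff_hz, markers.rate_hz,
                       order=order, zero_phase=zero_phase)
    return replace(markers, positions=filtered)


def _fill_gaps(positions: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate NaN runs of at most ``max_gap`` frames per marker."""
    out = positions.copy()
    n = out.shape[0]
    t = np.arange(n)
    for m in range(out.shape[1]):
        bad = np.isnan(out[:, m, :]).any(axis=1)
        if not bad.any():
            continue
        if bad.all():
            raise ValueError(f"marker column {m} has no valid samples")
        # measure run lengths of missing frames
        runs = []
        start = None
        for i in range(n):
            if bad[i] and start is None:
                start = i
            elif not bad[i] and start is not None:
                runs.append((start, i - 1))
                start = None
        if start is not None:
            runs.append((start, n - 1))
        worst = max(e - s + 1 for s, e in runs)
        if worst > max_gap:
            raise ValueError(f"marker gap of {worst} frames exceeds the maximum "
                             f"interpolatable gap ({max_gap} frames)")
        good = ~bad
        for k in range(3):
            out[bad, m, k] = np.interp(t[bad], t[good], out[good, m, k])
    return out


# ---------------------------------------------------------------------------
# marker IO


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("trc", "csv", "c3d"):
        return ext
    raise ValueError(f"cannot infer marker file format from {path!r}; "
                     "pass format='trc' or 'csv'")


def read_markers(path: str, format: str | None = None, *,
                 units: str | None = None, up_axis: str | None = None,
                 max_gap: int = 10) -> MarkerTrajectorySet:
    """Read a marker trajectory file into the canonical frame (metres, z-up).

    ``units`` / ``up_axis`` override the file's declared metadata (TRC declares
    units; TRC is Y-up by convention unless overridden; CSV is metres, z-up).
    Gaps (missing samples) of at most ``max_gap`` frames are linearly
    interpolated; longer gaps raise.
    """
    fmt = _infer_format(path, format)
    if fmt == "trc":
        return _read_trc(path, units=units, up_axis=up_axis or "y", max_gap=max_gap)
    if fmt == "csv":
        return _read_marker_csv(path, units=units or "m",
                                up_axis=up_axis or "z", max_gap=max_gap)
    if fmt == "c3d":
        raise ValueError("C3D input is not supported by this build; export the "
                         "trial to TRC or to the CSV interchange dialect")
    raise ValueError(f"unknown marker format {fmt!r} (expected 'trc' or 'csv')")


_UNIT_SCALE = {"m": 1.0, "mm": 0.001, "cm": 0.01}


def _axis_transform(up_axis: str) -> np.ndarray:
    if up_axis == "z":
        return np.eye(3)
    if up_axis == "y":
        return _YUP_TO_ZUP
    raise ValueError(f"unsupported up_axis {up_axis!r} (expected 'y' or 'z')")


def _read_trc(path: str, units: str | None, up_axis: str, max_gap: int):
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise ValueError(f"{path!r} is not a TRC file (missing PathFileType header)")
    meta_keys = lines[1].split("\t")
    meta_vals = lines[2].split("\t")
    meta = dict(zip(meta_keys, meta_vals))
    rate_hz = float(meta["DataRate"])
    file_units = meta.get("Units", "mm")
    scale = _UNIT_SCALE[(units or file_units).lower()]
    header = lines[3].split("\t")
    labels = [h for h in header[2:] if h.strip()]
    data_rows = [ln for ln in lines[5:] if ln.strip()]
    values = []
    for ln in data_rows:
        cells = ln.split("\t")[2:]  # drop Frame#, Time
        row = [float(c) if c.strip() else np.nan for c in cells]
        if len(row) < 3 * len(labels):
            row += [np.nan] * (3 * len(labels) - len(row))
        values.append(row[:3 * len(labels)])
    pos = np.asarray(values, dtype=float).reshape(len(values), len(labels), 3)
    pos = pos * scale @ _axis_transform(up_axis).T
    pos = _fill_gaps(pos, max_gap)
    return MarkerTrajectorySet(labels, pos, rate_hz)


def _read_marker_csv(path: str, units: str, up_axis: str, max_gap: int):
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError("CSV marker file must have a 'time' column (seconds)")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("CSV marker file must contain at least two frames")
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise ValueError("CSV marker file is not uniformly sampled")
    rate_hz = 1.0 / dts[0]
    labels = []
    for col in df.columns:
        if col.endswith("_x"):
            lab = col[:-2]
            if f"{lab}_y" in df.columns and f"{lab}_z" in df.columns:
                labels.append(lab)
    if not labels:
        raise ValueError("CSV marker file defines no <label>_x/_y/_z column triples")
    pos = np.stack([df[[f"{l}_x", f"{l}_y", f"{l}_z"]].to_numpy(dtype=float)
                    for l in labels], axis=1)
    pos = pos * _UNIT_SCALE[units.lower()] @ _axis_transform(up_axis).T
    pos = _fill_gaps(pos, max_gap)
    return MarkerTrajectorySet(labels, pos, rate_hz)


def write_markers(markers: MarkerTrajectorySet, path: str,
                  format: str | None = None) -> None:
    """Write a trajectory set as TRC (mm, Y-up, OpenSim dialect) or CSV (m, z-up)."""
    fmt = _infer_format(path, format)
    if fmt == "csv":
        data = {"time": markers.time}
        for i, lab in enumerate(markers.labels):
            for k, ax in enumerate("xyz"):
                data[f"{lab}_{ax}"] = markers.positions[:, i, k]
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.9f")
        return
    if fmt == "trc":
        n, m = markers.n_frames, markers.n_markers
        pos_yup = markers.positions @ _YUP_TO_ZUP * 1000.0  # inverse rotation, mm
        with open(path, "w") as fh:
            fh.write(f"PathFileType\t4\t(X/Y/Z)\t{os.path.basename(path)}\n")
            fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                     "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
            fh.write(f"{markers.rate_hz:g}\t{markers.rate_hz:g}\t{n}\t{m}\tmm\t"
                     f"{markers.rate_hz:g}\t1\t{n}\n")
            fh.write("Frame#\tTime\t" + "\t\t\t".join(markers.labels) + "\t\t\n")
            fh.write("\t\t" + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(m))
                     + "\n")
            for f in range(n):
                cells = [f"{f+1}", f"{f / markers.rate_hz:.6f}"]
                cells += [f"{v:.6f}" for v in pos_yup[f].ravel()]
                fh.write("\t".join(cells) + "\n")
        return
    raise ValueError(f"unsupported marker output format {fmt!r}")


# ---------------------------------------------------------------------------
# force-plate IO

_FP_COLUMNS = ["Fx", "Fy", "Fz", "Mx", "My", "Mz"]


def read_forceplate(path: str, format: str = "csv", *,
                    cutoff_hz: float | None = 18.0, order: int = 4,
                    rate_out: float | None = None,
                    contact_threshold: float = 20.0) -> ForcePlateRecord:
    """Read a force-plate record from CSV, low-pass filter it, and optionally
    decimate to the marker rate.

    Expected columns: ``time, Fx, Fy, Fz, Mx, My, Mz`` (optionally ``COPx, COPy``;
    recomputed from the moments otherwise).  ``cutoff_hz=None`` skips filtering.
    COP is NaN wherever Fz is below ``contact_threshold`` (N).
    """
    if format.lower() == "c3d":
        raise ValueError("C3D input is not supported by this build; export the "
                         "plate channels to CSV (time, Fx..Mz)")
    if format.lower() != "csv":
        raise ValueError(f"unknown force-plate format {format!r}")
    df = pd.read_csv(path)
    missing = [c for c in ["time", *_FP_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"force-plate CSV {path!r} lacks columns {missing}; "
                         f"expected time, {', '.join(_FP_COLUMNS)}")
    t = df["time"].to_numpy(dtype=float)
    rate_hz = 1.0 / np.mean(np.diff(t))
    force = df[["Fx", "Fy", "Fz"]].to_numpy(dtype=float)
    moment = df[["Mx", "My", "Mz"]].to_numpy(dtype=float)
    if cutoff_hz is not None:
        force = lowpass(force, cutoff_hz, rate_hz, order=order)
        moment = lowpass(moment, cutoff_hz, rate_hz, order=order)
    if rate_out is not None:
        step = rate_hz / rate_out
        if abs(step - round(step)) > 1e-6 or step < 1:
            raise ValueError(f"cannot decimate {rate_hz:g} Hz to {rate_out:g} Hz "
                             "by an integer factor")
        sl = slice(None, None, int(round(step)))
        force, moment = force[sl], moment[sl]
        rate_hz = rate_out
    fz = force[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        cop = np.stack([-moment[:, 1] / fz, moment[:, 0] / fz], axis=1)
    cop[fz < contact_threshold] = np.nan
    if "COPx" in df.columns and "COPy" in df.columns and cutoff_hz is None \
            and rate_out is None:
        cop_file = df[["COPx", "COPy"]].to_numpy(dtype=float)
        cop = np.where(np.isnan(cop), cop, cop_file)
    return ForcePlateRecord(force, moment, cop, rate_hz)


def write_forceplate(rec: ForcePlateRecord, path: str) -> None:
    """Write a force-plate record to the CSV dialect read_forceplate expects."""
    df = pd.DataFrame({
        "time": rec.time,
        "Fx": rec.force[:, 0], "Fy": rec.force[:, 1], "Fz": rec.force[:, 2],
        "Mx": rec.moment[:, 0], "My": rec.moment[:, 1], "Mz": rec.moment[:, 2],
        "COPx": rec.cop[:, 0], "COPy": rec.cop[:, 1],
    })
    df.to_csv(path, index=False, float_format="%.9f")
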