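"""Foot contact points: calibration from a static trial and reconstruction.

Each foot carries 11 contact points (22 across both feet) laid out on the sole
in a foot-local frame.  During a static standing calibration the points are
pinned 10 mm below the ground plane ("toward the ground"), which absorbs shoe
sole thickness and marker mounting height.  During dynamic trials the points
are reconstructed rigidly: a least-squares (Kabsch) rigid fit maps the
calibration-pose foot markers onto each dynamic frame's markers and the same
transform is applied to the calibrated points, so the layout is exactly
equivariant under rigid foot motion.  Each point's height above the ground
plane, floored at zero, is the distance the force distribution uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .io import MarkerTrajectorySet

__all__ = [
    "ContactPointSet",
    "ContactDistanceSeries",
    "load_layout",
    "build_contact_points",
    "reconstruct_points",
    "contact_distances",
    "write_point_trajectories",
]

DEFAULT_OFFSET = 0.010  # m, calibration offset toward the ground


def load_layout(path: str | None = None) -> dict:
    """Load a contact-point layout (default: packaged 11-point approximation)."""
    if path is None:
        text = resources.files("footgrf.data").joinpath("contact_layout.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    layout = yaml.safe_load(text)
    for key in ("markers", "frame", "points"):
        if key not in layout:
            raise ValueError(f"contact layout lacks required key {key!r}")
    return layout


@dataclass
class ContactPointSet:
    """Calibrated contact points for one foot.

    ``calib_markers`` is the static-pose foot marker cloud and ``points`` the
    calibrated world positions of the 11 points in that pose; dynamic frames
    reuse both through a rigid fit.
    """

    side: str                      # "left" | "right"
    point_names: list[str]
    marker_labels: list[str]
    calib_markers: np.ndarray      # (n_markers, 3) static pose
    points: np.ndarray             # (n_points, 3) calibrated, static pose
    offset: float
    ground_level: float

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class ContactDistanceSeries:
    """Per-point height above the ground plane over time, floored at zero."""

    point_names: list[str]
    positions: np.ndarray    # (n_frames, n_points, 3) reconstructed
    distances: np.ndarray    # (n_frames, n_points) >= 0
    in_contact: np.ndarray   # (n_frames, n_points) bool
    threshold: float
    rate_hz: float


def _foot_labels(side: str, layout: dict) -> list[str]:
    prefix = {"left": "L.", "right": "R."}.get(side)
    if prefix is None:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return [prefix + m for m in layout["markers"]]


def build_contact_points(static_markers: MarkerTrajectorySet, side: str,
                         layout: dict | str | None = None, *,
                         offset: float = DEFAULT_OFFSET,
                         ground_level: float | str = 0.0,
                         min_frames: int = 10) -> ContactPointSet:
    """Calibrate one foot's contact points from a static standing trial.

    The layout's (x, y_medial) sole coordinates are expressed in a frame built
    from the averaged static markers (origin at the heel marker's ground
    projection, x horizontal toward the toe marker, y medial) and every point's
    height is pinned to ``ground_level - offset``: 10 mm toward the ground by
    default, exactly as the calibration prescribes.

    ``ground_level`` is the floor height in the lab frame (0.0 by convention);
    pass ``"auto"`` to estimate it as the static minimum of the foot markers'
    heights (useful when the lab origin is not on the floor).
    """
    if isinstance(layout, str) or layout is None:
        layout = load_layout(layout)
    if static_markers.n_frames < min_frames:
        raise ValueError(f"static trial has {static_markers.n_frames} frames; "
                         f"at least {min_frames} needed for averaging")
    labels = _foot_labels(side, layout)
    missing = [l for l in labels if l not in static_markers.labels]
    if missing:
        raise ValueError(f"static trial lacks foot markers {missing} for the "
                         f"{side} foot")
    mean = static_markers.mean_pose()
    cloud = np.stack([mean[static_markers.index(l)] for l in labels])

    prefix = "L." if side == "left" else "R."
    origin = cloud[labels.index(prefix + layout["frame"]["origin_marker"])].copy()
    fwd = cloud[labels.index(prefix + layout["frame"]["forward_marker"])] - origin
    fwd[2] = 0.0
    norm = np.linalg.norm(fwd)
    if norm < 1e-6:
        raise ValueError("foot markers are vertically stacked; cannot build a "
                         "foot frame from the static trial")
    xhat = fwd / norm
    zhat = np.array([0.0, 0.0, 1.0])
    yhat = np.cross(zhat, xhat)  # left of forward

    if ground_level == "auto":
        ground_level = float(cloud[:, 2].min())
    ground_level = float(ground_level)

    # sanity check: foot approximately flat (sole markers within a few cm band)
    spread = cloud[:, 2].max() - cloud[:, 2].min()
    if spread > 0.25:
        raise ValueError(f"static foot marker vertical spread {spread:.3f} m is "
                         "implausible; is the trial really a flat standing pose?")

    medial_sign = 1.0 if side == "right" else -1.0  # canonical +y is left
    names, pts = [], []
    for name, (x_loc, y_med) in layout["points"].items():
        p = origin + x_loc * xhat + medial_sign * y_med * yhat
        p[2] = ground_level - offset
        names.append(name)
        pts.append(p)
    return ContactPointSet(side, names, labels, cloud, np.stack(pts),
                           offset, ground_level)


def _rigid_fits(ref: np.ndarray, frames: np.ndarray):
    """Batched Kabsch: per-frame rotation R_t and translation t_t minimising
    ||R_t ref + t_t - frames[t]||^2.  ref (m,3), frames (n,m,3)."""
    ref_c = ref - ref.mean(axis=0)
    cen = frames.mean(axis=1, keepdims=True)
    dyn_c = frames - cen
    h = np.einsum("mi,nmj->nij", ref_c, dyn_c)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("nij->nji", vt) @ np.einsum("nij->nji", u))
    d = np.ones((frames.shape[0], 3))
    d[:, 2] = det
    rot = np.einsum("nji,nj,nkj->nik", vt, d, u)  # R = V diag(1,1,det) U^T
    trans = cen[:, 0, :] - np.einsum("nij,j->ni", rot, ref.mean(axis=0))
    return rot, trans


def reconstruct_points(cps: ContactPointSet,
                       markers: MarkerTrajectorySet) -> np.ndarray:
    """Rigidly map the calibrated points into every dynamic frame,
    shape (n_frames, n_points, 3)."""
    missing = [l for l in cps.marker_labels if l not in markers.labels]
    if missing:
        raise ValueError(f"dynamic trial lacks foot markers {missing}")
    frames = np.stack([markers.get(l) for l in cps.marker_labels], axis=1)
    rot, trans = _rigid_fits(cps.calib_markers, frames)
    return np.einsum("nij,pj->npi", rot, cps.points) + trans[:, None, :]


def contact_distances(cps: ContactPointSet, markers: MarkerTrajectorySet,
                      threshold: float = 0.030) -> ContactDistanceSeries:
    """Reconstruct the foot's points in every frame and measure each point's
    height above the ground plane (floored at 0; sole penetration reads as
    full contact)."""
    pos = reconstruct_points(cps, markers)
    d = np.maximum(0.0, pos[:, :, 2] - cps.ground_level)
    return ContactDistanceSeries(cps.point_names, pos, d, d < threshold,
                                 threshold, markers.rate_hz)


def write_point_trajectories(series: ContactDistanceSeries, path: str) -> None:
    """Debug writer: CSV of reconstructed contact-point trajectories."""
    n = series.positions.shape[0]
    data = {"time": np.arange(n) / series.rate_hz}
    for i, name in enumerate(series.point_names):
        for k, ax in enumerate("xyz"):
            data[f"{name}_{ax}"] = series.positions[:, i, k]
        data[f"{name}_dist"] = series.distances[:, i]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")
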