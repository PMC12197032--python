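"""Segment inertia model and translational dynamics.

A Gait-2392-style table of segment mass fractions is scaled to the participant's
mass; each segment's centre of mass (COM) is located as a fixed convex
combination of marker positions.  Only the translational equations of motion are
evaluated — the rotational equation is deliberately excluded, so no segment
moments of inertia are needed: the total external force is

    F_ext(t) = sum_i m_i a_i(t) - M g

with m_i the segment masses, a_i the segment COM accelerations (central finite
differences), M the total mass and g gravity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .io import MarkerTrajectorySet

__all__ = [
    "Segment",
    "AnthropometricModel",
    "SegmentKinematics",
    "load_body_config",
    "scale_model",
    "segment_kinematics",
    "total_external_force",
    "second_derivative",
    "GRAVITY",
]

GRAVITY = np.array([0.0, 0.0, -9.80665])


def load_body_config(path: str | None = None) -> dict:
    """Load the segment/locator/marker-map configuration (default: packaged YAML)."""
    if path is None:
        text = resources.files("footgrf.data").joinpath("body_model.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    for key in ("segments", "marker_set"):
        if key not in cfg:
            raise ValueError(f"body model config lacks required key {key!r}")
    return cfg


@dataclass
class Segment:
    name: str
    mass: float  # kg, after scaling
    locator: dict[str, float]  # marker label -> convex weight, sums to 1


@dataclass
class AnthropometricModel:
    segments: list[Segment]
    total_mass: float
    height: float
    gravity: np.ndarray = field(default_factory=lambda: GRAVITY.copy())
    marker_set: list[str] = field(default_factory=list)

    @property
    def masses(self) -> np.ndarray:
        return np.array([s.mass for s in self.segments])

    @property
    def segment_names(self) -> list[str]:
        return [s.name for s in self.segments]


def scale_model(height: float, mass: float,
                config: dict | str | None = None) -> AnthropometricModel:
    """Scale the embedded segment mass-fraction table so segment masses sum to
    the participant's mass.

    ``config`` may be a loaded configuration dict, a path to a YAML file, or
    None for the packaged default.
    """
    if height <= 0 or mass <= 0:
        raise ValueError(f"height and mass must be positive, got {height}, {mass}")
    if config is None or isinstance(config, str):
        config = load_body_config(config)
    marker_set = list(config["marker_set"])
    fractions = {name: spec["mass_fraction"] for name, spec in config["segments"].items()}
    total_frac = sum(fractions.values())
    if abs(total_frac - 1.0) > 1e-6:
        raise ValueError(f"segment mass fractions sum to {total_frac:.8f}, not 1")
    segments = []
    for name, spec in config["segments"].items():
        locator = dict(spec["locator"])
        wsum = sum(locator.values())
        if abs(wsum - 1.0) > 1e-6:
            raise ValueError(f"locator weights for segment {name!r} sum to {wsum:.8f}")
        for label in locator:
            if label not in marker_set:
                raise ValueError(f"segment {name!r} locator references marker "
                                 f"{label!r} absent from the marker map")
        # renormalise so masses sum to `mass` exactly
        segments.append(Segment(name, mass * spec["mass_fraction"] / total_frac, locator))
    return AnthropometricModel(segments, total_mass=mass, height=height,
                               marker_set=marker_set)


def second_derivative(x: np.ndarray, rate_hz: float) -> np.ndarray:
    """Second time derivative along axis 0: central differences in the interior,
    second-order one-sided stencils at the two boundary frames (length preserved;
    exact for quadratic trajectories)."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 4:
        raise ValueError(f"need at least 4 frames to differentiate twice, "
                         f"got {x.shape[0]}")
    dt2 = (1.0 / rate_hz) ** 2
    a = np.empty_like(x)
    a[1:-1] = (x[2:] - 2.0 * x[1:-1] + x[:-2]) / dt2
    a[0] = (2.0 * x[0] - 5.0 * x[1] + 4.0 * x[2] - x[3]) / dt2
    a[-1] = (2.0 * x[-1] - 5.0 * x[-2] + 4.0 * x[-3] - x[-4]) / dt2
    return a


@dataclass
class SegmentKinematics:
    """Per-segment and whole-body COM position/acceleration series."""

    segment_names: list[str]
    com_position: np.ndarray      # (n_segments, n_frames, 3)
    com_acceleration: np.ndarray  # (n_segments, n_frames, 3)
    body_com: np.ndarray          # (n_frames, 3)
    rate_hz: float

    @property
    def n_frames(self) -> int:
        return self.body_com.shape[0]


def segment_kinematics(markers: MarkerTrajectorySet,
                       model: AnthropometricModel) -> SegmentKinematics:
    """Locate every segment COM from the marker locators and differentiate.

    Markers are assumed already low-pass filtered and in the canonical frame.
    The whole-body COM is the mass-weighted mean of the segment COMs.
    """
    if markers.n_frames < 4:
        raise ValueError("cannot differentiate a trial shorter than 4 frames")
    pos = []
    for seg in model.segments:
        p = np.zeros((markers.n_frames, 3))
        for label, w in seg.locator.items():
            p += w * markers.get(label)
        pos.append(p)
    com_position = np.stack(pos, axis=0)
    com_acceleration = np.stack(
        [second_derivative(p, markers.rate_hz) for p in pos], axis=0)
    m = model.masses[:, None, None]
    body_com = (m * com_position).sum(axis=0) / model.total_mass
    return SegmentKinematics(model.segment_names, com_position, com_acceleration,
                             body_com, markers.rate_hz)


def total_external_force(kin: SegmentKinematics,
                         model: AnthropometricModel) -> np.ndarray:
    """Total external force on the body, shape (n_frames, 3):
    F_ext = sum_i m_i a_i - M g."""
    if kin.segment_names != model.segment_names:
        raise ValueError("kinematics and model disagree on the segment set")
    m = model.masses[:, None, None]
    return (m * kin.com_acceleration).sum(axis=0) - model.total_mass * model.gravity
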