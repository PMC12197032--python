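"""Foot-deformation GRF/GRM/COP estimation.

The pipeline allocates the vertical component of the total external force
(from translational dynamics) to the 22 foot contact points according to each
point's distance to the ground:

    w_i = max(0, 1 - d_i / range_d)^k,   f_i = Fz_total * w_i / sum_j w_j

which yields per-foot vertical GRF, centre of pressure (COP) and the frontal /
sagittal ground reaction moments.  Horizontal GRFs are then reconstructed from
the virtual pivot point (VPP) assumption — the GRF vector passes through a
point 37.5 mm above the whole-body COM:

    (Fx, Fy) = Fz * (VPP_xy - COP_xy) / (VPP_z - ground)

and the transverse GRM is the moment of that force about the vertical axis
through the lab origin (free moment assumed zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import body as _body
from . import contact as _contact
from .io import MarkerTrajectorySet, filter_markers

__all__ = [
    "DistributionParams",
    "FDAConfig",
    "SideRecord",
    "GroundReactionRecord",
    "distribute_vertical",
    "cop_and_planar_moments",
    "horizontal_from_vpp",
    "transverse_moment",
    "estimate_grf",
]

VPP_HEIGHT = 0.0375  # m above the whole-body COM


@dataclass
class DistributionParams:
    """Distance-based load-sharing weights.

    range_d: distance (m) beyond which a point carries no load.
    exponent_k: sharpness of the weight falloff (>= 1).
    min_total_weight: total-weight floor below which the frame reads as no contact.
    """

    range_d: float = 0.030
    exponent_k: float = 2.0
    min_total_weight: float = 1e-9

    def __post_init__(self) -> None:
        if not self.range_d > 0:
            raise ValueError(f"range_d must be positive, got {self.range_d}")
        if not self.exponent_k >= 1:
            raise ValueError(f"exponent_k must be >= 1, got {self.exponent_k}")


@dataclass
class FDAConfig:
    """End-to-end configuration for estimate_grf."""

    cutoff_hz: float = 6.0
    filter_order: int = 4
    zero_phase: bool = True
    distribution: DistributionParams = field(default_factory=DistributionParams)
    vpp_height: float = VPP_HEIGHT
    contact_offset: float = _contact.DEFAULT_OFFSET
    ground_level: float | str = 0.0
    contact_threshold: float | None = None  # default: distribution.range_d
    normalize_by_mass: bool = False
    body_config: dict | str | None = None
    layout: dict | str | None = None


@dataclass
class SideRecord:
    """One foot's (or the total) reaction time series."""

    force: np.ndarray   # (n, 3) N
    moment: np.ndarray  # (n, 3) N*m about the lab origin (on the floor plane)
    cop: np.ndarray     # (n, 2) m, NaN where the foot is unloaded


@dataclass
class GroundReactionRecord:
    """Estimated per-foot and total GRF/GRM/COP series."""

    time: np.ndarray
    rate_hz: float
    left: SideRecord
    right: SideRecord
    total: SideRecord
    vpp_height: float = VPP_HEIGHT
    mass: float | None = None
    normalized: bool = False
    body_com: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.time.shape[0]

    def normalized_copy(self) -> "GroundReactionRecord":
        """Forces in N/kg, moments in N*m/kg (per-body-mass, figure style)."""
        if self.normalized:
            return self
        if self.mass is None:
            raise ValueError("cannot normalize a record with unknown body mass")

        def scale(side: SideRecord) -> SideRecord:
            return SideRecord(side.force / self.mass, side.moment / self.mass,
                              side.cop.copy())

        return replace(self, left=scale(self.left), right=scale(self.right),
                       total=scale(self.total), normalized=True)

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.time}
        for tag, side in (("l", self.left), ("r", self.right), ("total", self.total)):
            for j, comp in enumerate(("Fx", "Fy", "Fz")):
                data[f"{tag}_{comp}"] = side.force[:, j]
            for j, comp in enumerate(("Mx", "My", "Mz")):
                data[f"{tag}_{comp}"] = side.moment[:, j]
            data[f"{tag}_COPx"] = side.cop[:, 0]
            data[f"{tag}_COPy"] = side.cop[:, 1]
        return pd.DataFrame(data)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9f")

    @classmethod
    def from_csv(cls, path: str) -> "GroundReactionRecord":
        df = pd.read_csv(path)
        t = df["time"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError(f"GRF record {path!r} has fewer than 2 frames")
        rate = 1.0 / float(np.mean(np.diff(t)))

        def side(tag: str) -> SideRecord:
            force = df[[f"{tag}_Fx", f"{tag}_Fy", f"{tag}_Fz"]].to_numpy(float)
            moment = df[[f"{tag}_Mx", f"{tag}_My", f"{tag}_Mz"]].to_numpy(float)
            cop = df[[f"{tag}_COPx", f"{tag}_COPy"]].to_numpy(float)
            return SideRecord(force, moment, cop)

        return cls(t, rate, side("l"), side("r"), side("total"))


# ---------------------------------------------------------------------------
# stage operations


def distribute_vertical(fz_total: np.ndarray, distances: np.ndarray,
                        params: DistributionParams | None = None) -> np.ndarray:
    """Share the (clamped) vertical external force among contact points.

    fz_total: (n,) N, clamped at zero from below before distribution.
    distances: (n, n_points) heights above ground, >= 0.
    Returns per-point vertical forces (n, n_points); all-zero on frames where
    every point is out of range.
    """
    if params is None:
        params = DistributionParams()
    fz = np.maximum(0.0, np.asarray(fz_total, dtype=float))
    d = np.asarray(distances, dtype=float)
    w = np.maximum(0.0, 1.0 - d / params.range_d) ** params.exponent_k
    wsum = w.sum(axis=1)
    loaded = wsum > params.min_total_weight
    f = np.zeros_like(w)
    f[loaded] = fz[loaded, None] * w[loaded] / wsum[loaded, None]
    return f


def cop_and_planar_moments(f: np.ndarray, points: np.ndarray):
    """COP and frontal/sagittal moments of distributed vertical point forces.

    f: (n, n_points) vertical forces; points: (n, n_points, >=2) positions.
    Returns (cop (n,2) with NaN where unloaded, mx (n,), my (n,)); moments are
    about the lab origin on the floor plane: Mx = sum f_i y_i, My = -sum f_i x_i.
    """
    f = np.asarray(f, dtype=float)
    xy = np.asarray(points, dtype=float)[:, :, :2]
    fsum = f.sum(axis=1)
    mx = (f * xy[:, :, 1]).sum(axis=1)
    my = -(f * xy[:, :, 0]).sum(axis=1)
    cop = np.full((f.shape[0], 2), np.nan)
    loaded = fsum > 0
    cop[loaded, 0] = (f * xy[:, :, 0]).sum(axis=1)[loaded] / fsum[loaded]
    cop[loaded, 1] = (f * xy[:, :, 1]).sum(axis=1)[loaded] / fsum[loaded]
    return cop, mx, my


def horizontal_from_vpp(fz: np.ndarray, cop: np.ndarray, body_com: np.ndarray,
                        vpp_height: float = VPP_HEIGHT,
                        ground_level: float = 0.0) -> np.ndarray:
    """Horizontal GRF components from the virtual-pivot-point construction.

    The force line through the COP is required to pierce VPP = COM +
    (0, 0, vpp_height); similar triangles give
    (Fx, Fy) = Fz * (VPP_xy - COP_xy) / (VPP_z - ground).  Frames with Fz = 0
    (or undefined COP) return zero.  Returns (n, 2).
    """
    fz = np.asarray(fz, dtype=float)
    cop = np.asarray(cop, dtype=float)
    com = np.asarray(body_com, dtype=float)
    lever = com[:, 2] + vpp_height - ground_level
    loaded = fz > 0
    if np.any(lever[loaded] <= 0):
        raise ValueError("VPP lies at or below the ground on loaded frames; "
                         "nonphysical geometry (check up-axis and units)")
    out = np.zeros((fz.shape[0], 2))
    ok = loaded & ~np.isnan(cop).any(axis=1)
    out[ok] = fz[ok, None] * (com[ok, :2] + 0.0 - cop[ok]) / lever[ok, None]
    return out


def transverse_moment(cop: np.ndarray, force: np.ndarray) -> np.ndarray:
    """Transverse GRM about the vertical axis through the lab origin:
    Mz = COPx * Fy - COPy * Fx (free moment assumed zero).  Unloaded frames
    (NaN COP) return zero."""
    cop = np.asarray(cop, dtype=float)
    force = np.asarray(force, dtype=float)
    mz = cop[:, 0] * force[:, 1] - cop[:, 1] * force[:, 0]
    return np.where(np.isnan(mz), 0.0, mz)


# ---------------------------------------------------------------------------
# orchestration


def _stage(name: str):
    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise RuntimeError(f"GRF estimation failed in stage "
                                   f"'{name}': {exc}") from exc
            return False

    return _ctx()


def estimate_grf(dynamic_markers: MarkerTrajectorySet,
                 static_markers: MarkerTrajectorySet,
                 height: float, mass: float,
                 config: FDAConfig | None = None) -> GroundReactionRecord:
    """Run the full pipeline: filter -> segment kinematics -> external force ->
    contact distances (22 points pooled) -> distance-based vertical distribution
    -> per-foot COP/GRM -> VPP horizontal forces -> transverse GRM."""
    cfg = config or FDAConfig()
    params = cfg.distribution
    threshold = cfg.contact_threshold if cfg.contact_threshold is not None \
        else params.range_d

    with _stage("filtering"):
        dyn = filter_markers(dynamic_markers, cfg.cutoff_hz,
                             order=cfg.filter_order, zero_phase=cfg.zero_phase)

    with _stage("body model scaling"):
        model = _body.scale_model(height, mass, cfg.body_config)

    with _stage("contact calibration"):
        cps = {side: _contact.build_contact_points(
                   static_markers, side, cfg.layout,
                   offset=cfg.contact_offset, ground_level=cfg.ground_level)
               for side in ("left", "right")}
        ground = cps["left"].ground_level

    with _stage("segment kinematics"):
        kin = _body.segment_kinematics(dyn, model)
        fext = _body.total_external_force(kin, model)

    with _stage("contact distances"):
        series = {side: _contact.contact_distances(cps[side], dyn, threshold)
                  for side in ("left", "right")}
        dist_pool = np.hstack([series["left"].distances, series["right"].distances])
        pos_pool = np.concatenate([series["left"].positions,
                                   series["right"].positions], axis=1)

    with _stage("force distribution"):
        fz_total = np.maximum(0.0, fext[:, 2])
        f_pool = distribute_vertical(fz_total, dist_pool, params)

    n_left = series["left"].distances.shape[1]
    n = dyn.n_frames
    sides: dict[str, SideRecord] = {}
    with _stage("per-foot aggregation"):
        for side, sl in (("left", slice(0, n_left)), ("right", slice(n_left, None))):
            f_side = f_pool[:, sl]
            cop, mx, my = cop_and_planar_moments(f_side, pos_pool[:, sl])
            fz = f_side.sum(axis=1)
            fh = horizontal_from_vpp(fz, cop, kin.body_com,
                                     cfg.vpp_height, ground)
            force = np.column_stack([fh, fz])
            mz = transverse_moment(cop, force)
            sides[side] = SideRecord(force, np.column_stack([mx, my, mz]), cop)

    with _stage("totals"):
        cop_tot, mx_t, my_t = cop_and_planar_moments(f_pool, pos_pool)
        force_tot = sides["left"].force + sides["right"].force
        mz_t = sides["left"].moment[:, 2] + sides["right"].moment[:, 2]
        total = SideRecord(force_tot, np.column_stack([mx_t, my_t, mz_t]), cop_tot)

    rec = GroundReactionRecord(
        time=np.arange(n) / dyn.rate_hz, rate_hz=dyn.rate_hz,
        left=sides["left"], right=sides["right"], total=total,
        vpp_height=cfg.vpp_height, mass=mass, body_com=kin.body_com)
    if cfg.normalize_by_mass:
        rec = rec.normalized_copy()
    return rec
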