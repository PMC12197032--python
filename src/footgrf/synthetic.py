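"""Synthetic level-walking trials with dynamically consistent ground truth.

The generator emulates the validation experiment's conditions: a 49-marker
Gait-2392-style full-body set sampled at 100 Hz, level walking at three speed
classes (0.8x / 1.0x / 1.2x of a preferred speed), and footwear sole-thickness
offsets (sneaker 38 mm, running shoe 44 mm, barefoot 0).  Every trial carries
marker trajectories, a matching static calibration trial, heel-strike/toe-off
events, and ground-truth per-foot GRF/GRM/COP that satisfy Newton's
translational law by construction:

* vertical: per-foot double-bump stance profiles are scaled so the two-foot sum
  integrates to body weight over the cycle; the COM height is the double
  integral of the implied acceleration;
* horizontal: per-foot COP templates progress heel-to-toe, and the horizontal
  COM dynamics are the exact periodic orbit of the virtual-pivot-point (VPP)
  equations x'' = k(t) (x - u(t)) (an inverted-pendulum template), solved by a
  linear two-point boundary method — so the truth force lines pass through
  COM + 37.5 mm exactly and total horizontal force equals M a_xy exactly.

Markers are placed by rigid per-segment clouds consistent with the default
body-model locators; the lumped torso/head/arms (HAT) segment is positioned so
that the model's mass-weighted COM reproduces the truth COM at every frame.
Footwear is emulated by raising the foot marker clouds by the sole thickness
and adding a deterministic sole-compliance lateral wobble of the foot markers
proportional to sole thickness and load, which degrades medio-lateral contact
geometry the way compliant soles do.  Optional Gaussian marker noise is seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import body as _body
from . import contact as _contact
from .estimator import GroundReactionRecord, SideRecord, VPP_HEIGHT
from .io import MarkerTrajectorySet

__all__ = ["GaitScenario", "SyntheticTrial", "generate_trial", "make_static_trial"]

SPEED_MULTIPLIERS = {"slow": 0.8, "normal": 1.0, "fast": 1.2}
SOLE_THICKNESS = {"barefoot": 0.0, "sneaker": 0.038, "running": 0.044}

_G = 9.80665
_FLAT_END = 0.62           # stance fraction: flat -> forefoot rocker
_THETA_HS = 0.35       # rad toe-up pitch at heel strike
_THETA_TO = 0.50       # rad toe-down pitch at toe off
_MET_PIVOT_X = 0.225   # m, rollover pivot just distal to the toe contact points
_TOE_X = 0.21          # m, toe ground-contact point (foot-local)
_SWING_CLEARANCE = 0.07
_EASE_HS = 0.6         # heel-rocker decay easing: rapid foot-flat after contact
_EASE_TO = 2.4         # push-off easing: heel rise starts late, accelerates
_SOLE_WOBBLE_GAIN = 0.25   # lateral marker excursion per metre of sole at full load


@dataclass
class GaitScenario:
    """Study conditions for one synthetic walking trial."""

    speed_class: str = "normal"
    shoe: str = "barefoot"
    sole_thickness: float | None = None  # m; None -> from shoe class
    height: float = 1.66   # m, study mean
    mass: float = 61.6     # kg, study mean
    cadence: float | None = None      # steps/min; None -> 110 * sqrt(mult)
    step_length: float | None = None  # m; None -> speed * step time
    noise_sd: float = 0.0  # m, isotropic Gaussian marker noise
    seed: int = 0
    n_strides: int = 3
    rate_hz: float = 100.0
    base_speed: float = 1.30       # m/s preferred walking speed
    stance_fraction: float = 0.62
    step_width: float = 0.18       # m between foot centres
    vpp_consistent: bool = True    # False: pendulum-mode horizontal truth

    def __post_init__(self) -> None:
        if self.speed_class not in SPEED_MULTIPLIERS:
            raise ValueError(f"speed_class must be one of {set(SPEED_MULTIPLIERS)}")
        if self.shoe not in SOLE_THICKNESS:
            raise ValueError(f"shoe must be one of {set(SOLE_THICKNESS)}")
        if self.sole_thickness is None:
            self.sole_thickness = SOLE_THICKNESS[self.shoe]
        if self.sole_thickness < 0 or self.noise_sd < 0:
            raise ValueError("sole_thickness and noise_sd must be non-negative")
        if self.n_strides < 2:
            raise ValueError("need at least 2 strides for a well-posed trial")

    @property
    def speed_multiplier(self) -> float:
        return SPEED_MULTIPLIERS[self.speed_class]

    @property
    def speed(self) -> float:
        return self.base_speed * self.speed_multiplier

    def timing(self):
        """(stride period s, frames per cycle, step length m) on the frame grid."""
        cadence = self.cadence if self.cadence is not None \
            else 110.0 * math.sqrt(self.speed_multiplier)
        stride_t = 2.0 * 60.0 / cadence
        n_cycle = int(round(stride_t * self.rate_hz))
        stride_t = n_cycle / self.rate_hz
        step_len = self.step_length if self.step_length is not None \
            else self.speed * stride_t / 2.0
        if step_len <= 0 or step_len > 0.55 * self.height:
            raise ValueError(f"step length {step_len:.3f} m is infeasible for a "
                             f"{self.height:.2f} m participant")
        return stride_t, n_cycle, step_len


@dataclass
class SyntheticTrial:
    """A generated walking trial plus its ground truth."""

    scenario: GaitScenario
    markers: MarkerTrajectorySet
    static_markers: MarkerTrajectorySet
    truth: GroundReactionRecord
    events: dict
    com: np.ndarray           # (n, 3) truth whole-body COM
    com_velocity: np.ndarray  # (n, 3)


# ---------------------------------------------------------------------------
# small helpers


def _smoothstep(s):
    s = np.clip(s, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def _ramp_profile(s: np.ndarray, contrast: float, ramp: float) -> np.ndarray:
    """Double-bump stance profile on s in [0,1]: quarter-sine load-transfer
    ramps of width ``ramp`` (the double-support fraction of stance — a steep
    rise at contact that tapers toward full load, the mirror image into toe
    off) times a midstance-valley shape; zero outside stance."""
    e = np.ones_like(s)
    lo = (s >= 0) & (s < ramp)
    hi = (s > 1.0 - ramp) & (s <= 1)
    e[lo] = np.sin(0.5 * np.pi * s[lo] / ramp)
    e[hi] = np.sin(0.5 * np.pi * (1.0 - s[hi]) / ramp)
    shape = 1.0 - contrast * np.cos(2.0 * np.pi * (s - 0.5))
    out = e * shape
    out[(s < 0) | (s > 1)] = 0.0
    return out


def _pitch_matrix(theta: float) -> np.ndarray:
    """Rotation about the lab y axis; positive theta pitches the toe up."""
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])


def _foot_phase(t: np.ndarray, offset: float, stride_t: float,
                stance_t: float, x0: float, stride_len: float):
    """Per-frame stance phase s (in [0,1] during stance, else swing phase in
    [0,1]), in_stance mask, and the stance/previous-stance heel anchor x."""
    rel = t - offset
    k = np.floor(rel / stride_t)
    tau = rel - k * stride_t
    in_stance = tau < stance_t
    s = np.where(in_stance, tau / stance_t,
                 (tau - stance_t) / (stride_t - stance_t))
    anchor = x0 + k * stride_len
    return s, in_stance, anchor


# ---------------------------------------------------------------------------
# cycle-level truth construction


def _build_cycle(scn: GaitScenario):
    """All ground-truth series on one gait cycle (length n_cycle)."""
    fs = scn.rate_hz
    stride_t, n_cycle, step_len = scn.timing()
    stride_len = 2.0 * step_len
    stance_t = scn.stance_fraction * stride_t
    dt = 1.0 / fs
    tau = np.arange(n_cycle) * dt
    mass = scn.mass

    contrast = 0.25 * scn.speed_multiplier ** 1.5
    if scn.stance_fraction <= 0.5:
        raise ValueError("stance_fraction must exceed 0.5: walking requires "
                         "double support")
    ramp = 1.0 - 0.5 / scn.stance_fraction  # double-support fraction of stance
    feet = {}
    for side, offset, x0, y_a in (("right", 0.0, 0.0, -scn.step_width / 2.0),
                                  ("left", stride_t / 2.0, stride_len / 2.0,
                                   scn.step_width / 2.0)):
        s, in_st, anchor = _foot_phase(tau, offset, stride_t, stance_t,
                                       x0, stride_len)
        profile = np.where(in_st, _ramp_profile(np.where(in_st, s, 0.0),
                                                contrast, ramp), 0.0)
        medial = 1.0 if side == "right" else -1.0
        prog = _smoothstep(s)
        cop_x = anchor + 0.02 + 0.18 * prog
        cop_y = y_a + medial * (-0.012 + 0.030 * prog)
        feet[side] = dict(s=s, in_stance=in_st, anchor=anchor, y_a=y_a,
                          profile=profile, cop=np.stack([cop_x, cop_y], axis=1))

    total_profile = feet["left"]["profile"] + feet["right"]["profile"]
    if total_profile.min() <= 0:
        raise ValueError("infeasible cadence/stance combination: the synthetic "
                         "gait has a flight phase")
    c = mass * _G * n_cycle / total_profile.sum()
    fz_tot = c * total_profile
    for side in feet:
        feet[side]["fz"] = c * feet[side]["profile"]

    # vertical COM: periodic double integration of az = Fz/M - g
    az = fz_tot / mass - _G
    vz = np.concatenate([[0.0], np.cumsum(0.5 * (az[:-1] + az[1:])) * dt])
    # close the cycle: append the wrap step, then remove the mean
    vz = vz[:n_cycle]
    vz -= vz.mean()
    z = np.concatenate([[0.0], np.cumsum(0.5 * (vz[:-1] + vz[1:])) * dt])[:n_cycle]
    z0 = 0.57 * scn.height
    z += z0 - z.mean()

    # horizontal COM: periodic orbit of x'' = k(t) (x - u(t))
    lever = z + VPP_HEIGHT
    k_arr = fz_tot / (mass * lever)
    w = np.stack([feet["left"]["fz"], feet["right"]["fz"]], axis=1) / fz_tot[:, None]
    u_xy = (w[:, 0:1] * feet["left"]["cop"] + w[:, 1:2] * feet["right"]["cop"])

    if scn.vpp_consistent:
        x, vx, ax = _periodic_pendulum(k_arr, u_xy[:, 0], dt, stride_len)
        y, vy, ay = _periodic_pendulum(k_arr, u_xy[:, 1], dt, 0.0)
    else:
        # pendulum-mode: smooth prescribed horizontal COM; the VPP relation is
        # deliberately violated (truth horizontal force = M a directly)
        mean_v = stride_len / stride_t
        x = mean_v * tau + 0.01 * np.sin(4.0 * np.pi * tau / stride_t)
        vx = mean_v + 0.01 * (4.0 * np.pi / stride_t) * np.cos(4.0 * np.pi * tau / stride_t)
        ax = -0.01 * (4.0 * np.pi / stride_t) ** 2 * np.sin(4.0 * np.pi * tau / stride_t)
        y = -0.02 * np.sin(2.0 * np.pi * tau / stride_t)
        vy = -0.02 * (2.0 * np.pi / stride_t) * np.cos(2.0 * np.pi * tau / stride_t)
        ay = 0.02 * (2.0 * np.pi / stride_t) ** 2 * np.sin(2.0 * np.pi * tau / stride_t)

    com = np.stack([x, y, z], axis=1)
    com_v = np.stack([vx, vy, vz], axis=1)

    # per-foot horizontal forces through the VPP (or M a split by load share)
    for side in feet:
        fz = feet[side]["fz"]
        if scn.vpp_consistent:
            fh = fz[:, None] * (com[:, :2] - feet[side]["cop"]) / lever[:, None]
        else:
            share = fz / fz_tot
            fh = share[:, None] * (mass * np.stack([ax, ay], axis=1))
        feet[side]["fh"] = np.where(fz[:, None] > 0, fh, 0.0)

    return dict(stride_t=stride_t, n_cycle=n_cycle, step_len=step_len,
                stride_len=stride_len, stance_t=stance_t, feet=feet, ramp=ramp,
                fz_tot=fz_tot, com=com, com_v=com_v,
                a=np.stack([ax, ay, az], axis=1))


def _periodic_pendulum(k_arr: np.ndarray, u: np.ndarray, dt: float,
                       drift: float):
    """Exact periodic orbit of x'' = k(t)(x - u(t)) with x(T) = x(0) + drift.

    The equation is affine in the state, so one RK4 pass with zero initial
    state plus two homogeneous passes give the cycle map; the periodic initial
    state solves a 2x2 linear system.  Returns (x, v, a) on the cycle grid.
    """
    n = k_arr.shape[0]
    k_ext = np.append(k_arr, k_arr[0])
    u_ext = np.append(u, u[0] + drift)

    def integrate(x0, v0, affine):
        xs = np.empty(n + 1)
        vs = np.empty(n + 1)
        xs[0], vs[0] = x0, v0
        for i in range(n):
            k0, k1 = k_ext[i], k_ext[i + 1]
            u0, u1 = (u_ext[i], u_ext[i + 1]) if affine else (0.0, 0.0)
            kh, uh = 0.5 * (k0 + k1), 0.5 * (u0 + u1)
            x0_, v0_ = xs[i], vs[i]
            a1 = k0 * (x0_ - u0)
            x2, v2 = x0_ + 0.5 * dt * v0_, v0_ + 0.5 * dt * a1
            a2 = kh * (x2 - uh)
            x3, v3 = x0_ + 0.5 * dt * v2, v0_ + 0.5 * dt * a2
            a3 = kh * (x3 - uh)
            x4, v4 = x0_ + dt * v3, v0_ + dt * a3
            a4 = k1 * (x4 - u1)
            xs[i + 1] = x0_ + dt / 6.0 * (v0_ + 2 * v2 + 2 * v3 + v4)
            vs[i + 1] = v0_ + dt / 6.0 * (a1 + 2 * a2 + 2 * a3 + a4)
        return xs, vs

    px, pv = integrate(0.0, 0.0, affine=True)
    h1x, h1v = integrate(1.0, 0.0, affine=False)
    h2x, h2v = integrate(0.0, 1.0, affine=False)
    bmat = np.array([[h1x[-1], h2x[-1]], [h1v[-1], h2v[-1]]])
    rhs = np.array([drift - px[-1], -pv[-1]])
    s0 = np.linalg.solve(bmat - np.eye(2), rhs)
    xs, vs = integrate(s0[0], s0[1], affine=True)
    x, v = xs[:n], vs[:n]
    a = k_arr * (x - u)
    return x, v, a


# ---------------------------------------------------------------------------
# marker construction

# foot-local marker clouds; origin at the heel ground-contact point, x forward,
# y medial-positive (mirrored for the left foot)
_FOOT_CLOUD = {
    "Heel": (-0.010, 0.000, 0.045),
    "Midfoot.Sup": (0.100, 0.015, 0.055),
    "Midfoot.Lat": (0.090, -0.045, 0.025),
    "Toe.Lat": (0.170, -0.040, 0.022),
    "Toe.Med": (0.170, 0.035, 0.022),
    "Toe.Tip": (0.220, 0.000, 0.018),
}
_ANKLE_LOCAL = (0.020, 0.000, 0.065)

_HAT_CLOUD = {
    "Sternum": (0.09, 0.00, 0.45),
    "Clavicle": (0.08, 0.00, 0.52),
    "C7": (-0.06, 0.00, 0.55),
    "R.Acromion": (0.00, -0.20, 0.53),
    "L.Acromion": (0.00, 0.20, 0.53),
    "Top.Head": (0.01, 0.00, 0.82),
    "Front.Head": (0.09, 0.00, 0.73),
    "Rear.Head": (-0.08, 0.00, 0.73),
    "R.Bicep": (0.02, -0.24, 0.38),
    "R.Elbow": (0.01, -0.26, 0.24),
    "R.Wrist": (0.03, -0.27, 0.05),
    "L.Bicep": (0.02, 0.24, 0.38),
    "L.Elbow": (0.01, 0.26, 0.24),
    "L.Wrist": (0.03, 0.27, 0.05),
}
_HAT_LOCATOR = {"Sternum": 0.35, "C7": 0.25, "R.Acromion": 0.20, "L.Acromion": 0.20}

_PELVIS_CLOUD = {
    "R.ASIS": (0.08, -0.12, 0.02),
    "L.ASIS": (0.08, 0.12, 0.02),
    "V.Sacral": (-0.11, 0.00, 0.03),
}
_HIP_LOCAL = {"right": (0.0, -0.09, -0.06), "left": (0.0, 0.09, -0.06)}


def _foot_local_cloud(side: str, sole: float) -> dict[str, np.ndarray]:
    sign = 1.0 if side == "right" else -1.0
    pre = "R." if side == "right" else "L."
    return {pre + name: np.array([x, sign * y, z + sole])
            for name, (x, y, z) in _FOOT_CLOUD.items()}


def _foot_transform(s: float, in_stance: bool, anchor_x: float, y_a: float,
                    stride_len: float, heel_rocker_end: float = 0.19):
    """(rotation, origin) of the foot-local frame at one frame; the heel
    rocker spans the double-support fraction of stance."""
    if in_stance:
        if s < heel_rocker_end:
            theta = _THETA_HS * (1.0 - _smoothstep(s / heel_rocker_end)) ** _EASE_HS
            pivot_w = np.array([anchor_x, y_a, 0.0])
            pivot_l = np.zeros(3)
        elif s < _FLAT_END:
            theta = 0.0
            pivot_w = np.array([anchor_x, y_a, 0.0])
            pivot_l = np.zeros(3)
        else:
            theta = -_THETA_TO * _smoothstep(
                (s - _FLAT_END) / (1.0 - _FLAT_END)) ** _EASE_TO
            pivot_w = np.array([anchor_x + _MET_PIVOT_X, y_a, 0.0])
            pivot_l = np.array([_MET_PIVOT_X, 0.0, 0.0])
        rot = _pitch_matrix(theta)
        origin = pivot_w - rot @ pivot_l
        return rot, origin
    # swing: plantarflexion unwinds quickly after toe off, the foot clears the
    # ground near neutral pitch, then dorsiflexes toward the heel-strike pose;
    # the vertical path is set so the lowest sole point (heel or toe) follows
    # an explicit clearance profile, continuous with the toe-off pose
    u = s
    theta = -_THETA_TO * (1.0 - _smoothstep(u / 0.3)) \
        + _THETA_HS * _smoothstep((u - 0.55) / 0.45)
    rot_off = _pitch_matrix(-_THETA_TO)
    o_off = np.array([anchor_x + _MET_PIVOT_X, y_a, 0.0]) \
        - rot_off @ np.array([_MET_PIVOT_X, 0.0, 0.0])
    o_hs = np.array([anchor_x + stride_len, y_a, 0.0])
    blend = _smoothstep(u)
    origin = o_off + blend * (o_hs - o_off)
    toe_drop = min(0.0, math.sin(theta) * _TOE_X)
    z_start = math.sin(-_THETA_TO) * (_TOE_X - _MET_PIVOT_X)
    clearance = z_start * (1.0 - _smoothstep(u / 0.25)) \
        + _SWING_CLEARANCE * math.sin(math.pi * u) ** 1.2
    origin[2] = clearance - toe_drop
    return _pitch_matrix(theta), origin


def _two_link_ik(hip: np.ndarray, ankle: np.ndarray, l1: float, l2: float):
    """Knee-joint position bending forward (+x); clamps at near-full extension."""
    d_vec = ankle - hip
    d = np.linalg.norm(d_vec)
    d_max = 0.999 * (l1 + l2)
    if d > d_max:
        d_vec = d_vec * (d_max / d)
        d = d_max
        ankle = hip + d_vec
    alpha = (l1 * l1 - l2 * l2 + d * d) / (2.0 * d * d)
    beta_sq = l1 * l1 - alpha * alpha * d * d
    beta = math.sqrt(max(0.0, beta_sq))
    fwd = np.array([1.0, 0.0, 0.0])
    fwd = fwd - (fwd @ d_vec) / (d * d) * d_vec
    n = np.linalg.norm(fwd)
    fwd = fwd / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])
    return hip + alpha * d_vec + beta * fwd


def _leg_markers(side: str, hip: np.ndarray, ankle: np.ndarray, height: float):
    l1, l2 = 0.245 * height, 0.246 * height
    knee = _two_link_ik(hip, ankle, l1, l2)
    lat = -1.0 if side == "right" else 1.0  # lateral = away from the midline
    pre = "R." if side == "right" else "L."
    out = {}
    thigh, shank = knee - hip, ankle - knee
    out[pre + "Thigh.Upper"] = hip + 0.30 * thigh + np.array([0.00, lat * 0.06, 0.0])
    out[pre + "Thigh.Front"] = hip + 0.55 * thigh + np.array([0.06, lat * 0.02, 0.0])
    out[pre + "Thigh.Rear"] = hip + 0.75 * thigh + np.array([-0.05, lat * 0.03, 0.0])
    out[pre + "Knee.Lat"] = knee + np.array([0.0, lat * 0.055, 0.0])
    out[pre + "Knee.Med"] = knee + np.array([0.0, -lat * 0.055, 0.0])
    out[pre + "Shank.Upper"] = knee + 0.25 * shank + np.array([0.04, lat * 0.04, 0.0])
    out[pre + "Shank.Front"] = knee + 0.50 * shank + np.array([0.05, 0.0, 0.0])
    out[pre + "Shank.Rear"] = knee + 0.70 * shank + np.array([-0.04, lat * 0.02, 0.0])
    out[pre + "Ankle.Lat"] = ankle + np.array([0.0, lat * 0.045, 0.0])
    out[pre + "Ankle.Med"] = ankle + np.array([0.0, -lat * 0.045, 0.0])
    return out


def _assemble_frames(scn: GaitScenario, model, com_target: np.ndarray,
                     foot_pose_fn, n_frames: int) -> np.ndarray:
    """Place all 49 markers frame by frame so the model COM equals com_target.

    foot_pose_fn(i, side) -> (rot, origin, wobble_y) gives each foot's rigid
    pose (plus the sole-compliance lateral offset) at frame i.
    """
    labels = model.marker_set
    idx = {l: j for j, l in enumerate(labels)}
    pos = np.zeros((n_frames, len(labels), 3))
    clouds = {side: _foot_local_cloud(side, scn.sole_thickness)
              for side in ("left", "right")}
    hat_local = np.array([_HAT_CLOUD[l] for l in _HAT_CLOUD])
    hat_locator_local = sum(w * np.array(_HAT_CLOUD[l])
                            for l, w in _HAT_LOCATOR.items())
    seg_by_name = {s.name: s for s in model.segments}
    m_hat = seg_by_name["hat"].mass

    pelvis_z0 = 0.47 * scn.height
    com_z_mean = float(com_target[:, 2].mean())

    for i in range(n_frames):
        frame: dict[str, np.ndarray] = {}
        for side in ("left", "right"):
            rot, origin, wob = foot_pose_fn(i, side)
            for lab, loc in clouds[side].items():
                frame[lab] = origin + rot @ loc + np.array([0.0, wob, 0.0])
        po = np.array([com_target[i, 0] - 0.02, com_target[i, 1],
                       pelvis_z0 + (com_target[i, 2] - com_z_mean)])
        for lab, loc in _PELVIS_CLOUD.items():
            frame[lab] = po + np.array(loc)
        for side in ("left", "right"):
            pre = "R." if side == "right" else "L."
            hip = po + np.array(_HIP_LOCAL[side])
            rot, origin, wob = foot_pose_fn(i, side)
            ankle_local = np.array([_ANKLE_LOCAL[0],
                                    _ANKLE_LOCAL[1],
                                    _ANKLE_LOCAL[2] + scn.sole_thickness])
            ankle = origin + rot @ ankle_local + np.array([0.0, wob, 0.0])
            frame.update(_leg_markers(side, hip, ankle, scn.height))
        # place the HAT so the whole-body COM hits the target exactly
        partial = np.zeros(3)
        for seg in model.segments:
            if seg.name == "hat":
                continue
            p = np.zeros(3)
            for lab, w in seg.locator.items():
                p += w * frame[lab]
            partial += seg.mass * p
        hat_com = (model.total_mass * com_target[i] - partial) / m_hat
        h = hat_com - hat_locator_local
        for lab, loc in zip(_HAT_CLOUD, hat_local):
            frame[lab] = h + loc
        for lab, p in frame.items():
            pos[i, idx[lab]] = p
    return pos


# ---------------------------------------------------------------------------
# public generators


def make_static_trial(scenario: GaitScenario, duration: float = 1.2,
                      rng: np.random.Generator | None = None) -> MarkerTrajectorySet:
    """Motionless anatomical standing pose, feet flat and hip-width apart,
    with the whole-body COM directly above the contact-point centroid."""
    scn = scenario
    model = _body.scale_model(scn.height, scn.mass)
    n = max(int(round(duration * scn.rate_hz)), 10)

    layout = _contact.load_layout()
    pts = np.array(list(layout["points"].values()))
    heel_local_x = _FOOT_CLOUD["Heel"][0]
    anchor_x = -0.11
    # layout frame origin = heel marker ground projection = anchor + heel_local_x
    centroid_x = anchor_x + heel_local_x + pts[:, 0].mean()
    com_target = np.tile([centroid_x, 0.0, 0.57 * scn.height], (n, 1))

    def pose(i, side):
        y_a = -scn.step_width / 2.0 if side == "right" else scn.step_width / 2.0
        return np.eye(3), np.array([anchor_x, y_a, 0.0]), 0.0

    pos = _assemble_frames(scn, model, com_target, pose, n)
    if scn.noise_sd > 0:
        rng = rng or np.random.default_rng(scn.seed)
        pos = pos + rng.normal(0.0, scn.noise_sd, pos.shape)
    return MarkerTrajectorySet(list(model.marker_set), pos, scn.rate_hz)


def generate_trial(scenario: GaitScenario) -> SyntheticTrial:
    """Generate a complete synthetic walking trial (markers + ground truth)."""
    scn = scenario
    cyc = _build_cycle(scn)
    fs = scn.rate_hz
    n_cycle = cyc["n_cycle"]
    stride_t, stride_len = cyc["stride_t"], cyc["stride_len"]
    stance_t = cyc["stance_t"]
    n = scn.n_strides * n_cycle
    t = np.arange(n) / fs
    reps = scn.n_strides

    def tile(a, drift=0.0):
        out = np.tile(a, (reps,) + (1,) * (a.ndim - 1)) if a.ndim > 1 \
            else np.tile(a, reps)
        if drift:
            shift = np.repeat(np.arange(reps) * drift, n_cycle)
            if a.ndim > 1:
                out = out.copy()
                out[:, 0] += shift
            else:
                out = out + shift
        return out

    com = tile(cyc["com"], drift=stride_len)
    com_v = tile(cyc["com_v"])
    model = _body.scale_model(scn.height, scn.mass)

    # ground truth record
    sides = {}
    fz_tot = tile(cyc["fz_tot"])
    for side in ("left", "right"):
        foot = cyc["feet"][side]
        fz = tile(foot["fz"])
        fh = tile(foot["fh"])
        cop = tile(foot["cop"], drift=stride_len)
        cop = np.where(fz[:, None] > 0, cop, np.nan)
        force = np.column_stack([fh, fz])
        mx = np.where(fz > 0, cop[:, 1] * fz, 0.0)
        my = np.where(fz > 0, -cop[:, 0] * fz, 0.0)
        mz = np.where(fz > 0, cop[:, 0] * fh[:, 1] - cop[:, 1] * fh[:, 0], 0.0)
        sides[side] = SideRecord(force, np.column_stack([mx, my, mz]), cop)
    tot_force = sides["left"].force + sides["right"].force
    tot_moment = sides["left"].moment + sides["right"].moment
    with np.errstate(invalid="ignore"):
        tot_cop = np.stack([-tot_moment[:, 1] / tot_force[:, 2],
                            tot_moment[:, 0] / tot_force[:, 2]], axis=1)
    truth = GroundReactionRecord(
        time=t, rate_hz=fs, left=sides["left"], right=sides["right"],
        total=SideRecord(tot_force, tot_moment, tot_cop),
        vpp_height=VPP_HEIGHT, mass=scn.mass, body_com=com)

    # markers
    pose_cache: dict[tuple[int, str], tuple] = {}

    def pose(i, side):
        key = (i, side)
        if key not in pose_cache:
            offset = 0.0 if side == "right" else stride_t / 2.0
            x0 = 0.0 if side == "right" else stride_len / 2.0
            y_a = -scn.step_width / 2.0 if side == "right" else scn.step_width / 2.0
            ti = np.array([t[i]])
            s, in_st, anchor = _foot_phase(ti, offset, stride_t, stance_t,
                                           x0, stride_len)
            rot, origin = _foot_transform(float(s[0]), bool(in_st[0]),
                                          float(anchor[0]), y_a, stride_len,
                                          heel_rocker_end=cyc["ramp"])
            foot = cyc["feet"][side]
            load = foot["fz"][i % n_cycle] / (scn.mass * _G)
            medial = 1.0 if side == "right" else -1.0
            wob = _SOLE_WOBBLE_GAIN * scn.sole_thickness * load \
                * math.sin(2.0 * math.pi * float(s[0])) * medial \
                if in_st[0] else 0.0
            pose_cache[key] = (rot, origin, wob)
        return pose_cache[key]

    pos = _assemble_frames(scn, model, com, pose, n)
    rng = np.random.default_rng(scn.seed)
    if scn.noise_sd > 0:
        pos = pos + rng.normal(0.0, scn.noise_sd, pos.shape)
    markers = MarkerTrajectorySet(list(model.marker_set), pos, fs)
    static = make_static_trial(scn, rng=rng)

    events = {side: {"heel_strike": [], "toe_off": []} for side in ("left", "right")}
    for k in range(-1, scn.n_strides + 1):
        for side, offset in (("right", 0.0), ("left", stride_t / 2.0)):
            hs = offset + k * stride_t
            to = hs + stance_t
            if 0.0 <= hs < t[-1]:
                events[side]["heel_strike"].append(hs)
            if 0.0 <= to < t[-1]:
                events[side]["toe_off"].append(to)

    return SyntheticTrial(scn, markers, static, truth, events, com, com_v)
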