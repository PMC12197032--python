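# Methods

## Estimation model

`footgrf` implements the foot deformation approach to GRF/GRM/COP estimation
from marker kinematics. The chain is:

1. **Filtering.** Marker trajectories are low-pass filtered with a Butterworth
   filter, fourth order net, −3 dB at 6 Hz (the standard gait bandwidth at a
   100 Hz capture rate). Filtering is zero-phase (forward–backward) by
   default, with the per-pass corner widened by `(√2 − 1)^(−1/(2n))` so the
   net magnitude is −3 dB at the nominal cutoff; a causal single-pass mode is
   selectable for users who must match on-line processing. Force-plate records
   are filtered the same way at 18 Hz / 1000 Hz and decimated after filtering
   when compared against 100 Hz predictions.

2. **Translational dynamics.** A segment mass-fraction table keyed to the
   Gait 2392 segment set (pelvis, two femora, two tibiae, two feet with toes
   merged, and a lumped head–arms–torso "HAT" segment; fractions from the
   model's segment masses, normalised) is scaled so Σ m_i equals the
   participant's mass. Segment COMs are located by fixed convex combinations
   of marker positions (e.g. the femur COM at a fixed fraction along the
   hip–knee line); the table and locators ship as editable YAML
   (`src/footgrf/data/body_model.yaml`). Accelerations are central second
   differences with second-order one-sided stencils at the two boundary
   frames (exact for quadratic trajectories, series length preserved), and

       F_ext = Σ m_i a_i − M g ,   g = (0, 0, −9.80665) m/s² exactly.

   The rotational equation of motion is excluded by design, so no segment
   moments of inertia enter. Full inverse kinematics is deliberately replaced
   by the direct marker-locator scheme: it is dependency-free and fast, at the
   cost of an unquantified (small) difference between locator COMs and
   model-based COMs on real data — a validation caveat, not an error term the
   synthetic tests can see, because the generator places markers consistently
   with the same locators.

3. **Contact geometry.** Eleven contact points per foot (two medially shifted
   heel points, two midfoot points, a four-point metatarsal arc, three toe
   points including a medial toe point) are defined in a foot-local sole frame
   (`src/footgrf/data/contact_layout.yaml`). The published layout figure has
   no millimetre coordinates, so the shipped table is an explicit, editable
   approximation. During a static standing calibration each point is pinned
   10 mm below the ground plane ("toward the ground"), absorbing sole
   thickness and marker mounting height. Dynamic reconstruction uses a
   per-frame least-squares rigid (Kabsch) fit of the calibration foot-marker
   cloud, so the layout is exactly equivariant under rigid foot motion and
   robust to isotropic marker jitter. Distances to the floor are floored at
   zero: sole penetration reads as full contact.

4. **Force distribution.** The clamped vertical external force is shared over
   all 22 points with compactly supported, monotone weights
   `w_i = max(0, 1 − d_i/r)^k`, defaults r = 30 mm, k = 2. The source for the
   distance-based rule does not print its functional form; this smooth
   minimal choice is declared as an interpretation and both parameters are
   config-exposed. Pooling both feet makes double support need no special
   case, and per-foot sums conserve the total exactly. Per-foot COP is the
   force-weighted centroid; frontal/sagittal GRMs are the moments of the
   distributed vertical forces about the lab origin (on the floor plane).

5. **VPP reconstruction.** Horizontal GRFs are set so each foot's force line
   passes through the whole-body COM + 37.5 mm (one VPP, shared by both
   feet); the transverse GRM is the moment of that force at the COP about the
   vertical axis, with the free moment taken as zero. Whether per-foot
   horizontal forces should be computed foot-wise or from the pooled COP is
   not specified by the method's source; foot-wise is implemented.

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `cutoff_hz` | 6 (markers), 18 (plate) | Hz | Butterworth −3 dB point, order 4 net |
| `contact_offset` | 0.010 | m | calibration offset toward the ground |
| `range_d` | 0.030 | m | distance beyond which a point carries no load |
| `exponent_k` | 2 | — | weight sharpness |
| `vpp_height` | 0.0375 | m | VPP height above the whole-body COM |
| `ground_level` | 0.0 | m | floor height; `"auto"` = static minimum |
| `contact_threshold` | `range_d` | m | in-contact flag for reporting |
| stance threshold | 20 | N | plate stance detection in validation |

The lab frame is x anterior, y to the participant's left, z up, with the floor
at z = 0 (the force-plate convention); readers convert TRC's mm/Y-up on
ingest. `ground_level="auto"` (static minimum of the sole points) covers labs
whose origin is not on the floor. GRMs are reported about the lab origin; a
config switch reports about the COP instead (then Mx = My = 0 identically).

## Synthetic gait generator

The generator (`footgrf.synthetic`) emulates the validation study's
conditions: 49-marker full-body set at 100 Hz, walking at 0.8×/1.0×/1.2× of a
1.30 m/s preferred speed (cadence 110·√mult steps/min, stance fraction 0.62,
step width 0.18 m), participant height 1.66 m and mass 61.6 kg (study means),
and sole thicknesses 0 / 38 / 44 mm for barefoot / sneaker / running shoe.
Ground truth is dynamically consistent by construction:

* **Vertical.** Per-foot stance profiles are double bumps: quarter-sine
  load-transfer ramps spanning exactly the double-support window (a steep rise
  at contact that tapers toward full load, mirrored into toe-off) times a
  midstance-valley shape whose contrast grows with speed (0.25·mult^1.5, so
  peak vertical GRF rises with walking speed). The two-foot sum is scaled to
  integrate to body weight per cycle; COM height is its double integral
  (periodic by construction).

* **Horizontal.** Per-foot COP templates progress heel→toe over stance. Given
  those and the vertical forces, the horizontal COM trajectory is the exact
  periodic orbit of the VPP/inverted-pendulum equation
  `ẍ = k(t)(x − u(t))`, `k = F_z,tot/(M·(z_COM + 0.0375))`, obtained by a
  linear two-point boundary solve (the equation is affine, so one particular
  and two homogeneous RK4 passes give the cycle map; the periodic initial
  state solves a 2×2 system). Truth horizontal forces then satisfy both
  Newton's law and the VPP geometry exactly. Sharing the VPP assumption with
  the estimator is disclosed as favourable: the noiseless residual isolates
  contact/distribution error. A `vpp_consistent=False` mode generates
  pendulum-prescribed horizontal truth that deliberately violates the VPP
  property, for probing the assumption's failure (it does not hold during
  strong acceleration/deceleration).

* **Markers.** Feet follow rocker trajectories — heel rocker spanning double
  support with fast easing to foot-flat, flat midstance, rollover about a
  pivot just distal to the toe points with late-accelerating heel rise, and a
  swing phase whose lowest sole point follows an explicit clearance profile
  (7 cm peak). The rocker timing is designed to be mutually consistent with
  the force-transfer ramps: in real gait, load transfer *is* geometric, so a
  generator whose kinematic and kinetic transfer disagreed would be
  internally contradictory. Legs are posed by two-link inverse kinematics,
  the pelvis tracks the COM, and the HAT segment is translated so the
  model's mass-weighted COM reproduces the truth COM at every frame — hence
  noiseless recovery error comes from the contact/distribution stage only.
  Footwear raises the foot marker clouds by the sole thickness and adds a
  deterministic sole-compliance lateral wobble (0.25 m lateral excursion per
  metre of sole at full load, sinusoidal in stance phase), emulating how
  compliant soles perturb medio-lateral contact geometry; marker noise is
  isotropic Gaussian from a single seeded generator recorded in the scenario.

**What the generator does not emulate:** soft-tissue artifact (correlated,
non-isotropic marker motion), inverse-kinematics COM error, marker occlusion
beyond short gaps, uneven or inclined ground, and running/jumping. Passing
synthetic tests therefore demonstrates the correctness and internal
consistency of the pipeline, not field accuracy on human recordings.

## Numerical choices

* Zero-phase filtering is the default because validation against force plates
  must be lag-free; the −3 dB point is matched after the double pass.
* Marker gaps up to 10 frames are linearly interpolated; longer gaps raise.
* Degenerate distribution frames (all points out of range) yield exactly zero
  force and an undefined (NaN) COP; negative total vertical force clamps to
  zero GRF.
* The distribution is scale-free in force: per-frame conservation holds to
  machine precision, and the VPP line identity is exact by construction
  (both are asserted at 1e-6 N and 1e-9 m respectively in the tests).
* Trial edges: the first and last half-stride of a trial carry filter and
  one-sided-difference transients; recovery metrics in the tests and the
  acceptance script are computed on the interior window, and problem sizes
  (3–4 strides per trial, 10–16 seeds per Monte-Carlo mean) are chosen to
  keep the whole suite fast while leaving the means statistically stable.
* The noise-degradation study monitors the **total** vertical GRF rRMSE:
  marker noise corrupts the estimated total external force directly, whereas
  per-foot errors are dominated by the systematic double-support allocation
  residual, which noise does not scale — the per-foot mean shift at 1 mm
  noise is below Monte-Carlo resolution at practical seed counts.

## Known limitations

* The distance-based distribution loads the striking heel slightly before,
  and unloads the trailing toe slightly after, the true force transfer; the
  residual error concentrates in loading response and terminal stance, and
  grows with walking speed and with compliant footwear (medio-lateral
  components first). This is the method's characteristic artifact, visible
  even on noiseless synthetic gait.
* One VPP for both feet, free moment assumed zero, level ground only, and no
  support for movements that put the COP at the foot edge (running, jumping):
  the 11-point layout is too coarse there.
* C3D files are not read; convert to TRC or the CSV dialect.
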