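# Default anthropometric model: Gait-2392-style segment set with the arms, head and
# torso lumped into a single HAT segment. Mass fractions are the Gait 2392 segment
# masses (toes merged into the foot) normalised to the model's 75.16 kg total.
# COM locators are fixed convex combinations of marker positions; weights sum to 1
# per segment. Edit this file (or pass your own) to substitute exact model values.
segments:
  pelvis:
    mass_fraction: 0.156682
    locator: {R.ASIS: 0.333334, L.ASIS: 0.333333, V.Sacral: 0.333333}
  femur_r:
    mass_fraction: 0.123747
    locator: {R.ASIS: 0.42, V.Sacral: 0.18, R.Knee.Lat: 0.20, R.Knee.Med: 0.20}
  femur_l:
    mass_fraction: 0.123747
    locator: {L.ASIS: 0.42, V.Sacral: 0.18, L.Knee.Lat: 0.20, L.Knee.Med: 0.20}
  tibia_r:
    mass_fraction: 0.049325
    locator: {R.Knee.Lat: 0.285, R.Knee.Med: 0.285, R.Ankle.Lat: 0.215, R.Ankle.Med: 0.215}
  tibia_l:
    mass_fraction: 0.049325
    locator: {L.Knee.Lat: 0.285, L.Knee.Med: 0.285, L.Ankle.Lat: 0.215, L.Ankle.Med: 0.215}
  foot_r:
    mass_fraction: 0.020843
    locator: {R.Heel: 0.5, R.Toe.Tip: 0.3, R.Toe.Lat: 0.1, R.Toe.Med: 0.1}
  foot_l:
    mass_fraction: 0.020843
    locator: {L.Heel: 0.5, L.Toe.Tip: 0.3, L.Toe.Lat: 0.1, L.Toe.Med: 0.1}
  hat:
    mass_fraction: 0.455488
    locator: {Sternum: 0.35, C7: 0.25, R.Acromion: 0.20, L.Acromion: 0.20}

# 49-label marker map (Gait-2392-style full-body set).
marker_set:
  - Top.Head
  - Front.Head
  - Rear.Head
  - Sternum
  - Clavicle
  - C7
  - R.Acromion
  - L.Acromion
  - R.Bicep
  - R.Elbow
  - R.Wrist
  - L.Bicep
  - L.Elbow
  - L.Wrist
  - R.ASIS
  - L.ASIS
  - V.Sacral
  - R.Thigh.Upper
  - R.Thigh.Front
  - R.Thigh.Rear
  - L.Thigh.Upper
  - L.Thigh.Front
  - L.Thigh.Rear
  - R.Knee.Lat
  - R.Knee.Med
  - L.Knee.Lat
  - L.Knee.Med
  - R.Shank.Upper
  - R.Shank.Front
  - R.Shank.Rear
  - L.Shank.Upper
  - L.Shank.Front
  - L.Shank.Rear
  - R.Ankle.Lat
  - R.Ankle.Med
  - L.Ankle.Lat
  - L.Ankle.Med
  - R.Heel
  - R.Midfoot.Sup
  - R.Midfoot.Lat
  - R.Toe.Lat
  - R.Toe.Med
  - R.Toe.Tip
  - L.Heel
  - L.Midfoot.Sup
  - L.Midfoot.Lat
  - L.Toe.Lat
  - L.Toe.Med
  - L.Toe.Tip
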