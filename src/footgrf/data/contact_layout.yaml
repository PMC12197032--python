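# Default foot contact-point layout: 11 points per foot in a foot-local frame whose
# origin is the heel marker's ground projection, x pointing from heel to toe tip
# (horizontal), y medial-positive. Coordinates in metres. The layout approximates the
# published placement figure (no millimetre coordinates are tabulated there): two heel
# points shifted medially, two midfoot points, a four-point metatarsal arc, and three
# toe points including the added medial toe point. Mirror symmetry gives the other
# foot. Per-shoe layouts may be supplied by pointing the pipeline at an edited copy.
markers: [Heel, Midfoot.Sup, Midfoot.Lat, Toe.Lat, Toe.Med, Toe.Tip]
frame:
  origin_marker: Heel
  forward_marker: Toe.Tip
points:
  heel_med:       [0.010,  0.012]
  heel_centre:    [0.035,  0.022]
  midfoot_lat:    [0.075, -0.030]
  midfoot_centre: [0.110, -0.020]
  met_1:          [0.150,  0.032]
  met_2:          [0.155,  0.010]
  met_3:          [0.150, -0.012]
  met_5:          [0.140, -0.035]
  toe_med:        [0.190,  0.030]
  toe_centre:     [0.200,  0.005]
  toe_lat:        [0.185, -0.022]
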