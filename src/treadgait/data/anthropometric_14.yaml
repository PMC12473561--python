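# Default 14-segment anthropometric table (Winter-lineage dismountable model).
#
# Each segment runs from a proximal ("upper", P_u) to a distal ("lower", P_l)
# tracked joint.  l is the dimensionless CoM position parameter measured from
# the proximal end (segment CoM = P_u - l * (P_u - P_l)); r is the segment
# mass as a fraction of whole-body mass.  Head and neck are merged into one
# segment so the bilateral expansion of head+neck, trunk, upper arms,
# forearms, hands, thighs, shanks and feet totals exactly 14 segments over
# exactly 20 distinct joints, and the mass fractions sum to 1 exactly.
#
# The table is plain data: replace it (same schema) to use alternate
# anthropometry; it is validated on load.
name: winter14
segments:
  - {name: head_neck,       proximal: head,           distal: neck,           l: 0.500, r: 0.0810}
  - {name: trunk,           proximal: spine_chest,    distal: pelvis,         l: 0.500, r: 0.4970}
  - {name: upper_arm_left,  proximal: shoulder_left,  distal: elbow_left,     l: 0.436, r: 0.0280}
  - {name: upper_arm_right, proximal: shoulder_right, distal: elbow_right,    l: 0.436, r: 0.0280}
  - {name: forearm_left,    proximal: elbow_left,     distal: wrist_left,     l: 0.430, r: 0.0160}
  - {name: forearm_right,   proximal: elbow_right,    distal: wrist_right,    l: 0.430, r: 0.0160}
  - {name: hand_left,       proximal: wrist_left,     distal: hand_tip_left,  l: 0.506, r: 0.0060}
  - {name: hand_right,      proximal: wrist_right,    distal: hand_tip_right, l: 0.506, r: 0.0060}
  - {name: thigh_left,      proximal: hip_left,       distal: knee_left,      l: 0.433, r: 0.1000}
  - {name: thigh_right,     proximal: hip_right,      distal: knee_right,     l: 0.433, r: 0.1000}
  - {name: shank_left,      proximal: knee_left,      distal: ankle_left,     l: 0.433, r: 0.0465}
  - {name: shank_right,     proximal: knee_right,     distal: ankle_right,    l: 0.433, r: 0.0465}
  - {name: foot_left,       proximal: ankle_left,     distal: foot_left,      l: 0.500, r: 0.0145}
  - {name: foot_right,      proximal: ankle_right,    distal: foot_right,     l: 0.500, r: 0.0145}
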