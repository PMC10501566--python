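# Bundled 9-segment 3-D toy model: pelvis, torso, head+arms lump, and
# left/right thigh, shank, foot.  Table frame: x down the in-run, y
# perpendicular to the table, z to the jumper's right.  Zero pose = standing
# straight, legs vertical, feet flat.  Masses follow standard anthropometric
# fractions of a 62 kg, 1.70 m subject.  Angles in this file are degrees.
schema_version: 1
name: toy9
generic_height: 1.70
generic_mass: 62.0
gravity: [0.0, -9.81, 0.0]
segments:
  - name: pelvis
    mass: 8.804
    com_offset: [0.0, 0.0, 0.0]
    inertia: [0.08, 0.09, 0.07]
    length: 0.19
    markers:
      hip_l: [0.0, -0.07, -0.09]
      hip_r: [0.0, -0.07, 0.09]
      sacrum: [-0.12, 0.02, 0.0]
  - name: torso
    mass: 22.010
    com_offset: [0.0, 0.22, 0.0]
    inertia: [0.37, 0.12, 0.37]
    length: 0.45
    markers:
      c7: [-0.05, 0.44, 0.0]
      sternum: [0.08, 0.30, 0.0]
      shoulder_l: [0.0, 0.42, -0.18]
      shoulder_r: [0.0, 0.42, 0.18]
  - name: headarms
    mass: 11.222
    com_offset: [0.0, 0.12, 0.0]
    inertia: [0.12, 0.05, 0.12]
    length: 0.25
    markers:
      head_top: [0.0, 0.22, 0.0]
      forehead: [0.08, 0.15, 0.0]
  - name: thigh_l
    mass: 6.200
    com_offset: [0.0, -0.18, 0.0]
    inertia: [0.09, 0.015, 0.09]
    length: 0.42
    markers:
      knee_l: [0.0, -0.42, 0.0]
  - name: thigh_r
    mass: 6.200
    com_offset: [0.0, -0.18, 0.0]
    inertia: [0.09, 0.015, 0.09]
    length: 0.42
    markers:
      knee_r: [0.0, -0.42, 0.0]
  - name: shank_l
    mass: 2.883
    com_offset: [0.0, -0.18, 0.0]
    inertia: [0.045, 0.005, 0.045]
    length: 0.43
    markers:
      ankle_l: [0.0, -0.43, 0.0]
  - name: shank_r
    mass: 2.883
    com_offset: [0.0, -0.18, 0.0]
    inertia: [0.045, 0.005, 0.045]
    length: 0.43
    markers:
      ankle_r: [0.0, -0.43, 0.0]
  - name: foot_l
    mass: 0.899
    com_offset: [0.05, -0.05, 0.0]
    inertia: [0.002, 0.004, 0.004]
    length: 0.22
    markers:
      heel_l: [-0.06, -0.07, 0.0]
      toe_l: [0.16, -0.07, 0.0]
    stations:
      proximal_metatarsal: [0.10, -0.07, 0.0]
  - name: foot_r
    mass: 0.899
    com_offset: [0.05, -0.05, 0.0]
    inertia: [0.002, 0.004, 0.004]
    length: 0.22
    markers:
      heel_r: [-0.06, -0.07, 0.0]
      toe_r: [0.16, -0.07, 0.0]
    stations:
      proximal_metatarsal: [0.10, -0.07, 0.0]
joints:
  - name: ground_pelvis
    parent: ground
    child: pelvis
    type: free6dof
    location_in_parent: [0.0, 0.0, 0.0]
    coordinates: [pelvis_tx, pelvis_ty, pelvis_tz, pelvis_rx, pelvis_ry, pelvis_rz]
  - name: lumbar
    parent: pelvis
    child: torso
    type: ball
    location_in_parent: [0.0, 0.10, 0.0]
    coordinates: [lumbar_rx, lumbar_ry, lumbar_rz]
    ranges: [[-45, 45], [-45, 45], [-95, 30]]
  - name: neck
    parent: torso
    child: headarms
    type: pin
    axis: [0.0, 0.0, 1.0]
    location_in_parent: [0.0, 0.45, 0.0]
    coordinates: [neck_angle]
    ranges: [[-60, 60]]
  - name: hip_l
    parent: pelvis
    child: thigh_l
    type: pin
    axis: [0.0, 0.0, 1.0]
    location_in_parent: [0.0, -0.07, -0.09]
    coordinates: [hip_flexion_l]
    ranges: [[-30, 130]]
  - name: hip_r
    parent: pelvis
    child: thigh_r
    type: pin
    axis: [0.0, 0.0, 1.0]
    location_in_parent: [0.0, -0.07, 0.09]
    coordinates: [hip_flexion_r]
    ranges: [[-30, 130]]
  - name: knee_l
    parent: thigh_l
    child: shank_l
    type: pin
    axis: [0.0, 0.0, 1.0]
    location_in_parent: [0.0, -0.42, 0.0]
    coordinates: [knee_angle_l]
    ranges: [[-150, 5]]
  - name: knee_r
    parent: thigh_r
    child: shank_r
    type: pin
    axis: [0.0, 0.0, 1.0]
    location_in_parent: [0.0, -0.42, 0.0]
    coordinates: [knee_angle_r]
    ranges: [[-150, 5]]
  - name: ankle_l
    parent: shank_l
    child: foot_l
    type: pin
    axis: [0.0, 0.0, 1.0]
    location_in_parent: [0.0, -0.43, 0.0]
    coordinates: [ankle_angle_l]
    ranges: [[-60, 60]]
  - name: ankle_r
    parent: shank_r
    child: foot_r
    type: pin
    axis: [0.0, 0.0, 1.0]
    location_in_parent: [0.0, -0.43, 0.0]
    coordinates: [ankle_angle_r]
    ranges: [[-60, 60]]
# Muscle paths are straight lines through via points.  Hip extensors route
# through an ischial via point so their line of action stays behind the hip
# even in deep flexion; knee extensors route over an anterior (patellar) via
# point.  Forces represent whole functional groups, athlete-grade.
muscles:
  - name: soleus_r
    path: [[shank_r, [-0.03, -0.20, 0.0]], [foot_r, [-0.06, -0.04, 0.0]]]
    max_isometric_force: 4000.0
    optimal_fiber_length: 0.05
  - name: gasmed_r
    path: [[thigh_r, [-0.03, -0.38, 0.0]], [foot_r, [-0.06, -0.04, 0.0]]]
    max_isometric_force: 2500.0
    optimal_fiber_length: 0.06
  - name: tibant_r
    path: [[shank_r, [0.04, -0.20, 0.0]], [foot_r, [0.07, -0.02, 0.0]]]
    max_isometric_force: 1200.0
    optimal_fiber_length: 0.07
  - name: vaslat_r
    path: [[thigh_r, [0.05, -0.15, 0.0]], [thigh_r, [0.09, -0.42, 0.0]], [shank_r, [0.05, -0.12, 0.0]]]
    max_isometric_force: 9000.0
    optimal_fiber_length: 0.09
  - name: recfem_r
    path: [[pelvis, [0.05, -0.05, 0.09]], [thigh_r, [0.09, -0.42, 0.0]], [shank_r, [0.05, -0.12, 0.0]]]
    max_isometric_force: 2500.0
    optimal_fiber_length: 0.08
  - name: glmax_r
    path: [[pelvis, [-0.12, 0.02, 0.09]], [pelvis, [-0.06, -0.16, 0.09]], [thigh_r, [-0.02, -0.22, 0.0]]]
    max_isometric_force: 6000.0
    optimal_fiber_length: 0.15
  - name: bflh_r
    path: [[pelvis, [-0.07, -0.15, 0.09]], [shank_r, [-0.03, -0.06, 0.0]]]
    max_isometric_force: 3000.0
    optimal_fiber_length: 0.11
  - name: semimem_r
    path: [[pelvis, [-0.08, -0.14, 0.09]], [shank_r, [-0.04, -0.05, 0.0]]]
    max_isometric_force: 3000.0
    optimal_fiber_length: 0.08
  - name: soleus_l
    path: [[shank_l, [-0.03, -0.20, 0.0]], [foot_l, [-0.06, -0.04, 0.0]]]
    max_isometric_force: 4000.0
    optimal_fiber_length: 0.05
  - name: gasmed_l
    path: [[thigh_l, [-0.03, -0.38, 0.0]], [foot_l, [-0.06, -0.04, 0.0]]]
    max_isometric_force: 2500.0
    optimal_fiber_length: 0.06
  - name: tibant_l
    path: [[shank_l, [0.04, -0.20, 0.0]], [foot_l, [0.07, -0.02, 0.0]]]
    max_isometric_force: 1200.0
    optimal_fiber_length: 0.07
  - name: vaslat_l
    path: [[thigh_l, [0.05, -0.15, 0.0]], [thigh_l, [0.09, -0.42, 0.0]], [shank_l, [0.05, -0.12, 0.0]]]
    max_isometric_force: 9000.0
    optimal_fiber_length: 0.09
  - name: recfem_l
    path: [[pelvis, [0.05, -0.05, -0.09]], [thigh_l, [0.09, -0.42, 0.0]], [shank_l, [0.05, -0.12, 0.0]]]
    max_isometric_force: 2500.0
    optimal_fiber_length: 0.08
  - name: glmax_l
    path: [[pelvis, [-0.12, 0.02, -0.09]], [pelvis, [-0.06, -0.16, -0.09]], [thigh_l, [-0.02, -0.22, 0.0]]]
    max_isometric_force: 6000.0
    optimal_fiber_length: 0.15
  - name: bflh_l
    path: [[pelvis, [-0.07, -0.15, -0.09]], [shank_l, [-0.03, -0.06, 0.0]]]
    max_isometric_force: 3000.0
    optimal_fiber_length: 0.11
  - name: semimem_l
    path: [[pelvis, [-0.08, -0.14, -0.09]], [shank_l, [-0.04, -0.05, 0.0]]]
    max_isometric_force: 3000.0
    optimal_fiber_length: 0.08
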