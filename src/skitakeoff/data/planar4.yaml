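# Bundled planar 4-segment toy model: pelvis (base) plus one thigh, shank and
# foot, all pin joints about z so sagittal-plane motions stay in the x-y
# plane.  Useful for hand-checkable dynamics and optimization fixtures.
schema_version: 1
name: planar4
generic_height: 1.70
generic_mass: 62.0
gravity: [0.0, -9.81, 0.0]
segments:
  - name: pelvis
    mass: 42.0
    com_offset: [0.0, 0.15, 0.0]
    inertia: [0.8, 0.4, 0.8]
    length: 0.5
    markers:
      hip: [0.0, -0.07, 0.0]
      sacrum: [-0.12, 0.02, 0.0]
      chest: [0.05, 0.35, 0.0]
  - name: thigh
    mass: 12.4
    com_offset: [0.0, -0.18, 0.0]
    inertia: [0.18, 0.03, 0.18]
    length: 0.42
    markers:
      knee: [0.0, -0.42, 0.0]
  - name: shank
    mass: 5.8
    com_offset: [0.0, -0.18, 0.0]
    inertia: [0.09, 0.01, 0.09]
    length: 0.43
    markers:
      ankle: [0.0, -0.43, 0.0]
  - name: foot
    mass: 1.8
    com_offset: [0.05, -0.05, 0.0]
    inertia: [0.004, 0.008, 0.008]
    length: 0.22
    markers:
      heel: [-0.06, -0.07, 0.0]
      toe: [0.16, -0.07, 0.0]
    stations:
      proximal_metatarsal: [0.10, -0.07, 0.0]
joints:
  - name: ground_pelvis
    parent: ground
    child: pelvis
    type: free6dof
    location_in_parent: [0.0, 0.0, 0.0]
    coordinates: [pelvis_tx, pelvis_ty, pelvis_tz, pelvis_rx, pelvis_ry, pelvis_rz]
  - name: hip
    parent: pelvis
    child: thigh
    type: pin
    axis: [0.0, 0.0, 1.0]
    location_in_parent: [0.0, -0.07, 0.0]
    coordinates: [hip_flexion]
    ranges: [[-30, 130]]
  - name: knee
    parent: thigh
    child: shank
    type: pin
    axis: [0.0, 0.0, 1.0]
    location_in_parent: [0.0, -0.42, 0.0]
    coordinates: [knee_angle]
    ranges: [[-150, 5]]
  - name: ankle
    parent: shank
    child: foot
    type: pin
    axis: [0.0, 0.0, 1.0]
    location_in_parent: [0.0, -0.43, 0.0]
    coordinates: [ankle_angle]
    ranges: [[-60, 60]]
muscles:
  - name: vasti
    path: [[thigh, [0.04, -0.15, 0.0]], [shank, [0.05, -0.08, 0.0]]]
    max_isometric_force: 5000.0
    optimal_fiber_length: 0.09
  - name: soleus
    path: [[shank, [-0.02, -0.15, 0.0]], [foot, [-0.05, -0.06, 0.0]]]
    max_isometric_force: 4000.0
    optimal_fiber_length: 0.05
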