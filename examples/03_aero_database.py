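"""Build the posture-indexed aerodynamic database and query it.

The reference grid has 278 postures in five blocks keyed by knee angle δ2
(three take-off blocks with the arms at the sides, two early-flight blocks
with spread skis and nonzero angle of attack).  Forces at arbitrary postures
come from block-wise multilinear interpolation, then scale with air density,
linearly with height and quadratically with speed.
"""

from skitakeoff import PostureAngles, generate_aero_db, scale_aero

db = generate_aero_db()  # analytic coefficient function on the 278-node grid
print(f"database: {db.n_records} postures, reference "
      f"{db.ref_height} m / {db.ref_speed} m/s / {db.ref_rho} kg/m^3")

posture = PostureAngles(delta1=55.0, delta2=127.0, delta3=63.0, delta4=0.0,
                        theta1=0.0, theta2=0.0, alpha=0.0)
rec = db.interpolate(posture)
print(f"whole-body force at a mid-extension posture (reference conditions): "
      f"drag {-rec.total_force[0]:.1f} N, lift {rec.total_force[1]:.1f} N")

scaled = scale_aero(rec, height=1.76, speed=25.0)
print(f"scaled to a 1.76 m jumper at 25 m/s: drag {-scaled.total_force[0]:.1f} N "
      "(height linear, speed quadratic)")

trunk = scaled.forces["trunk"]
calves = scaled.forces["calf_l"] + scaled.forces["calf_r"]
print(f"per part: trunk {-trunk[0]:.1f} N, calves+skis {-calves[0]:.1f} N of drag")
# Trunk and calves carry most of the drag, matching the part decomposition
# the database stores for each of the 10 body parts.
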