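"""Load the bundled 9-segment model and scale it to an athlete.

Segment lengths scale with height, masses with body mass, and maximum
isometric muscle forces are first doubled (professional jumpers are much
stronger than the generic population the model represents) and then
multiplied by the mass*height volume factor.
"""

from skitakeoff import load_model, scale_model, toy_model_path

generic = load_model(toy_model_path("toy9"))
print(f"generic model: {len(generic.segments)} segments, "
      f"{generic.n_coordinates} coordinates, "
      f"{generic.total_mass:.1f} kg at {generic.generic_height:.2f} m")

athlete = scale_model(generic, height=1.76, mass=62.0, strength_doubling=True)
print(f"scaled model:  total mass {athlete.total_mass:.1f} kg "
      f"(fractions preserved)")

m0 = generic.muscles[0]
m1 = athlete.muscles[0]
factor = m1.max_isometric_force / m0.max_isometric_force
print(f"{m0.name}: F_max {m0.max_isometric_force:.0f} N -> "
      f"{m1.max_isometric_force:.0f} N  (x{factor:.3f} = 2 x mass ratio x "
      "height ratio)")
# The factor above is the strength adjustment applied to every muscle; the
# doubling dominates, the volume term corrects for the athlete's build.
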