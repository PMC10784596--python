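"""Build a cochlear model and place landmarks under the angular schemes.

The model centerline is the lateral wall of a coiling spiral anchored at
the four quadrant extents; landmarks are placed every 45/90/180 degrees
(plus a terminal one at the apex) or with the minimal 5-landmark scheme.
"""

from cochreg import PlacementScheme, build_centerline, mean_params, place_landmarks

params = mean_params()
print(f"mean cochlea: A_a={params.A_a} A_b={params.A_b} "
      f"B_a={params.B_a} B_b={params.B_b} mm -> turns={params.turns:.3f}")

centerline = build_centerline(params)
for scheme, name in [
    (PlacementScheme(90), "every 90 deg"),
    (PlacementScheme(180), "every 180 deg"),
    (PlacementScheme(45), "every 45 deg"),
    (PlacementScheme.minimal(), "minimal basal+apex"),
]:
    lm = place_landmarks(centerline, scheme)
    print(f"{name:>20}: {len(lm)} landmarks")

# With the patient's graphically estimated 2.4 turns the 90-degree scheme
# drops to 11 landmarks (the terminal one moves to the shorter last turn).
patient = mean_params(turns=2.4)
lm = place_landmarks(build_centerline(patient), PlacementScheme(90))
print(f"2.4-turn model, 90 deg: {len(lm)} landmarks")
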