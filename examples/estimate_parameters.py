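"""Estimate quadrant extents from two basal-turn chords picked in a scan.

Four points picked on the lateral wall of the basal turn span two
perpendicular chords; the spiral center is the least-squares closest point
to both chord lines, and the four quadrant extents are the distances from
the chord endpoints to that center.  These extents parameterize a
patient-specific model.
"""

from cochreg import PlacementScheme, build_centerline, estimate_quadrant_params, place_landmarks

# chord endpoints (mm) as picked in the coronal slice with the largest
# spiral footprint: P1/P2 span the long axis, Q1/Q2 the perpendicular one
P1, P2 = (5.71, 0.0, 0.0), (-3.29, 0.0, 0.0)
Q1, Q2 = (0.0, 4.37, 0.0), (0.0, -2.75, 0.0)

params, center = estimate_quadrant_params(P1, P2, Q1, Q2, return_center=True)
print(f"center M  : ({center[0]:.3f}, {center[1]:.3f}, {center[2]:.3f}) mm")
print(f"A_a={params.A_a:.2f}  A_b={params.A_b:.2f}  "
      f"B_a={params.B_a:.2f}  B_b={params.B_b:.2f} mm")
print(f"implied turns: {params.turns:.3f}")

# a fixed number of turns (e.g. estimated graphically) can override the
# implied value; the 90-degree scheme then yields 11 landmarks
patient = params.with_turns(2.4)
lm = place_landmarks(build_centerline(patient), PlacementScheme(90))
print(f"with turns fixed at 2.4: {len(lm)} landmarks at 90 deg spacing")
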