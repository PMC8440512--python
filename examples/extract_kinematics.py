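"""Extract kinematic and spatial features from a two-triangle recording.

Builds a synthetic 45 s touchscreen recording, screens it with the
quality-control filter, and prints the six stimulus features used by the
accuracy analyses.  Speeds are in mm/s (and mm/s^2, mm/s^3 for the higher
derivatives), rotation in degrees per frame, distance in mm.
"""

from animakin import TrajectoryRecipe, compute_kinematics, gen_pure_frequency_trajectory, qc_filter

rec = gen_pure_frequency_trajectory(
    TrajectoryRecipe(components=((2.0, 0.5, 0.0),), base_speed=40.0, seed=7),
    animation_id="demo_seducing",
)

report = qc_filter(rec)
print(f"QC passed: {report.passed} "
      f"(duration {report.duration_s:.1f} s, "
      f"quadrants visited {sorted(report.visited_quadrants)})")

prof = compute_kinematics(rec)
print(f"mean speed:            {prof.mean_speed:8.2f} mm/s")
print(f"mean acceleration:     {prof.mean_acceleration:8.2f} mm/s^2")
print(f"mean jerk:             {prof.mean_jerk:8.2f} mm/s^3")
print(f"simultaneous movement: {prof.simultaneous_movement:8.2f} (proportion)")
print(f"relative distance:     {prof.relative_distance:8.2f} mm")
print(f"mean rotation:         {prof.mean_rotation:8.2f} deg/frame")
print("\nHigh jerk marks abrupt acceleration changes; the similarity "
      "analyses compare these values between observer and animator.")
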