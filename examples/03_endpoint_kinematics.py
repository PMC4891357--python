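"""Endpoint-kinematics battery on a clean 30 cm minimum-jerk reach.

Generates the reference reach (amplitude 300 mm, duration 1 s, 100 Hz with
stationary holds), detects the movement bounds by the 25 mm/s + 10 mm
criteria, and prints the standard metrics.
"""
import numpy as np

from ucmreach import (
    detect_bounds,
    minimum_jerk_path,
    phase_times,
    tangential_velocity,
)
from ucmreach.kinematics import curvature

start = np.array([215.0, 0.0, -300.0])
target = start + np.array([300.0, 0.0, 0.0])
traj = minimum_jerk_path(start, target, movement_time=1.0)

velocity = tangential_velocity(traj)
bounds = detect_bounds(traj, velocity, start, target)
acc, dec = phase_times(velocity, bounds, traj.time)

print(f"samples: {traj.n_samples} at 100 Hz")
print(f"movement bounds: samples {bounds.start_index}..{bounds.end_index} "
      f"({bounds.movement_time:.2f} s)")
print(f"peak velocity: {velocity.max():.1f} mm/s (closed form 562.5)")
print(f"acceleration {acc:.2f} s, deceleration {dec:.2f} s")
print(f"horizontal curvature: "
      f"{curvature(traj, bounds, start, target, 'horizontal'):.2e} mm")
print(f"vertical curvature:   "
      f"{curvature(traj, bounds, start, target, 'vertical'):.2e} mm")
# The detected acceleration phase is shorter than the deceleration phase
# even though the speed profile is symmetric: the movement only counts as
# started once the tip is both faster than 25 mm/s and outside the 10 mm
# start dot.
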