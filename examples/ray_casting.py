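"""Gaze-ray casting: from a local eye-tracker direction to a labelled target.

Builds a two-object scene, converts a local gaze direction into a global
ray given the head pose, and reports the first object the ray hits.
"""

import numpy as np

from gazenet import (
    OOI, Box, HeadPose, Scene, Sphere,
    first_hit, gaze_angles, global_gaze_ray, rotate_forward,
)

scene = Scene([
    OOI("teacher", Sphere(center=(650, 120, 150), radius=40)),
    OOI("board", Box(min_corner=(780, -150, 100), max_corner=(800, 150, 250))),
])

# Head seated at the origin (eye height 120 cm), looking straight ahead;
# the eye tracker reports gaze slightly left and up in its local frame.
head = HeadPose.identity(position=(0, 0, 120))
local_gaze = np.array([-0.18, 0.05, 0.98])
local_gaze /= np.linalg.norm(local_gaze)

angles = gaze_angles(local_gaze)
direction = rotate_forward(head, angles)
ray = global_gaze_ray(head, direction, k=25000)
hit = first_hit(ray, scene)

print(f"gaze angles: yaw {angles.yaw_deg:+.2f} deg, pitch {angles.pitch_deg:+.2f} deg")
print(f"world direction: {np.round(direction, 3)}")
if hit.hit:
    print(f"first hit: {hit.target_name} at {np.round(hit.impact_point, 1)} uu, "
          f"distance {hit.distance:.1f} uu")
else:
    print("gaze ray hit nothing")
# Yaw is negative toward the viewer's left in the local frame convention;
# the hit distance is in unreal units (1 uu = 1 cm), so ~7 m to the target.
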