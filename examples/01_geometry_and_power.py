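"""Display geometry and sample-size planning.

Computes the physical extent and visual angles of the recording setup
(23-inch 16:9 display, 1920x1080, viewed at 55 cm) and the per-group
sample size needed to detect a medium rank effect (r = 0.30).
"""

from eden_gaze import (
    ScreenGeometry,
    physical_extent,
    r_to_d,
    required_n_per_group,
    visual_angles,
)

geom = ScreenGeometry(diagonal_in=23, aspect_w=16, aspect_h=9,
                      distance_cm=55, res_x_px=1920, res_y_px=1080)
w_cm, h_cm = physical_extent(geom)
ax, ay = visual_angles(geom)
print(f"display: {w_cm:.1f} x {h_cm:.1f} cm -> {ax:.1f} x {ay:.1f} degrees")
# ~50 x 29 degrees: the stimulus fills most of the central visual field.

d = r_to_d(0.30)
n = required_n_per_group(d, alpha=0.05, power=0.80, tails=1)
print(f"r = 0.30 corresponds to Cohen's d = {d:.3f}")
print(f"one-tailed alpha=.05, power=.80 -> {n} participants per group "
      f"({3 * n} total across high/medium/low)")
# 16 per evaluation group; with three groups the study needs 48 viewers.
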