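"""Compute the 12 sagittal alignment parameters from annotated landmarks.

Builds a key-point set with a 40-degree sacral slope and a 15-degree pelvic
tilt, then prints all twelve parameters.  The pelvic incidence must come out
as 55 degrees (PI = PT + SS) without ever being measured directly.
"""

import math

from spinealign import (EndplateLine, KeyPointSet, Point2D,
                        compute_all_parameters)


def plate(mid_x, mid_y, slope_deg, half_width):
    s = math.radians(slope_deg)
    return EndplateLine(
        Point2D(mid_x - half_width * math.cos(s), mid_y - half_width * math.sin(s)),
        Point2D(mid_x + half_width * math.cos(s), mid_y + half_width * math.sin(s)),
    )


sacral = plate(135, 595, slope_deg=40.0, half_width=17)
mid = sacral.midpoint
pt = math.radians(15.0)
femoral = Point2D(mid.x - 81 * math.sin(pt), mid.y + 81 * math.cos(pt))

kps = KeyPointSet(
    c2_inf=plate(130, 110, -20.0, 11),
    c7_inf=plate(135, 174, -30.0, 13),
    t1_sup=plate(136, 190, -28.0, 13),
    l1_sup=plate(132, 498, 2.0, 15),
    s1_sup=sacral,
    femoral_center=femoral,
)

params = compute_all_parameters(kps)
for name, value in params.as_dict().items():
    print(f"{name:>5}: {value:7.2f} deg")

print()
print("PI equals PT + SS:", round(params.pi, 2), "=",
      round(params.pt, 2), "+", round(params.ss, 2))
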