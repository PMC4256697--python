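"""Build a street network and an 800-m line-based buffer around a home.

The buffer is the planar region within 50 m of every street-centerline
portion reachable within 800 network meters of the origin; its area is the
denominator of the density metrics.
"""

import math

from shapely.geometry import LineString, Point

import walkbmi as w

# a single 2-km straight road
segment = w.StreetSegment(
    "main_st", LineString([(0, 0), (2000, 0)]),
    speed_limit=25, adt=4000, sidewalk_code=2,
)
net = w.build_network([segment])

buf = net.service_area(Point(1000, 0), radius=800, offset=50)
closed_form = (1600 * 100 + math.pi * 50**2) / 1e6

print(f"reached centerline length: {buf.reached_length:.1f} m")
print(f"buffer area:               {buf.area_km2:.5f} km^2")
print(f"closed-form (rect + caps): {closed_form:.5f} km^2")
# 800 m in each direction from the midpoint is reached (1600 m of road);
# the polygon is that line fattened by 50 m with round caps.
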