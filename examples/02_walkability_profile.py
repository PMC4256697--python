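"""Generate a synthetic town and evaluate the eight walkability metrics
for one home near the town center.

The town has an urban-to-suburban gradient, so a central home sees high
intersection density, complete sidewalks and a rich business mix, while
homes near the edge see the opposite.
"""

from shapely.geometry import Point

import walkbmi as w

town = w.generate_town(seed=11)
center = town.spec.extent / 2
home = Point(center + 35, center - 10)

profile = w.compute_profile(
    town.network, home, town.openspace, town.businesses, town.tracts
)

for key, value in profile.as_dict().items():
    if isinstance(value, float):
        print(f"{key:32s} {value:,.3f}")
    else:
        print(f"{key:32s} {value}")
# openspace_distance_km is the capped network distance to the nearest
# park; the remaining buffer metrics are evaluated on the 800-m buffer.
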