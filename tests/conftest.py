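"""Shared fixtures: small networks, a synthetic town, growth references.

The session-scoped town/exposure fixtures are computed once and reused by
the statistical and acceptance tests, which only redraw outcomes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

import walkbmi as w


def grid_segments(n: int = 4, spacing: float = 1.0, **attrs) -> list[w.StreetSegment]:
    """n x n node grid of unit segments (horizontal + vertical)."""
    defaults = dict(speed_limit=25.0, adt=100.0, sidewalk_code=2)
    defaults.update(attrs)
    segs = []
    k = 0
    for i in range(n):
        for j in range(n):
            x, y = i * spacing, j * spacing
            if i + 1 < n:
                segs.append(
                    w.StreetSegment(f"h{k}", LineString([(x, y), (x + spacing, y)]), **defaults)
                )
                k += 1
            if j + 1 < n:
                segs.append(
                    w.StreetSegment(f"v{k}", LineString([(x, y), (x, y + spacing)]), **defaults)
                )
                k += 1
    return segs


@pytest.fixture
def unit_grid():
    return w.build_network(grid_segments(4))


@pytest.fixture(scope="session")
def bmi_ref():
    return w.synthetic_growth_reference("bmi")


@pytest.fixture(scope="session")
def stature_ref():
    return w.synthetic_growth_reference("stature")


@pytest.fixture(scope="session")
def town():
    return w.generate_town(seed=11)


@pytest.fixture(scope="session")
def home_exposures(town):
    """400 distinct homes with their exposure profiles (computed once)."""
    homes = w.sample_homes(town, 400, seed=12)
    expo = w.compute_exposure_table(
        town.network, homes, town.openspace, town.businesses, town.tracts
    )
    return pd.concat([homes, expo], axis=1)


def straight_road(length: float = 2000.0, **attrs) -> w.StreetNetwork:
    defaults = dict(speed_limit=25.0, adt=1000.0, sidewalk_code=2)
    defaults.update(attrs)
    seg = w.StreetSegment("r0", LineString([(0, 0), (length, 0)]), **defaults)
    return w.build_network([seg])
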