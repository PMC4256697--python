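"""Synthetic town and pediatric cohort with known ground truth.

The town is a planar grid city with an urban-to-suburban gradient: street
blocks are deleted with increasing probability away from the center, so the
core is dense and well-connected while the periphery is sparse.  Per-zone
attribute distributions (traffic, speed limits, sidewalks), business
placement and category mixtures, recreational open spaces, and census
tracts with an income gradient are all generated from one seed, so every
exposure metric spans its quartiles and tract income is coupled to
walkability by construction (the suburbs are richer and less walkable),
which is what lets the qualitative-confounding behaviour of the income
adjustment be reproduced on known truth.

The cohort simulator places children at homes on block faces, draws
demographics calibrated to a large pediatric primary-care population
(ages uniform on [4, 19), balanced sexes, fixed race/ethnicity mixture),
and builds BMI z-scores as

    z_index = alpha + sum(quartile-step effects) + income term + noise

with cross-sectional noise SD 1.04 and change-score SD 0.7 (the observed
dispersions in the population the generator emulates).  Heights come from
the stature reference at a per-child height percentile and weights are
back-computed through the inverse LMS transform, so re-deriving BMI
z-scores from the written heights and weights reproduces the simulated
z exactly.  A ground-truth record of the injected effect vectors
accompanies every cohort.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box

from .anthropometry import (
    FEMALE,
    MALE,
    GrowthReference,
    StudyWindows,
    inverse_lms,
    synthetic_growth_reference,
)
from .cohort import quartile_cut
from .errors import WalkbmiError
from .exposures import EXPOSURE_COLUMNS, compute_exposure_table
from .layers import (
    BUSINESS_CATEGORIES,
    BusinessLayer,
    BusinessPoint,
    OpenSpaceFeature,
    OpenSpaceLayer,
    Tract,
    TractLayer,
)
from .spatial import StreetNetwork, StreetSegment, build_network

#: race/ethnicity mixture of the emulated population (normalized)
RACE_PROPORTIONS = {
    "black": 0.119, "hispanic": 0.051, "asian": 0.084,
    "white": 0.587, "other": 0.059, "missing": 0.119,
}


@dataclass(frozen=True)
class TownSpec:
    """Parameters of the synthetic grid town.

    The defaults give a ~3.6 km x 3.6 km town (24 blocks of 150 m) whose
    center is dense, mixed-use and lower-income and whose periphery is
    sparse, single-use and higher-income.
    """

    grid_blocks: int = 24
    block_size: float = 150.0
    suburban_gradient: float = 0.55  # max block-deletion probability at the edge
    openspace_intensity: float = 1.4  # features per km²
    business_intensity: float = 60.0  # points per km² at the center
    tract_blocks: int = 6  # blocks per tract side
    income_range: tuple[float, float] = (48_000.0, 135_000.0)

    def __post_init__(self) -> None:
        if self.grid_blocks < 4 or self.block_size <= 0:
            raise WalkbmiError("town spec needs >= 4 blocks of positive size")
        if self.grid_blocks % self.tract_blocks != 0:
            raise WalkbmiError("tract_blocks must divide grid_blocks")

    @property
    def extent(self) -> float:
        return self.grid_blocks * self.block_size


@dataclass
class Town:
    spec: TownSpec
    segments: list[StreetSegment]
    network: StreetNetwork
    openspace: OpenSpaceLayer
    businesses: BusinessLayer
    tracts: TractLayer
    region: Polygon


def _radial(spec: TownSpec, x: float, y: float) -> float:
    """Normalized distance of a point from the town center, in [0, ~1]."""
    c = spec.extent / 2.0
    r = math.hypot(x - c, y - c)
    return min(r / c, 1.0)


def generate_town(spec: TownSpec | None = None, seed: int = 0) -> Town:
    """Deterministically generate the street, open-space, business and
    tract layers for one seed."""
    spec = spec or TownSpec()
    rng = np.random.default_rng(seed)
    nb, bs = spec.grid_blocks, spec.block_size

    # -- street grid with suburban thinning --------------------------------
    raw = []
    for i in range(nb + 1):
        for j in range(nb + 1):
            x, y = i * bs, j * bs
            for dx, dy in ((1, 0), (0, 1)):
                i2, j2 = i + dx, j + dy
                if i2 > nb or j2 > nb:
                    continue
                x2, y2 = i2 * bs, j2 * bs
                mx, my = (x + x2) / 2, (y + y2) / 2
                u = _radial(spec, mx, my)
                if rng.random() < spec.suburban_gradient * u**1.5:
                    continue
                raw.append(((x, y), (x2, y2), u))

    # keep the largest connected component so every home can route anywhere
    import networkx as nx

    g = nx.Graph()
    for a, b, _ in raw:
        g.add_edge(a, b)
    comp = max(nx.connected_components(g), key=len)
    raw = [e for e in raw if e[0] in comp]

    segments = []
    for k, (a, b, u) in enumerate(raw):
        adt = float(rng.lognormal(math.log(1500 + 8000 * (1 - u) ** 2), 0.6))
        speed = float(np.clip(rng.normal(24 + 12 * u, 3.0), 15, 45))
        r = rng.random()
        p2 = 0.05 + 0.85 * (1 - u)
        code = 2 if r < p2 else (1 if r < p2 + 0.25 else 0)
        segments.append(
            StreetSegment(
                segment_id=f"s{k:05d}",
                geometry=_line(a, b),
                speed_limit=speed,
                adt=adt,
                sidewalk_code=code,
                has_median=bool(rng.random() < 0.05 + 0.05 * u),
                pedestrian_accessible=not (speed > 38 and rng.random() < 0.5),
            )
        )
    network = build_network(segments)

    area_km2 = (spec.extent / 1000.0) ** 2

    # -- open space ---------------------------------------------------------
    n_os = max(1, rng.poisson(spec.openspace_intensity * area_km2))
    os_feats = []
    for k in range(n_os):
        cx, cy = rng.uniform(0, spec.extent, 2)
        half = 30.0
        os_feats.append(
            OpenSpaceFeature(f"os{k:03d}", box(cx - half, cy - half, cx + half, cy + half))
        )
    openspace = OpenSpaceLayer(tuple(os_feats))

    # -- businesses: density and variety decay outward ----------------------
    n_biz = rng.poisson(spec.business_intensity * area_km2 * 0.45)
    pts = []
    cat_suburban = np.array([0.05, 0.10, 0.60, 0.15, 0.10])
    cat_urban = np.full(5, 0.2)
    while len(pts) < n_biz:
        x, y = rng.uniform(0, spec.extent, 2)
        u = _radial(spec, x, y)
        if rng.random() > (1 - u) ** 2 + 0.02:  # rejection: core is denser
            continue
        probs = (1 - u) * cat_urban + u * cat_suburban
        cat = rng.choice(len(BUSINESS_CATEGORIES), p=probs / probs.sum())
        pts.append(BusinessPoint(Point(x, y), BUSINESS_CATEGORIES[cat]))
    businesses = BusinessLayer(tuple(pts))

    # -- census tracts: income rises outward, housing density falls ---------
    tracts = []
    tb = spec.tract_blocks
    lo, hi = spec.income_range
    for ti in range(nb // tb):
        for tj in range(nb // tb):
            x0, y0 = ti * tb * bs, tj * tb * bs
            x1, y1 = x0 + tb * bs, y0 + tb * bs
            poly = box(x0, y0, x1, y1)
            u = _radial(spec, (x0 + x1) / 2, (y0 + y1) / 2)
            income = float(
                np.clip(lo + (hi - lo) * u + rng.normal(0, 6000), lo * 0.8, hi * 1.2)
            )
            land = poly.area / 1e6
            dens = (300 + 2200 * (1 - u) ** 2) * rng.lognormal(0, 0.20)
            tracts.append(
                Tract(
                    tract_id=f"t{ti:02d}{tj:02d}",
                    geometry=poly,
                    median_income=income,
                    housing_units=float(round(dens * land)),
                    land_area_km2=land,
                )
            )
    region = box(0, 0, spec.extent, spec.extent)
    return Town(
        spec, segments, network, openspace, businesses,
        TractLayer(tuple(tracts)), region,
    )


def _line(a, b):
    from shapely.geometry import LineString

    return LineString([a, b])


def sample_homes(town: Town, n_homes: int, seed: int = 0) -> pd.DataFrame:
    """Sample distinct home locations on block faces.

    Homes sit a small perpendicular offset (15 m) from a random position on
    a random street segment (length-weighted), so every home projects onto
    the network well within tolerance.
    """
    rng = np.random.default_rng(seed)
    segs = town.segments
    lengths = np.array([s.length for s in segs])
    probs = lengths / lengths.sum()
    xs, ys = [], []
    while len(xs) < n_homes:
        seg = segs[rng.choice(len(segs), p=probs)]
        t = rng.uniform(0.1, 0.9) * seg.length
        p = seg.geometry.interpolate(t)
        (x0, y0), (x1, y1) = seg.geometry.coords[0], seg.geometry.coords[-1]
        dx, dy = x1 - x0, y1 - y0
        norm = math.hypot(dx, dy)
        side = 1 if rng.random() < 0.5 else -1
        hx = p.x - side * 15.0 * dy / norm
        hy = p.y + side * 15.0 * dx / norm
        if not town.region.covers(Point(hx, hy)):
            continue
        xs.append(hx)
        ys.append(hy)
    return pd.DataFrame({"x": xs, "y": ys})


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth data-generating parameters for the cohort.

    ``quartile_effects`` maps an exposure name to the (Q1, Q2, Q3) step
    effects on cross-sectional BMI z-score relative to Q4;
    ``change_quartile_effects`` does the same for the change score.
    ``income_effect_per_100k`` is the z change per $100,000 of tract median
    income (mean-centered).  Noise SDs default to the emulated population's
    dispersions: cross-sectional 1.04, change 0.7; mean follow-up 3.2 y
    (SD 0.8).
    """

    quartile_effects: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    change_quartile_effects: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    income_effect_per_100k: float = 0.0
    mean_z: float = 0.42
    cross_sectional_sd: float = 1.04
    change_mean: float = 0.07
    change_sd: float = 0.7
    mean_followup_years: float = 3.2
    followup_sd_years: float = 0.8

    def __post_init__(self) -> None:
        if self.cross_sectional_sd <= 0 or self.change_sd <= 0:
            raise WalkbmiError("noise SDs must be positive")

    def to_json(self) -> dict:
        return asdict(self)


def assign_children(
    home_exposures: pd.DataFrame,
    n: int,
    seed: int = 0,
    windows: StudyWindows | None = None,
) -> pd.DataFrame:
    """Place ``n`` children at homes and draw demographics and visit timing.

    ``home_exposures`` has one row per home with ``x``, ``y``, the eight
    exposure metrics and tract covariates.  Ages at the index visit are
    uniform on [4, 19), sexes balanced, race/ethnicity from the fixed
    mixture; follow-up gaps are normal (mean 3.2, SD 0.8 y), truncated so
    first visits stay inside the history window and above the growth
    reference's age floor — children too young for a compliant first visit
    get none (and will drop from the longitudinal sample).
    """
    if n < 100:
        raise WalkbmiError("cohort size must be >= 100")
    windows = windows or StudyWindows()
    rng = np.random.default_rng(seed)
    homes = home_exposures.reset_index(drop=True)
    pick = rng.integers(0, len(homes), n)
    df = homes.iloc[pick].reset_index(drop=True).copy()
    df.insert(0, "child_id", [f"c{i:06d}" for i in range(n)])
    df["sex"] = rng.choice([MALE, FEMALE], n)
    races = list(RACE_PROPORTIONS)
    pr = np.array(list(RACE_PROPORTIONS.values()))
    df["race_ethnicity"] = rng.choice(races, n, p=pr / pr.sum())
    df["age_years"] = rng.uniform(4.0, 19.0, n)
    span_days = (windows.index_end - windows.index_start).days
    offs = rng.integers(0, span_days + 1, n)
    df["index_date"] = [
        pd.Timestamp(windows.index_start) + pd.Timedelta(days=int(o)) for o in offs
    ]
    max_hist = (
        (df["index_date"] - pd.Timestamp(windows.history_start)).dt.days / 365.25
        - 0.05
    )
    gap = rng.normal(3.2, 0.8, n)
    gap = np.clip(gap, 1.05, np.minimum(max_hist, df["age_years"] - 2.2))
    gap[gap < 1.05] = np.nan  # child too young for a >= 1 y earlier visit
    df["gap_years"] = gap
    df["excluded_condition"] = 0
    return df


def simulate_outcomes(
    children: pd.DataFrame,
    effects: EffectSpec,
    seed: int = 0,
    bmi_ref: GrowthReference | None = None,
) -> pd.DataFrame:
    """Draw ground-truth BMI z-scores for an assigned cohort.

    Adds ``z_index``, ``z_first`` and ``delta_z_true`` columns; quartile
    labels used for effect injection are stored as ``{exposure}_qtrue``.
    Simulated z values are clipped to the invertible domain of the LMS
    transform (and to the +/-6 eligibility range) so that heights and
    weights can always be realized exactly.
    """
    bmi_ref = bmi_ref or synthetic_growth_reference("bmi")
    rng = np.random.default_rng(seed)
    df = children.copy()
    n = len(df)
    mean_income = df["tract_income_usd"].mean()

    base = np.full(n, effects.mean_z)
    for exp, betas in effects.quartile_effects.items():
        labels, _ = quartile_cut(df[exp])
        df[f"{exp}_qtrue"] = labels.astype(int)
        lab = labels.astype(int).to_numpy()
        step = np.array([*betas, 0.0])
        base = base + step[lab - 1]
    base = base + effects.income_effect_per_100k * (
        (df["tract_income_usd"].to_numpy() - mean_income) / 1e5
    )
    z_index = base + rng.normal(0.0, effects.cross_sectional_sd, n)

    delta = np.full(n, effects.change_mean)
    for exp, betas in effects.change_quartile_effects.items():
        qcol = f"{exp}_qtrue"
        if qcol in df.columns:
            lab = df[qcol].to_numpy()
        else:
            labels, _ = quartile_cut(df[exp])
            df[qcol] = labels.astype(int)
            lab = labels.astype(int).to_numpy()
        step = np.array([*betas, 0.0])
        delta = delta + step[lab - 1]
    delta = delta + rng.normal(0.0, effects.change_sd, n)

    # clip into the invertible LMS domain at each child's age
    z_index = np.clip(z_index, -5.9, 5.9)
    z_first = np.clip(z_index - delta, -5.9, 5.9)
    for i, (sex, age) in enumerate(zip(df["sex"], df["age_years"])):
        L, M, S = bmi_ref.lms(int(sex), float(age) * 12)
        lim = 0.97 / (abs(L) * S)
        z_index[i] = min(z_index[i], lim)
        gap = df["gap_years"].iloc[i]
        if not np.isnan(gap):
            La, Ma, Sa = bmi_ref.lms(int(sex), (float(age) - gap) * 12)
            z_first[i] = min(z_first[i], 0.97 / (abs(La) * Sa))
    df["z_index"] = z_index
    df["z_first"] = z_first
    df["delta_z_true"] = df["z_index"] - df["z_first"]
    return df


def realize_visits(
    children: pd.DataFrame,
    bmi_ref: GrowthReference | None = None,
    stature_ref: GrowthReference | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Turn simulated z-scores into a long visit table with heights/weights.

    Each child gets an index visit and, when a follow-up gap was assigned,
    an earlier first visit.  A per-child stature percentile (standard
    normal, stable across visits) produces heights from the stature
    reference; weights are back-computed through the inverse LMS transform
    so recomputing BMI z from the table reproduces the simulated z.
    """
    bmi_ref = bmi_ref or synthetic_growth_reference("bmi")
    stature_ref = stature_ref or synthetic_growth_reference("stature")
    rng = np.random.default_rng(seed)
    rows = []
    hz = rng.normal(0.0, 1.0, len(children))
    for i, r in enumerate(children.itertuples(index=False)):
        visits = [(r.index_date, float(r.age_years), float(r.z_index))]
        if not (r.gap_years is None or np.isnan(r.gap_years)):
            first_date = r.index_date - timedelta(days=float(r.gap_years) * 365.25)
            visits.append(
                (first_date, float(r.age_years - r.gap_years), float(r.z_first))
            )
        birth = r.index_date - timedelta(days=float(r.age_years) * 365.25)
        for when, age, z in visits:
            months = age * 12.0
            h_cm = inverse_lms(float(np.clip(hz[i], -3.5, 3.5)), stature_ref, int(r.sex), months)
            h_m = h_cm / 100.0
            bmi_val = inverse_lms(z, bmi_ref, int(r.sex), months)
            rows.append(
                {
                    "child_id": r.child_id,
                    "sex": int(r.sex),
                    "birth_date": birth.date().isoformat(),
                    "race_ethnicity": r.race_ethnicity,
                    "x": float(r.x),
                    "y": float(r.y),
                    "tract_id": r.tract_id,
                    "visit_date": pd.Timestamp(when).date().isoformat(),
                    "height_m": round(h_m, 4),
                    "weight_kg": round(bmi_val * h_m**2, 6),
                    "excluded_condition": int(r.excluded_condition),
                }
            )
    return pd.DataFrame(rows).sort_values(["child_id", "visit_date"]).reset_index(drop=True)


def _ineligible_children(
    town: Town,
    windows: StudyWindows,
    bmi_ref: GrowthReference,
    stature_ref: GrowthReference,
    seed: int,
) -> pd.DataFrame:
    """Hand-crafted children exercising each eligibility failure mode."""
    rng = np.random.default_rng(seed)
    ext = town.spec.extent
    inside = (ext / 2 + 40.0, ext / 2 + 15.0)
    idx_date = pd.Timestamp(windows.index_start) + pd.Timedelta(days=60)
    mk = []

    def visit(cid, sex, age, z, when, x, y, cond=0):
        months = age * 12
        h = inverse_lms(0.0, stature_ref, sex, months) / 100
        b = inverse_lms(z, bmi_ref, sex, months)
        birth = when - timedelta(days=age * 365.25)
        mk.append(
            {
                "child_id": cid, "sex": sex,
                "birth_date": birth.date().isoformat(),
                "race_ethnicity": "white", "x": x, "y": y,
                "tract_id": "t0000", "visit_date": pd.Timestamp(when).date().isoformat(),
                "height_m": round(h, 4), "weight_kg": round(b * h * h, 6),
                "excluded_condition": cond,
            }
        )

    # a: home outside the study region
    visit("x_a", MALE, 9.0, 0.2, idx_date, ext + 2500.0, ext + 2500.0)
    # b: 19.5 years old at the index visit
    visit("x_b", FEMALE, 19.5, 0.1, idx_date, *inside)
    # c: visits exist, but none in the index window
    visit("x_c", MALE, 8.0, 0.0, pd.Timestamp("2010-05-01"), *inside)
    # d: outlier z at the index visit
    visit("x_d", FEMALE, 10.0, -6.5, idx_date, *inside)
    # e: growth-affecting condition flag
    visit("x_e", MALE, 12.0, 0.3, idx_date, *inside, cond=1)
    # f: only one BMI measure (fails the longitudinal two-measure rule)
    visit("x_f", FEMALE, 7.0, 0.4, idx_date, *inside)
    # g: two measures under one year apart
    visit("x_g", MALE, 14.0, 0.1, idx_date, *inside)
    visit("x_g", MALE, 14.0 - 0.5, 0.2, idx_date - pd.Timedelta(days=182), *inside)
    del rng
    return pd.DataFrame(mk)


def generate_cohort(
    town: Town,
    effects: EffectSpec | None = None,
    n: int = 2000,
    seed: int = 0,
    n_homes: int = 400,
    windows: StudyWindows | None = None,
    include_ineligible: bool = True,
    bmi_ref: GrowthReference | None = None,
    stature_ref: GrowthReference | None = None,
    home_exposures: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """End-to-end cohort generation: visits table plus ground truth.

    Children are placed at ``n_homes`` distinct homes (exposures computed
    once per home), outcomes simulated under ``effects``, heights/weights
    realized, and one child per eligibility failure mode appended so the
    exclusion log is fully exercised.  Pass ``home_exposures`` to reuse a
    precomputed home exposure table across replicates.
    """
    effects = effects or EffectSpec()
    windows = windows or StudyWindows()
    bmi_ref = bmi_ref or synthetic_growth_reference("bmi")
    stature_ref = stature_ref or synthetic_growth_reference("stature")
    rng = np.random.default_rng(seed)
    s_homes, s_assign, s_outcome, s_visits, s_bad = rng.integers(0, 2**31 - 1, 5)
    if home_exposures is None:
        homes = sample_homes(town, n_homes, seed=int(s_homes))
        home_exposures = pd.concat(
            [homes, compute_exposure_table(
                town.network, homes, town.openspace, town.businesses, town.tracts
            )],
            axis=1,
        )
    children = assign_children(home_exposures, n, seed=int(s_assign), windows=windows)
    children = simulate_outcomes(children, effects, seed=int(s_outcome), bmi_ref=bmi_ref)
    visits = realize_visits(children, bmi_ref, stature_ref, seed=int(s_visits))
    if include_ineligible:
        bad = _ineligible_children(town, windows, bmi_ref, stature_ref, int(s_bad))
        visits = pd.concat([visits, bad], ignore_index=True)
    truth = {
        "seed": int(seed),
        "n": int(n),
        "n_homes": int(n_homes),
        "effects": effects.to_json(),
    }
    return visits, truth


def write_cohort(
    path_csv: str | Path, path_truth: str | Path, visits: pd.DataFrame, truth: dict
) -> None:
    visits.to_csv(path_csv, index=False)
    with open(path_truth, "w") as fh:
        json.dump(truth, fh, indent=1)
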