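# Methods

This note documents the models, numerical choices and limitations behind
`walkbmi`, in the spirit of a statistical software methods appendix.

## Street networks and service areas

A street network is an undirected multigraph over polyline segments in one
projected planar CRS (meters). Segment endpoints within a snap tolerance
(default 0.5 m) are welded into shared nodes by union-find over a spatial
hash; edge weights are geometric polyline lengths. Points (homes, open-space
access points) attach to the network by perpendicular projection onto the
nearest segment, with a maximum allowed offset of 500 m; the projection
offset is included in every reported distance. Coordinates are assumed
planar — a declared geographic CRS (e.g. EPSG:4326) is rejected, but no
magnitude heuristic is applied, since legitimate test fixtures use
small-coordinate planar grids.

*Network distance* is the Dijkstra shortest path between the two
projection points, with each projected point inserted as a temporary graph
node splitting its edge (points sharing an edge are chained in arc-length
order, so the direct sub-edge path is represented). Distances are
truncated at a cap (default 15 km); unreachable pairs report the cap,
i.e. the cap acts by truncation, not exclusion.

*Service areas* collect every centerline portion whose network distance
from the origin is within the radius (default 800 m). For an edge with
end-node distances d_u, d_v and length L, the reached set is
[0, r−d_u] ∪ [L−(r−d_v), L] clipped to [0, L]; partial segments are cut at
exactly the radius. The buffer polygon is the union of round-capped,
round-joined offsets (default 50 m) of the reached portions, built with 32
quadrant segments per quarter circle, which keeps the polygonal cap-area
error near 5 × 10⁻⁴ relative — comfortably inside the 2% Monte-Carlo
acceptance band. Areas are reported in km².

*Intersections* are nodes with ≥ 3 incident segments, counted on the
pedestrian-accessible subnetwork when requested. Degree-2 nodes (segment
joins) never count, so splitting a segment cannot change intersection
density.

## Exposure metrics

Buffer sums and means (traffic density, average speed limit, sidewalk
completeness) are computed over *clipped reached portions*, not whole
intersecting segments. For the speed-limit average this is a documented
interpretation choice: the weighting uses "length of road within the
buffer", which the clipped portions represent exactly; using whole
intersecting segments would differ slightly near the buffer rim.

Sidewalk completeness is the length-weighted mean of the per-segment 0/1/2
code over non-median roads; it is undefined (an error) when only median
roads are reached. Land use mix is the normalized Shannon entropy
−Σ pᵢ ln pᵢ / ln 5 over the five business-category proportions among
points inside the closed buffer polygon; this is the unique standard mix
index matching both defining endpoints (0 for a single category, 1 for an
equal five-way mixture). A buffer containing no businesses is assigned mix
0 and flagged (`land_use_mix_empty`), since "no variety" is the natural
reading of the empty case.

Open-space nearest distance uses one access point per feature — the point
of the feature geometry nearest to the street network — and one
single-source Dijkstra per home, so the per-home cost is independent of the
number of features. Open-space counting uses any geometric intersection
with the buffer polygon (boundary touching counts; overlapping features
count once each).

Residential density and median income are tract-level: the containing
tract's `housing_units / land_area_km2` and `median_income`. A home
outside every tract is an error (upstream, the eligibility filter removes
out-of-region homes first).

## Anthropometry

BMI is weight/height² (kg/m²). Z-scores use the LMS method with reference
rows keyed by sex and half-month age bins (agemos = ⌊months⌋ + 0.5, the
CDC table convention); no interpolation between bins is performed. The
inverse transform is exact, so simulation can realize any target z as a
(height, weight) pair. The inverse is undefined when 1 + L·S·z ≤ 0; the
simulator clips drawn z-scores to 0.97/(|L|·S) (and to ±5.9, inside the
outlier-exclusion range), which at the shipped reference's S values
truncates well under 0.5% of draws.

**Synthetic growth reference.** The package cannot redistribute the CDC
2000 reference tables, so it generates a synthetic stand-in: monthly LMS
rows for ages 24.5–240.5 months, both sexes, for BMI and stature. Median
BMI curves are piecewise-linear through school-age anchors reproducing the
adiposity dip (~15.4 kg/m² near 5.5 y) and adolescent rise (boys ~17.8 at
11 y); S rises from ~0.085 at 4 y to ~0.145 in adolescence; L is a
constant −2 (pediatric BMI is right-skewed). Stature medians interpolate
anchor heights (boys ~143.5 cm at 11 y) with L = 1 and constant CV. The
weight translation of a z contrast — Δweight = [X(Δz) − X(0)] · height² at
the median 11-year-old boy — gives 0.30 kg for Δz = 0.06 and 0.55 kg for
Δz = 0.11 on this reference. Real CDC CSVs (`sex, agemos, L, M, S`) can be
dropped in via `GrowthReference.from_csv` for clinical-grade numbers; the
synthetic reference is for simulation and validation only.

## Eligibility

Criteria are applied in a fixed order (region, age 4 to < 19 at the index
visit, index-window z available, |z| < 6, condition flag, then for the
longitudinal sample ≥ 2 measures and ≥ 365 days between first and last);
the exclusion log records the first failing criterion per child. The
outlier rule is read as *keep* −6 < z < 6, applied at the index visit by
default (`outlier_all_visits` extends it to all visits — the source
protocol is ambiguous on this point). The index visit is the latest
in-window visit; the baseline is the earliest usable measure in the
history span. Criterion "address in the study region" is evaluated as
point-in-polygon against the union of tract geometries.

## Statistics

Exposure quartiles are rank-based: observations ordered by value with ties
broken by child id (stable), then split into four contiguous rank blocks,
so group sizes differ by at most one even under heavy ties (many children
share a home, hence exposure values); empirical 25/50/75 cut points are
reported alongside. Fewer than four distinct values is an error.

Models are ordinary least squares with normal-theory 95% CIs and
two-sided p-values — no clustering or robust variance by default, matching
the source analysis style; HC1 robust errors are available behind a flag.
Design matrices are checked for rank deficiency on column-normalized
copies (so the check is unit-invariant), and the most collinear pair is
named in the error. Race/ethnicity enters as five dummies plus an explicit
missing category. Trend tests refit the same covariate model with the
quartile as a single ordinal term; the p-value is invariant to affine
recoding of 1-2-3-4. Significance is α = 0.05 with no multiple-testing
correction (none is applied in the emulated analysis style) — a caveat,
since the pipeline fits 8 exposures × 3 models × 2 outcomes.

Stratified analyses refit model 3 inside strata of sample income quartile,
age group ([4,10), [10,14), [14,19)), sex, or race, dropping covariates
that are constant within a stratum; strata below a configurable floor (50)
are skipped. Interaction tests add ordinal-quartile × modifier products
and report a joint Wald p.

## Synthetic data: what it emulates, and what it does not

The town is a block grid (default 24 × 150 m blocks) with edges deleted
with probability rising toward the periphery (largest connected component
kept), attribute gradients (central roads: more traffic, lower speeds,
complete sidewalks), centrally concentrated businesses with a balanced
category mixture in the core, Poisson-placed square open spaces, and
square tracts whose income rises outward while housing density falls.
This yields the empirical signature the pipeline needs: all eight metrics
span their quartiles, walkability metrics are mutually correlated, and
tract income is negatively coupled to walkability — making income a
genuine confounder by construction.

Cohort outcomes follow
z = 0.42 + Σ quartile-step effects + γ·(income − mean)/10⁵ + ε,
ε ~ N(0, 1.04); the change score is Δz ~ 0.07 + change effects + N(0, 0.7)
with z_first = z_index − Δz. The marginal SDs 1.04 and 0.7 (and mean
follow-up 3.2 ± 0.8 y, ages uniform on [4, 19), balanced sexes, fixed
race mixture) are the study conditions the generator reproduces. The
first-visit z SD implied by this construction (~1.25) is somewhat above
the ~1.09 a real cohort shows, because the change score is drawn
independently of the index z; the change-outcome calibrations are exact,
which is what the change models consume. Follow-up gaps are truncated so
first visits stay inside the history window and above the reference age
floor; children too young for a compliant earlier visit contribute only a
cross-sectional record, which reproduces the longitudinal-sample shrinkage
seen in practice. One hand-crafted child per eligibility failure mode is
appended so exclusion logging is always exercised.

Not emulated: real street topologies (one-ways, curves, cul-de-sac
geometry beyond random deletion), measurement error in clinic
anthropometry, residential moves, within-tract income heterogeneity,
spatial autocorrelation of outcomes beyond the shared-home structure, and
any direct race/ethnicity effect (none by default; configurable). Passing
tests therefore demonstrate correctness of the *computational pipeline*
under known truth, not epidemiological validity on real data.

## Problem sizes and determinism

Validation runs use a 24-block town, 400 distinct homes (exposures are
computed once per distinct home and broadcast over children), cohorts of
up to 20,000 children, 100 replicates for CI coverage and 500 refits for
null calibration — sizes chosen so the full suite validates the
statistical properties at desk scale. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; town layers, cohort
CSVs and pipeline outputs are byte-stable for a fixed seed.
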