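"""End-to-end pipeline stages: simulate, exposures, analyze.

Each stage reads and writes the package's documented file schemas and a
run manifest (config digest, seed, per-stage record counts), so a full run
is reproducible from its output directory alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from shapely.ops import unary_union

from . import __version__
from .anthropometry import GrowthReference, eligibility_filter, synthetic_growth_reference
from .cohort import CORRELATION_ORDER, quartile_cut, run_all_models, spearman_matrix
from .config import RunConfig
from .errors import WalkbmiError
from .exposures import EXPOSURE_COLUMNS, compute_exposure_table
from .layers import (
    read_businesses, read_openspace, read_streets, read_tracts,
    write_businesses, write_openspace, write_streets, write_tracts,
)
from .simulate import EffectSpec, Town, TownSpec, generate_cohort, generate_town, write_cohort
from .spatial import build_network

log = logging.getLogger("walkbmi")


def _ref(config: RunConfig, which: str) -> GrowthReference:
    path = getattr(config, f"{which}_reference" if which == "stature" else "growth_reference")
    if path:
        return GrowthReference.from_csv(path)
    return synthetic_growth_reference("bmi" if which == "growth" else "stature")


def cmd_simulate(
    config: RunConfig, effects: EffectSpec | None = None, spec: TownSpec | None = None
) -> dict:
    """Generate the synthetic town layers, cohort CSV and ground truth."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    town = generate_town(spec, seed=config.seed)
    visits, truth = generate_cohort(
        town,
        effects=effects,
        n=config.n_children,
        seed=config.seed,
        n_homes=config.n_homes,
        windows=config.windows,
    )
    write_streets(config.path("streets"), town.segments)
    write_openspace(config.path("openspace"), town.openspace)
    write_businesses(config.path("businesses"), town.businesses)
    write_tracts(config.path("tracts"), town.tracts)
    write_cohort(config.path("cohort"), out / "ground_truth.json", visits, truth)
    counts = {"segments": len(town.segments), "visits": len(visits),
              "children": visits["child_id"].nunique()}
    _write_manifest(config, "simulate", counts)
    return counts


def _load_town_inputs(config: RunConfig):
    segments = read_streets(config.path("streets"))
    net = build_network(segments)
    openspace = read_openspace(config.path("openspace"))
    businesses = read_businesses(config.path("businesses"))
    tracts = read_tracts(config.path("tracts"))
    region = unary_union([t.geometry for t in tracts.tracts])
    return net, openspace, businesses, tracts, region


def build_analysis(config: RunConfig, mode: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Eligibility-filter the cohort and attach the eight exposure metrics.

    Returns (analysis rows, exclusion log); one row per eligible child with
    outcome, covariates, exposures and per-exposure quartile labels.
    """
    net, openspace, businesses, tracts, region = _load_town_inputs(config)
    visits = pd.read_csv(config.path("cohort"))
    ref = _ref(config, "growth")
    analysis, excl = eligibility_filter(
        visits, ref, mode=mode, windows=config.windows, region=region
    )
    if analysis.empty:
        raise WalkbmiError(f"no eligible children for mode {mode!r}")
    expo = compute_exposure_table(
        net, analysis[["x", "y"]], openspace, businesses, tracts,
        radius=config.buffer_radius_m, offset=config.buffer_offset_m,
        cap_km=config.distance_cap_km, max_offset=config.max_offset_m,
    )
    # the exposure engine's tract assignment is authoritative
    analysis = pd.concat([analysis.drop(columns=["tract_id"]), expo], axis=1)
    for exp in EXPOSURE_COLUMNS:
        analysis[f"{exp}_q"], _ = quartile_cut(analysis[exp])
    log.info("%s: %d eligible, %d excluded", mode, len(analysis), len(excl))
    return analysis, excl


def cmd_exposures(config: RunConfig) -> pd.DataFrame:
    """Write the per-child exposure table (cross-sectional sample)."""
    analysis, _ = build_analysis(config, "cross_sectional")
    cols = ["child_id"] + EXPOSURE_COLUMNS + ["tract_id", "tract_income_usd"]
    table = analysis[cols]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "exposures.csv", index=False)
    _write_manifest(config, "exposures", {"rows": len(table)})
    return table


def cmd_analyze(config: RunConfig) -> dict:
    """Run the full statistical analysis; write the results tables.

    Outputs: correlation matrix CSV, cross-sectional and change-score
    quartile regression tables, the exclusion logs and a manifest with
    per-stage record counts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    cs, cs_excl = build_analysis(config, "cross_sectional")
    lg, lg_excl = build_analysis(config, "longitudinal")
    rho, pvals = spearman_matrix(cs, CORRELATION_ORDER)
    rho.to_csv(out / "correlations.csv")
    pvals.to_csv(out / "correlation_pvalues.csv")
    tab_cs = run_all_models(cs, outcome="cross_sectional")
    tab_cs.to_csv(out / "results_cross_sectional.csv", index=False)
    tab_ch = run_all_models(lg, outcome="change")
    tab_ch.to_csv(out / "results_change.csv", index=False)
    cs_excl.to_csv(out / "exclusions_cross_sectional.csv", index=False)
    lg_excl.to_csv(out / "exclusions_longitudinal.csv", index=False)
    counts = {
        "cross_sectional_n": len(cs),
        "longitudinal_n": len(lg),
        "excluded_cross_sectional": len(cs_excl),
        "excluded_longitudinal": len(lg_excl),
    }
    if counts["cross_sectional_n"] < counts["longitudinal_n"]:
        raise WalkbmiError(
            "internal inconsistency: longitudinal sample exceeds cross-sectional"
        )
    _write_manifest(config, "analyze", counts)
    results.update(
        correlations=rho, cross_sectional=tab_cs, change=tab_ch, counts=counts
    )
    return results


def _write_manifest(config: RunConfig, stage: str, counts: dict) -> None:
    out = Path(config.out_dir)
    path = out / "manifest.json"
    doc = {}
    if path.exists():
        doc = json.loads(path.read_text())
    doc.setdefault("config_digest", config.digest())
    doc.setdefault("seed", config.seed)
    doc.setdefault("version", __version__)
    doc.setdefault("stages", {})[stage] = counts
    path.write_text(json.dumps(doc, indent=1))
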