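"""Per-site pipeline runs, the omnivory sensitivity sweep, aggregation.

``run_site`` chains the full method for one site: isotope refinements ->
diet-matrix reconstruction -> metabolic demands -> steady-state flux
solve -> trophic-function / body-mass-spectrum summaries.  The omnivory
sweep re-runs it on an 11-point grid of the omnivory parameter (0 to 1,
step 0.1).  ``aggregate_sites`` reduces many solved sites to per-forest
means and sample SDs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import Config
from .energetics import assimilation_efficiency, node_metabolic_demand
from .fluxes import FluxSolution, solve_fluxes
from .io import export_network
from .model import InfeasibleWebError, Resource, SiteBundle, RESOURCE_IDS
from .reconstruction import (
    DietMatrix,
    apply_omnivory,
    build_diet_matrix,
    refine_preferences,
)
from .summaries import (
    BodyMassSpectrum,
    TrophicFunctionSummary,
    bin_spectrum,
    fb_ratio,
    npp_share,
    spectrum_slope,
    trophic_functions,
    TROPHIC_FUNCTIONS,
)

log = logging.getLogger(__name__)

OMNIVORY_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


@dataclass
class SiteResult:
    """Everything computed for one site."""

    bundle: SiteBundle
    diet: DietMatrix
    solution: FluxSolution
    functions: TrophicFunctionSummary
    spectrum: BodyMassSpectrum
    fungivory_bacterivory: float | None
    npp_share_pct: float | None

    @property
    def site_id(self) -> str:
        return self.bundle.context.site_id

    def summary_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "forest_type": self.bundle.context.forest_type,
            "total_biomass_g_m2": sum(g.biomass for g in self.bundle.guilds),
            "total_flux_mW_m2": self.solution.total_flux,
            "max_trophic_level": float(self.solution.TL.max()),
            "functions_mW_m2": self.functions.absolute,
            "functions_pct": self.functions.percent,
            "fungivory_bacterivory": self.fungivory_bacterivory,
            "npp_share_pct": self.npp_share_pct,
            "biomass_slope": self.spectrum.biomass_slope,
            "flux_slope": self.spectrum.flux_slope,
        }


@dataclass
class RunManifest:
    """Provenance record: rerunning with identical inputs reproduces outputs."""

    config_hash: str
    inputs: dict[str, str]
    seed: int | None
    version: str = __version__
    warnings: list[str] = field(default_factory=list)

    @classmethod
    def create(cls, config: Config, inputs: dict[str, str], seed: int | None = None):
        blob = yaml.safe_dump(asdict(config), sort_keys=True).encode()
        return cls(
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            inputs=dict(inputs),
            seed=seed,
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _prepare(bundle: SiteBundle, config: Config) -> SiteBundle:
    if not isinstance(config.omnivory_parameter, str):
        bundle = SiteBundle(
            context=bundle.context,
            guilds=apply_omnivory(bundle.guilds, float(config.omnivory_parameter)),
            missing_isotopes=list(bundle.missing_isotopes),
        )
    return refine_preferences(bundle, config)


def run_site(bundle: SiteBundle, config: Config | None = None) -> SiteResult:
    """Run reconstruction, flux estimation and summaries for one site."""
    config = config or Config()
    try:
        refined = _prepare(bundle, config)
        diet = build_diet_matrix(refined, config)
        temp = bundle.context.mean_annual_temperature
        X = np.array(
            [node_metabolic_demand(g, temp, config) for g in refined.guilds]
        )
        guild_by_id = {g.guild_id: g for g in refined.guilds}
        e = np.array(
            [
                assimilation_efficiency(
                    Resource(nid, assimilation_efficiency=config.efficiency_table[nid])
                    if nid in RESOURCE_IDS
                    else guild_by_id[nid],
                    config,
                )
                for nid in diet.node_ids
            ]
        )
        solution = solve_fluxes(diet, X, e)
    except (InfeasibleWebError, ValueError) as exc:
        raise type(exc)(f"site {bundle.context.site_id!r}: {exc}") from exc

    functions = trophic_functions(solution)
    masses_ug = np.array([g.mean_body_mass * 1000.0 for g in refined.guilds])
    biomass = np.array([g.biomass for g in refined.guilds])
    spectrum = bin_spectrum(masses_ug, biomass, solution.F)
    for quantity, attr in (("biomass", "biomass_slope"), ("flux", "flux_slope")):
        try:
            setattr(spectrum, attr, spectrum_slope(spectrum, quantity))
        except ValueError as exc:
            log.warning("site %s: %s", bundle.context.site_id, exc)
    share = None
    if bundle.context.NPP:
        share = npp_share(solution.total_flux, bundle.context.NPP, config)
    return SiteResult(
        bundle=bundle,
        diet=diet,
        solution=solution,
        functions=functions,
        spectrum=spectrum,
        fungivory_bacterivory=fb_ratio(functions),
        npp_share_pct=share,
    )


def write_site_outputs(result: SiteResult, out_dir: str | Path) -> None:
    """Write nodes.csv, edges.csv, spectrum.csv and summary.json for a site."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sol, diet = result.solution, result.diet
    n_res = diet.n_resources
    nodes = pd.DataFrame(
        {
            "node_id": sol.node_ids,
            "trophic_level": sol.TL,
            "intake_mW_m2": np.concatenate([np.full(n_res, np.nan), sol.F]),
            "metabolism_mW_m2": np.concatenate([np.full(n_res, np.nan), sol.X]),
        }
    )
    nodes.to_csv(out / "nodes.csv", index=False)
    export_network(result.bundle, diet, sol, out / "edges.csv", fmt="csv")
    pd.DataFrame(
        {
            "bin_lo_ug": result.spectrum.bin_edges_ug[:-1],
            "bin_hi_ug": result.spectrum.bin_edges_ug[1:],
            "biomass_g_m2": result.spectrum.biomass,
            "flux_mW_m2": result.spectrum.flux,
        }
    ).to_csv(out / "spectrum.csv", index=False)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(result.summary_dict(), fh, indent=2, sort_keys=True)


def omnivory_sweep(bundle: SiteBundle, config: Config | None = None) -> pd.DataFrame:
    """Trophic-function percentages across the 11-point omnivory grid.

    Returns one row per grid value of the omnivory parameter; infeasible
    grid points are recorded as missing (NaN) with a warning and the
    sweep continues.
    """
    config = config or Config()
    rows = []
    for omega in OMNIVORY_GRID:
        cfg = Config(**{**_config_dict(config), "omnivory_parameter": float(omega)})
        row = {"omega": float(omega)}
        try:
            result = run_site(bundle, cfg)
            row.update(result.functions.percent)
            row["total_flux_mW_m2"] = result.solution.total_flux
        except (InfeasibleWebError, ValueError) as exc:
            log.warning("omnivory sweep at omega=%.1f failed: %s", omega, exc)
            row.update({fn: np.nan for fn in TROPHIC_FUNCTIONS})
            row["total_flux_mW_m2"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _config_dict(config: Config) -> dict:
    d = asdict(config)
    d["animal_efficiency_bounds"] = tuple(d["animal_efficiency_bounds"])
    d["animal_efficiency_N_range"] = tuple(d["animal_efficiency_N_range"])
    return d


def sweep_ranges(sweep: pd.DataFrame) -> pd.DataFrame:
    """Min-max range of each trophic-function percentage over the grid."""
    rows = []
    for fn in TROPHIC_FUNCTIONS:
        rows.append(
            {
                "function": fn,
                "min_pct": float(np.nanmin(sweep[fn])),
                "max_pct": float(np.nanmax(sweep[fn])),
            }
        )
    return pd.DataFrame(rows)


def aggregate_sites(results: list[SiteResult]) -> pd.DataFrame:
    """Forest-type means +- sample SD of the headline site quantities.

    Single-site groups report SD as NaN (flagged undefined rather than 0).
    Includes per-layer biomass means mirroring the layer x forest biomass
    table layout.
    """
    if not results:
        raise ValueError("no site results to aggregate")
    records = []
    for r in results:
        rec = {
            "forest_type": r.bundle.context.forest_type,
            "total_biomass_g_m2": sum(g.biomass for g in r.bundle.guilds),
            "litter_biomass_g_m2": sum(
                g.layer_biomass.get("litter", 0.0) for g in r.bundle.guilds
            ),
            "soil_biomass_g_m2": sum(
                g.layer_biomass.get("soil", 0.0) for g in r.bundle.guilds
            ),
            "total_flux_mW_m2": r.solution.total_flux,
            "max_trophic_level": float(r.solution.TL.max()),
            "biomass_slope": r.spectrum.biomass_slope,
            "flux_slope": r.spectrum.flux_slope,
            "fungivory_bacterivory": r.fungivory_bacterivory,
            "npp_share_pct": r.npp_share_pct,
        }
        rec.update({f"{fn}_pct": r.functions.percent[fn] for fn in TROPHIC_FUNCTIONS})
        records.append(rec)
    df = pd.DataFrame(records)
    agg = df.groupby("forest_type").agg(["mean", "std", "count"])
    agg.columns = ["_".join(c) for c in agg.columns]
    return agg.reset_index()
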