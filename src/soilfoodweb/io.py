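"""Readers, validators and writers for the four input tables and exports.

Input CSVs (comma-separated, UTF-8, ``.`` decimal):

* ``community.csv`` — site_id, layer, guild_id, density, mean_body_mass_mg,
  biomass_g_m2 (biomass may be derived from density x mass; mass may be
  derived from body_length_mm via an allometry table);
* ``traits.csv``    — per-guild feeding preferences, protection,
  microhabitat weights and flags;
* ``isotopes.csv``  — per site and guild litter-calibrated d15N, d13C and
  elemental C/N percentages (optional rows);
* ``sites.csv``     — forest type, mean annual temperature, NPP, pH,
  litter C/N per site.

Solved webs export as an edge-list CSV or GraphML, one row/edge per
nonzero feeding link carrying the diet share and the energy flux.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .energetics import AllometryCoefficients, length_to_mass, lookup_allometry
from .fluxes import FluxSolution
from .model import (
    Guild,
    LinkageError,
    SchemaError,
    SiteBundle,
    SiteContext,
    RESOURCE_IDS,
    SAMPLE_LAYERS,
)
from .reconstruction import DietMatrix

log = logging.getLogger(__name__)

COMMUNITY_REQUIRED = ("site_id", "layer", "guild_id")
TRAIT_PREF_COLS = tuple(f"pref_{r}" for r in RESOURCE_IDS) + ("pref_animal",)
TRAIT_HAB_COLS = ("hab_soil", "hab_litter", "hab_ground", "hab_aboveground")
TRAIT_REQUIRED = (
    ("guild_id", "taxon_group", "phylo_group", "protection")
    + TRAIT_PREF_COLS
    + TRAIT_HAB_COLS
)


def _require_columns(df: pd.DataFrame, required, table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


def load_community(
    path: str | Path,
    allometry: dict[str, AllometryCoefficients] | None = None,
) -> pd.DataFrame:
    """Read and validate a community table.

    Fills ``mean_body_mass_mg`` from ``body_length_mm`` (when an
    allometry table is given) and ``biomass_g_m2`` from density x mass
    when absent.  Biomass is g fresh m^-2; mass mg; density ind m^-2.
    """
    df = pd.read_csv(path)
    _require_columns(df, COMMUNITY_REQUIRED, "community")
    if "biomass_g_m2" not in df.columns and not (
        "density" in df.columns
        and ("mean_body_mass_mg" in df.columns or "body_length_mm" in df.columns)
    ):
        raise SchemaError(
            "community: need biomass_g_m2 or (density and mass/length) columns"
        )
    bad_layers = set(df["layer"]) - set(SAMPLE_LAYERS)
    if bad_layers:
        raise SchemaError(f"community: unknown layer(s) {sorted(bad_layers)}")
    dup = df.duplicated(subset=["site_id", "layer", "guild_id"])
    if dup.any():
        dupes = df.loc[dup, ["site_id", "layer", "guild_id"]].values.tolist()
        raise SchemaError(f"community: duplicate (site, layer, guild) rows {dupes}")

    if "mean_body_mass_mg" not in df.columns:
        df["mean_body_mass_mg"] = np.nan
    if "body_length_mm" in df.columns and allometry is not None:
        need = df["mean_body_mass_mg"].isna() & df["body_length_mm"].notna()
        for idx in df.index[need]:
            coeffs = lookup_allometry(df.at[idx, "guild_id"], allometry)
            df.at[idx, "mean_body_mass_mg"] = length_to_mass(
                df.at[idx, "body_length_mm"], coeffs
            )
    if "biomass_g_m2" not in df.columns:
        df["biomass_g_m2"] = np.nan
    derive = df["biomass_g_m2"].isna()
    if derive.any():
        if "density" not in df.columns:
            raise SchemaError("community: biomass missing and no density column")
        # biomass g m^-2 = density ind m^-2 * mass mg * 1e-3
        df.loc[derive, "biomass_g_m2"] = (
            df.loc[derive, "density"] * df.loc[derive, "mean_body_mass_mg"] * 1e-3
        )
    if df["biomass_g_m2"].isna().any():
        raise SchemaError("community: biomass could not be derived for some rows")
    if (df["biomass_g_m2"] < 0).any():
        bad = df.loc[df["biomass_g_m2"] < 0, "guild_id"].tolist()
        raise ValueError(f"community: negative biomass for {bad}")
    return df


def load_traits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, TRAIT_REQUIRED, "traits")
    if df["guild_id"].duplicated().any():
        raise SchemaError("traits: duplicate guild_id rows")
    return df


def load_isotopes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("guild_id",), "isotopes")
    return df


def load_sites(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(
        df, ("site_id", "forest_type", "mean_annual_temperature_C"), "sites"
    )
    return df


def merge_tables(
    community: pd.DataFrame,
    traits: pd.DataFrame,
    isotopes: pd.DataFrame | None,
    sites: pd.DataFrame,
) -> list[SiteBundle]:
    """Join the four tables into one validated bundle per site.

    Guilds present in the community but absent from the trait table raise
    a linkage error; guilds without isotope rows are flagged (downstream
    isotope weighting is then neutral for them).
    """
    trait_ids = set(traits["guild_id"])
    missing = sorted(set(community["guild_id"]) - trait_ids)
    if missing:
        raise LinkageError(f"guilds missing from trait table: {missing}")
    traits_by_id = traits.set_index("guild_id")

    bundles = []
    for _, srow in sites.iterrows():
        site_id = srow["site_id"]
        comm = community[community["site_id"] == site_id]
        if comm.empty:
            continue
        context = SiteContext(
            site_id=str(site_id),
            forest_type=srow["forest_type"],
            mean_annual_temperature=float(srow["mean_annual_temperature_C"]),
            NPP=_opt(srow, "npp_g_m2_y"),
            soil_pH=_opt(srow, "soil_pH"),
            litter_CN=_opt(srow, "litter_CN"),
        )
        iso = None
        if isotopes is not None and not isotopes.empty:
            iso = isotopes
            if "site_id" in isotopes.columns:
                iso = isotopes[isotopes["site_id"] == site_id]
            iso = iso.set_index("guild_id")

        guilds, flagged = [], []
        for gid, rows in comm.groupby("guild_id", sort=True):
            t = traits_by_id.loc[gid]
            layer_biomass = {
                layer: float(sub["biomass_g_m2"].sum())
                for layer, sub in rows.groupby("layer")
            }
            masses = rows["mean_body_mass_mg"].to_numpy(float)
            weights = rows["biomass_g_m2"].to_numpy(float)
            if weights.sum() > 0:
                mean_mass = float(np.average(masses, weights=weights))
            else:
                mean_mass = float(masses.mean())
            iso_row = None
            if iso is not None and gid in iso.index:
                iso_row = iso.loc[gid]
                if isinstance(iso_row, pd.DataFrame):
                    iso_row = iso_row.iloc[0]
            if iso_row is None:
                flagged.append(str(gid))
            density = (
                float(rows["density"].sum()) if "density" in rows.columns else None
            )
            guilds.append(
                Guild(
                    guild_id=str(gid),
                    taxon_group=str(t["taxon_group"]),
                    phylo_group=str(t["phylo_group"]),
                    layer_biomass=layer_biomass,
                    mean_body_mass=mean_mass,
                    sigma_log_mass=float(t.get("sigma_log_mass", 1.0) or 1.0),
                    preferences={
                        **{r: float(t[f"pref_{r}"]) for r in RESOURCE_IDS},
                        "animal": float(t["pref_animal"]),
                    },
                    protection=float(t["protection"]),
                    habitat={
                        "soil": float(t["hab_soil"]),
                        "litter": float(t["hab_litter"]),
                        "ground": float(t["hab_ground"]),
                        "aboveground": float(t["hab_aboveground"]),
                    },
                    density=density,
                    d15N=_opt(iso_row, "d15N"),
                    d13C=_opt(iso_row, "d13C"),
                    C_pct=_opt(iso_row, "C_pct"),
                    N_pct=_opt(iso_row, "N_pct"),
                    is_earthworm=bool(t.get("is_earthworm", False)),
                    is_omnivore=bool(t.get("is_omnivore", False)),
                )
            )
        if flagged:
            log.warning(
                "site %s: no isotope data for %s; neutral isotope weighting",
                site_id, flagged,
            )
        bundles.append(
            SiteBundle(context=context, guilds=guilds, missing_isotopes=flagged)
        )
    return bundles


def _opt(row, key):
    if row is None or key not in row or pd.isna(row[key]):
        return None
    return float(row[key])


def community_frame(bundle: SiteBundle) -> pd.DataFrame:
    """Round-trip helper: one community-table row per guild and layer."""
    rows = []
    for g in bundle.guilds:
        for layer, b in sorted(g.layer_biomass.items()):
            density = b * 1000.0 / g.mean_body_mass if g.density is not None else None
            rows.append(
                {
                    "site_id": bundle.context.site_id,
                    "layer": layer,
                    "guild_id": g.guild_id,
                    "density": density,
                    "mean_body_mass_mg": g.mean_body_mass,
                    "biomass_g_m2": b,
                }
            )
    return pd.DataFrame(rows)


def _solution_graph(
    bundle: SiteBundle, diet: DietMatrix, solution: FluxSolution
) -> nx.DiGraph:
    graph = nx.DiGraph()
    guilds = {g.guild_id: g for g in bundle.guilds}
    for i, node in enumerate(diet.node_ids):
        attrs = {"trophic_level": float(solution.TL[i])}
        if node in guilds:
            g = guilds[node]
            j = diet.consumer_ids.index(node)
            attrs.update(
                biomass_g_m2=g.biomass,
                body_mass_mg=g.mean_body_mass,
                intake_mW_m2=float(solution.F[j]),
            )
        graph.add_node(node, **attrs)
    for j, cons in enumerate(diet.consumer_ids):
        for i, node in enumerate(diet.node_ids):
            if diet.W[i, j] > 0:
                graph.add_edge(
                    node, cons,
                    diet_share=float(diet.W[i, j]),
                    flux_mW_m2=float(solution.L[i, j]),
                )
    return graph


def export_network(
    bundle: SiteBundle,
    diet: DietMatrix,
    solution: FluxSolution | None,
    path: str | Path,
    fmt: str = "csv",
) -> None:
    """Write the solved web as an edge-list CSV or a GraphML file.

    One row/edge per nonzero diet share, with the share and the link flux
    (mW m^-2); node attributes carry biomass, body mass, trophic level
    and intake.
    """
    if solution is None:
        raise RuntimeError("web is not solved; run the flux solver before export")
    graph = _solution_graph(bundle, diet, solution)
    path = Path(path)
    if fmt == "graphml":
        # GraphML writers reject None attribute values
        for _, attrs in graph.nodes(data=True):
            for k in [k for k, v in attrs.items() if v is None]:
                del attrs[k]
        nx.write_graphml(graph, path)
    elif fmt == "csv":
        rows = [
            {
                "source": u,
                "target": v,
                "diet_share": d["diet_share"],
                "flux_mW_m2": d["flux_mW_m2"],
            }
            for u, v, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
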