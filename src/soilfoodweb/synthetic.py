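"""Seeded synthetic site generator for the five studied forest types.

Generates community/trait/isotope/site tables with the statistical
structure the analysis assumes, so every downstream stage can be
exercised without the original field data:

* total fresh biomass per site drawn from a >0-truncated normal whose
  mean and SD follow the per-forest biomass table (taiga 7.8 +- 3.3,
  mixed broadleaved 17.1 +- 8.7, beech 26.9 +- 11.5, monsoon 50.4 +- 25.1,
  rainforest 6.6 +- 3.1 g m^-2), split between litter and soil layers at
  the tabulated per-forest fraction;
* a guild pool spanning all five body-mass classes, with per-forest
  biomass shares reproducing the macrofauna-dominance gradient (tropical
  > temperate) and earthworm dominance (> 90% of biomass) in mixed
  broadleaved forests; termites occur only in the tropical types;
* stable-isotope signatures with ~3.4 per-mill d15N (and 0.4 per-mill
  d13C) enrichment per intended trophic level over a 0 per-mill
  litter-calibrated baseline, plus Gaussian noise (SD 0.5 per mill).

All randomness flows through one numpy Generator seeded from the
(forest type, seed) pair, so bundles are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from . import io as sfw_io
from .model import FOREST_TYPES, SiteBundle, SiteContext, Guild, RESOURCE_IDS

#: Noise SDs: isotopes (per mill) and body mass (decades on log10 scale).
ISOTOPE_NOISE_SD = 0.5
MASS_NOISE_SD = 0.3

_TEF_N = 3.4
_TEF_C = 0.4


@dataclass(frozen=True)
class GuildTemplate:
    guild_id: str
    taxon_group: str
    log10_mass_mg: float  # center of the body-mass draw
    mass_bin: tuple[float, float]  # clamp range, log10 mg
    tl_intent: float  # intended trophic level (isotope structure)
    preferences: dict[str, float]
    habitat: dict[str, float]
    protection: float = 1.0
    is_earthworm: bool = False
    is_omnivore: bool = False
    N_pct: float = 9.0
    d15N_mean: float | None = None  # overrides the TL-based mean
    phylo_group: str = "invertebrate"


def _b(lo: float, hi: float) -> tuple[float, float]:
    return (np.log10(lo), np.log10(hi))


# log10 mg clamp ranges of the five body-mass classes
BIN1 = _b(5e-5, 1.6e-3)
BIN2 = _b(1.6e-3, 0.05)
BIN3 = _b(0.05, 1.6)
BIN4 = _b(1.6, 50.0)
BIN5 = _b(50.0, 1600.0)

GUILD_POOL: dict[str, GuildTemplate] = {
    t.guild_id: t
    for t in [
        GuildTemplate(
            "nem_bacterivore", "nematode-bacterivore", -3.52, BIN1, 2.0,
            {"B": 1.0}, {"soil": 0.8, "litter": 0.2}, N_pct=10.0,
        ),
        GuildTemplate(
            "nem_fungivore", "nematode-fungivore", -3.4, BIN1, 2.0,
            {"F": 1.0}, {"soil": 0.8, "litter": 0.2}, N_pct=10.0,
        ),
        GuildTemplate(
            "nem_herbivore", "nematode-herbivore", -3.0, BIN1, 2.0,
            {"P": 1.0}, {"soil": 0.9, "litter": 0.1}, N_pct=9.0,
        ),
        GuildTemplate(
            "nem_omnivore", "nematode-omnivore", -2.3, BIN2, 2.7,
            {"B": 0.4, "F": 0.3, "animal": 0.6},
            {"soil": 0.8, "litter": 0.2}, is_omnivore=True, N_pct=10.0,
        ),
        GuildTemplate(
            "nem_predator", "nematode-predator", -2.0, BIN2, 3.0,
            {"animal": 1.0}, {"soil": 0.7, "litter": 0.3}, N_pct=11.0,
        ),
        GuildTemplate(
            "springtail", "springtail", -2.0, BIN2, 2.0,
            {"F": 0.8, "A": 0.4, "L": 0.3},
            {"litter": 0.5, "soil": 0.3, "ground": 0.2},
            protection=0.8, N_pct=9.5, d15N_mean=1.0,
        ),
        GuildTemplate(
            "oribatid_mite", "oribatid-mite", -1.7, BIN2, 2.0,
            {"L": 0.6, "F": 0.6}, {"litter": 0.6, "soil": 0.4},
            protection=0.4, N_pct=8.5,
        ),
        GuildTemplate(
            "mesostig_mite", "mesostigmatid-mite", -1.8, BIN2, 3.0,
            {"animal": 1.0}, {"litter": 0.5, "soil": 0.5}, N_pct=11.0,
        ),
        GuildTemplate(
            "enchytraeid", "enchytraeid", -1.0, BIN3, 2.0,
            {"L": 0.5, "S": 0.5}, {"soil": 0.7, "litter": 0.3}, N_pct=9.0,
        ),
        GuildTemplate(
            "symphylan", "symphylan", -0.5, BIN3, 2.4,
            {"L": 0.5, "F": 0.3, "animal": 0.25},
            {"soil": 0.8, "litter": 0.2}, is_omnivore=True, N_pct=9.5,
        ),
        GuildTemplate(
            "pseudoscorpion", "pseudoscorpion", -0.2, BIN3, 3.2,
            {"animal": 1.0}, {"litter": 0.7, "ground": 0.3}, N_pct=11.0,
        ),
        GuildTemplate(
            "thrips", "thrips", -0.8, BIN3, 2.0,
            {"P": 0.8, "F": 0.3},
            {"litter": 0.3, "ground": 0.3, "aboveground": 0.4}, N_pct=9.0,
        ),
        GuildTemplate(
            "spider", "spider", 0.9, BIN4, 3.4,
            {"animal": 1.0},
            {"ground": 0.5, "litter": 0.4, "aboveground": 0.1}, N_pct=11.5,
        ),
        GuildTemplate(
            "centipede", "centipede", 1.4, BIN4, 3.4,
            {"animal": 1.0},
            {"litter": 0.5, "soil": 0.3, "ground": 0.2}, N_pct=11.0,
        ),
        GuildTemplate(
            "det_beetle", "detritivore-beetle", 1.1, BIN4, 2.0,
            {"L": 0.6, "W": 0.4},
            {"litter": 0.5, "ground": 0.3, "soil": 0.2},
            protection=0.6, N_pct=8.0,
        ),
        GuildTemplate(
            "woodlouse", "woodlouse", 1.2, BIN4, 2.0,
            {"L": 0.7, "W": 0.3}, {"litter": 0.7, "ground": 0.3},
            protection=0.7, N_pct=8.0,
        ),
        GuildTemplate(
            "diplopod", "millipede", 1.5, BIN4, 2.0,
            {"L": 0.7, "S": 0.3}, {"litter": 0.6, "soil": 0.4},
            protection=0.5, N_pct=8.0,
        ),
        GuildTemplate(
            "ant", "ant", 0.6, BIN4, 2.8,
            {"animal": 0.5, "P": 0.25, "F": 0.15},
            {"ground": 0.6, "litter": 0.3, "aboveground": 0.1},
            protection=0.8, is_omnivore=True, N_pct=10.5,
        ),
        GuildTemplate(
            "herb_insect", "herbivorous-insect", 1.3, BIN4, 2.0,
            {"P": 1.0},
            {"aboveground": 0.5, "ground": 0.3, "litter": 0.2}, N_pct=9.0,
        ),
        GuildTemplate(
            "termite", "termite", 0.7, BIN4, 2.0,
            {"W": 0.5, "L": 0.35, "S": 0.15},
            {"soil": 0.4, "litter": 0.4, "ground": 0.2}, N_pct=8.5,
        ),
        GuildTemplate(
            "earthworm_epigeic", "earthworm", 2.2, BIN5, 2.0,
            {"L": 0.85, "S": 0.15}, {"litter": 0.6, "soil": 0.4},
            is_earthworm=True, N_pct=9.0, d15N_mean=1.8,
        ),
        GuildTemplate(
            "earthworm_endogeic", "earthworm", 2.6, BIN5, 2.0,
            {"S": 0.7, "L": 0.3}, {"soil": 1.0},
            is_earthworm=True, N_pct=9.0, d15N_mean=4.8,
        ),
        GuildTemplate(
            "butterfly_larva", "butterfly-larva", 2.0, BIN5, 2.0,
            {"P": 1.0},
            {"aboveground": 0.6, "ground": 0.2, "litter": 0.2}, N_pct=9.5,
        ),
    ]
}


@dataclass(frozen=True)
class ForestPreset:
    """Per-forest generator targets (biomass table, climate, guild shares)."""

    forest_type: str
    litter_mean: float  # g m^-2, tabulated litter-layer mean
    soil_mean: float  # g m^-2, tabulated soil-layer mean
    total_mean: float  # g m^-2, tabulated (printed) total
    total_sd: float
    temperature_C: float
    npp_g_m2_y: float
    soil_pH: float
    litter_CN: float
    guild_shares: dict[str, float] = field(default_factory=dict)
    required: tuple[str, ...] = (
        "nem_bacterivore", "springtail", "enchytraeid", "spider",
        "earthworm_epigeic",
    )
    earthworm_share_range: tuple[float, float] | None = None

    @property
    def litter_fraction(self) -> float:
        return self.litter_mean / (self.litter_mean + self.soil_mean)


PRESETS: dict[str, ForestPreset] = {
    "taiga": ForestPreset(
        "taiga", 4.1, 3.7, 7.8, 3.3, 5.2, 4091.0, 4.1, 28.0,
        guild_shares={
            "nem_bacterivore": 0.06, "nem_fungivore": 0.04, "nem_herbivore": 0.02,
            "nem_omnivore": 0.03, "nem_predator": 0.02, "springtail": 0.15,
            "oribatid_mite": 0.13, "mesostig_mite": 0.04, "enchytraeid": 0.17,
            "symphylan": 0.02, "pseudoscorpion": 0.01, "thrips": 0.01,
            "spider": 0.05, "centipede": 0.03, "det_beetle": 0.05,
            "woodlouse": 0.02, "diplopod": 0.04, "ant": 0.02,
            "herb_insect": 0.01, "earthworm_epigeic": 0.08,
        },
    ),
    "mixed_broadleaved": ForestPreset(
        "mixed_broadleaved", 2.1, 14.9, 17.1, 8.7, 7.1, 3095.0, 5.6, 22.0,
        guild_shares={
            "nem_bacterivore": 0.008, "nem_fungivore": 0.005, "nem_omnivore": 0.004,
            "nem_predator": 0.003, "springtail": 0.012, "oribatid_mite": 0.01,
            "mesostig_mite": 0.004, "enchytraeid": 0.012, "symphylan": 0.002,
            "spider": 0.008, "centipede": 0.006, "det_beetle": 0.006,
            "woodlouse": 0.004, "diplopod": 0.008, "ant": 0.004,
            "earthworm_epigeic": 0.13, "earthworm_endogeic": 0.80,
        },
        required=(
            "nem_bacterivore", "springtail", "enchytraeid", "spider",
            "earthworm_epigeic", "earthworm_endogeic",
        ),
        earthworm_share_range=(0.91, 0.965),
    ),
    "beech": ForestPreset(
        "beech", 15.7, 11.2, 26.9, 11.5, 7.5, 4690.0, 4.8, 24.0,
        guild_shares={
            "nem_bacterivore": 0.03, "nem_fungivore": 0.02, "nem_herbivore": 0.01,
            "nem_omnivore": 0.02, "nem_predator": 0.01, "springtail": 0.08,
            "oribatid_mite": 0.07, "mesostig_mite": 0.03, "enchytraeid": 0.09,
            "symphylan": 0.02, "pseudoscorpion": 0.01, "thrips": 0.01,
            "spider": 0.05, "centipede": 0.04, "det_beetle": 0.07,
            "woodlouse": 0.07, "diplopod": 0.09, "ant": 0.03,
            "herb_insect": 0.02, "earthworm_epigeic": 0.12,
            "earthworm_endogeic": 0.11,
        },
    ),
    "monsoon": ForestPreset(
        "monsoon", 27.5, 22.9, 50.4, 25.1, 26.0, 6050.0, 6.2, 18.0,
        guild_shares={
            "nem_bacterivore": 0.01, "nem_fungivore": 0.005, "nem_herbivore": 0.005,
            "nem_omnivore": 0.005, "nem_predator": 0.005, "springtail": 0.02,
            "oribatid_mite": 0.015, "mesostig_mite": 0.005, "enchytraeid": 0.01,
            "thrips": 0.005, "spider": 0.06, "centipede": 0.04,
            "det_beetle": 0.04, "woodlouse": 0.03, "diplopod": 0.05,
            "ant": 0.08, "herb_insect": 0.10, "termite": 0.25,
            "earthworm_epigeic": 0.12, "earthworm_endogeic": 0.08,
            "butterfly_larva": 0.08,
        },
        required=(
            "nem_bacterivore", "springtail", "enchytraeid", "spider",
            "earthworm_epigeic", "termite",
        ),
    ),
    "rainforest": ForestPreset(
        "rainforest", 2.9, 3.7, 6.6, 3.1, 25.2, 7177.0, 4.3, 30.0,
        guild_shares={
            "nem_bacterivore": 0.02, "nem_fungivore": 0.015, "nem_herbivore": 0.01,
            "nem_omnivore": 0.01, "nem_predator": 0.01, "springtail": 0.05,
            "oribatid_mite": 0.04, "mesostig_mite": 0.015, "enchytraeid": 0.03,
            "symphylan": 0.01, "pseudoscorpion": 0.01, "thrips": 0.01,
            "spider": 0.08, "centipede": 0.04, "det_beetle": 0.05,
            "woodlouse": 0.03, "diplopod": 0.06, "ant": 0.13,
            "herb_insect": 0.06, "termite": 0.18, "earthworm_epigeic": 0.09,
            "butterfly_larva": 0.04,
        },
        required=(
            "nem_bacterivore", "springtail", "enchytraeid", "spider",
            "earthworm_epigeic", "termite",
        ),
    ),
}

#: Guilds treated as macrofauna for the dominance gradient (mass >= 1.6 mg).
MACROFAUNA_GUILDS = tuple(
    g for g, t in GUILD_POOL.items() if t.log10_mass_mg >= np.log10(1.6)
)


@lru_cache(maxsize=None)
def _calibrated_loc(mean: float, sd: float) -> float:
    """Location of a >0-truncated normal whose truncated mean equals `mean`."""

    def trunc_mean_minus_target(loc: float) -> float:
        a = (0.0 - loc) / sd
        return truncnorm.mean(a, np.inf, loc=loc, scale=sd) - mean

    return float(brentq(trunc_mean_minus_target, mean - 6 * sd, mean + sd))


def generate_site(forest_type: str, seed: int) -> SiteBundle:
    """Draw one synthetic site for a forest type, reproducible by seed."""
    frames = generate_site_tables(forest_type, seed)
    bundles = sfw_io.merge_tables(
        frames["community"], frames["traits"], frames["isotopes"], frames["sites"]
    )
    return bundles[0]


def generate_site_tables(forest_type: str, seed: int) -> dict[str, pd.DataFrame]:
    """Draw one synthetic site as the four raw input tables.

    Returns a dict with keys ``community``, ``traits``, ``isotopes`` and
    ``sites`` matching the CSV schemas of :mod:`soilfoodweb.io`.
    """
    if forest_type not in PRESETS:
        raise ValueError(
            f"unknown forest type {forest_type!r}; expected one of {FOREST_TYPES}"
        )
    preset = PRESETS[forest_type]
    rng = np.random.default_rng([int(seed), FOREST_TYPES.index(forest_type)])
    site_id = f"{forest_type}_{seed}"

    # --- total biomass: >0-truncated normal, location calibrated so the
    # truncated-distribution mean equals the tabulated mean
    loc = _calibrated_loc(preset.total_mean, preset.total_sd)
    a = (0.0 - loc) / preset.total_sd
    total_biomass = float(
        truncnorm.rvs(a, np.inf, loc=loc, scale=preset.total_sd, random_state=rng)
    )

    # --- guild subset: required guilds always present, others kept w.p. 0.75
    chosen = []
    for gid in preset.guild_shares:
        if gid in preset.required or rng.random() < 0.75:
            chosen.append(gid)

    # --- biomass shares
    if preset.earthworm_share_range is not None:
        lo, hi = preset.earthworm_share_range
        ew_total = rng.uniform(lo, hi)
        ew_ids = [g for g in chosen if GUILD_POOL[g].is_earthworm]
        ew_base = np.array([preset.guild_shares[g] for g in ew_ids])
        ew_shares = dict(zip(ew_ids, ew_total * ew_base / ew_base.sum()))
        other_ids = [g for g in chosen if g not in ew_ids]
        other_base = np.array([preset.guild_shares[g] for g in other_ids])
        other_draw = rng.dirichlet(other_base / other_base.sum() * 60.0)
        shares = {**ew_shares, **dict(zip(other_ids, (1 - ew_total) * other_draw))}
    else:
        base = np.array([preset.guild_shares[g] for g in chosen])
        draw = rng.dirichlet(base / base.sum() * 60.0)
        shares = dict(zip(chosen, draw))

    litter_frac = preset.litter_fraction
    comm_rows, iso_rows, trait_rows = [], [], []
    for gid in sorted(chosen):
        t = GUILD_POOL[gid]
        biomass = total_biomass * shares[gid]
        log_mass = np.clip(
            t.log10_mass_mg + rng.normal(0.0, MASS_NOISE_SD),
            t.mass_bin[0] + 0.02, t.mass_bin[1] - 0.02,
        )
        mass_mg = float(10 ** log_mass)
        for layer, frac in (("litter", litter_frac), ("soil", 1 - litter_frac)):
            b = biomass * frac
            comm_rows.append(
                {
                    "site_id": site_id,
                    "layer": layer,
                    "guild_id": gid,
                    "density": b * 1000.0 / mass_mg,
                    "mean_body_mass_mg": mass_mg,
                    "biomass_g_m2": b,
                }
            )
        if t.d15N_mean is not None:
            d15n = rng.normal(t.d15N_mean, 0.4)
            if t.is_earthworm:
                d15n = float(np.clip(d15n, 1.2, 5.5))
        else:
            d15n = rng.normal(_TEF_N * (t.tl_intent - 1.0), ISOTOPE_NOISE_SD)
        d13c = rng.normal(_TEF_C * (t.tl_intent - 1.0), ISOTOPE_NOISE_SD)
        iso_rows.append(
            {
                "site_id": site_id,
                "guild_id": gid,
                "d15N": float(d15n),
                "d13C": float(d13c),
                "C_pct": float(rng.normal(45.0, 2.0)),
                "N_pct": float(np.clip(rng.normal(t.N_pct, 0.8), 5.0, 12.0)),
            }
        )
        trait_rows.append(_trait_row(t))

    sites = pd.DataFrame(
        [
            {
                "site_id": site_id,
                "forest_type": forest_type,
                "mean_annual_temperature_C": preset.temperature_C,
                "npp_g_m2_y": preset.npp_g_m2_y,
                "soil_pH": preset.soil_pH,
                "litter_CN": preset.litter_CN,
            }
        ]
    )
    return {
        "community": pd.DataFrame(comm_rows),
        "traits": pd.DataFrame(trait_rows),
        "isotopes": pd.DataFrame(iso_rows),
        "sites": sites,
    }


def _trait_row(t: GuildTemplate) -> dict:
    row = {
        "guild_id": t.guild_id,
        "taxon_group": t.taxon_group,
        "phylo_group": t.phylo_group,
        "protection": t.protection,
        "sigma_log_mass": 1.0,
        "is_earthworm": t.is_earthworm,
        "is_omnivore": t.is_omnivore,
    }
    for r in RESOURCE_IDS:
        row[f"pref_{r}"] = t.preferences.get(r, 0.0)
    row["pref_animal"] = t.preferences.get("animal", 0.0)
    for h in ("soil", "litter", "ground", "aboveground"):
        row[f"hab_{h}"] = t.habitat.get(h, 0.0)
    return row


# ---------------------------------------------------------------------------
# tiny fixture webs with analytically tractable diet matrices


def _fixture_guild(gid: str, biomass: float, mass_mg: float, prefs, **kw) -> Guild:
    return Guild(
        guild_id=gid,
        taxon_group=gid,
        layer_biomass={"litter": biomass},
        mean_body_mass=mass_mg,
        preferences=prefs,
        habitat={"litter": 1.0},
        **kw,
    )


def generate_fixture_web(kind: str) -> SiteBundle:
    """Hand-specified miniature webs for exact testing.

    * ``chain3``: litter -> detritivore -> predator;
    * ``loop``:   two mutually preying omnivores over litter;
    * ``star``:   one predator over three prey differing only in biomass
      (2:1 between the first two; diet shares follow biomass).
    """
    context = SiteContext(
        site_id=f"fixture_{kind}", forest_type="beech", mean_annual_temperature=7.5
    )
    if kind == "chain3":
        guilds = [
            _fixture_guild("detritivore", 5.0, 1.0, {"L": 1.0}),
            _fixture_guild("predator", 0.5, 100.0, {"animal": 1.0}),
        ]
    elif kind == "loop":
        guilds = [
            _fixture_guild(
                "omnivore_a", 2.0, 10.0, {"L": 0.5, "animal": 0.5}, is_omnivore=True
            ),
            _fixture_guild(
                "omnivore_b", 2.0, 10.0, {"L": 0.5, "animal": 0.5}, is_omnivore=True
            ),
        ]
    elif kind == "star":
        guilds = [
            _fixture_guild("prey_big", 2.0, 1.0, {"L": 1.0}),
            _fixture_guild("prey_mid", 1.0, 1.0, {"L": 1.0}),
            _fixture_guild("prey_small", 0.5, 1.0, {"L": 1.0}),
            _fixture_guild("predator", 0.2, 100.0, {"animal": 1.0}),
        ]
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return SiteBundle(context=context, guilds=guilds)
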