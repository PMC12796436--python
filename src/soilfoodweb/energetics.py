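"""Allometry, metabolic rates and assimilation efficiencies.

Individual metabolic rate follows the metabolic theory of ecology:

    ln I = ln b0 + a * ln M - E / (k * T)

with I in J h^-1, M fresh body mass in mg, T in kelvin, E the activation
energy in eV and k the Boltzmann constant.  Community-level metabolic
demand of a guild is the individual rate times the number of individuals
per square meter.  Assimilation efficiencies are diet-specific: fixed per
basal resource, and for animal prey an increasing function of tissue
nitrogen content clipped to [0.50, 0.99].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import Config
from .model import Guild, Resource

log = logging.getLogger(__name__)

#: J h^-1 -> mW  (1 J h^-1 = 1000/3600 mW).
JPH_TO_MW = 1.0 / 3.6


@dataclass
class MetabolicCoefficients:
    """Metabolic regression constants for one phylogenetic group."""

    phylo_group: str
    ln_b0: float  # intercept, ln(J h^-1)
    a: float  # mass exponent
    E: float  # activation energy, eV

    def __post_init__(self) -> None:
        if not 0 < self.a < 1.5:
            raise ValueError(f"{self.phylo_group}: mass exponent out of (0, 1.5)")
        if not 0 <= self.E <= 2:
            raise ValueError(f"{self.phylo_group}: activation energy out of [0, 2] eV")


@dataclass
class AllometryCoefficients:
    """Length-mass regression log10(mass mg) = a_len + b_len*log10(length mm)."""

    taxon_group: str
    a_len: float
    b_len: float

    def __post_init__(self) -> None:
        if not 1 < self.b_len < 4:
            raise ValueError(f"{self.taxon_group}: length exponent out of (1, 4)")


def load_coefficient_tables(path: str | None = None) -> dict:
    """Load the editable coefficient tables (metabolic, allometry,
    efficiencies) from YAML; defaults to the packaged table.

    Returns a dict with keys ``metabolic`` (per phylo_group dicts usable
    in :class:`soilfoodweb.config.Config`), ``allometry`` (per
    taxon_group :class:`AllometryCoefficients`) and ``efficiencies``.
    """
    import yaml

    if path is None:
        from importlib.resources import files

        text = files("soilfoodweb.data").joinpath("coefficients.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    metabolic = {
        group: {k: v for k, v in entry.items() if k in ("ln_b0", "a", "E")}
        for group, entry in raw.get("metabolic", {}).items()
    }
    allometry = {
        taxon: AllometryCoefficients(taxon, entry["a_len"], entry["b_len"])
        for taxon, entry in raw.get("allometry", {}).items()
    }
    return {
        "metabolic": metabolic,
        "allometry": allometry,
        "efficiencies": dict(raw.get("efficiencies", {})),
    }


def length_to_mass(length_mm: float, coeffs: AllometryCoefficients) -> float:
    """Fresh body mass (mg) from body length (mm) by power-law regression."""
    if length_mm <= 0:
        raise ValueError("body length must be > 0")
    return float(10 ** (coeffs.a_len + coeffs.b_len * np.log10(length_mm)))


def lookup_allometry(
    taxon_group: str, table: dict[str, AllometryCoefficients]
) -> AllometryCoefficients:
    try:
        return table[taxon_group]
    except KeyError:
        raise KeyError(
            f"no length-mass coefficients for taxon {taxon_group!r}"
        ) from None


def individual_metabolic_rate(
    mass_mg: float, temperature_C: float, coeffs: MetabolicCoefficients,
    boltzmann_k: float = 8.617e-5,
) -> float:
    """Metabolic rate of one individual, mW.

    Evaluates exp(ln_b0 + a*ln(M) - E/(k*T_K)) J h^-1 and converts to mW.
    """
    if mass_mg <= 0:
        raise ValueError("body mass must be > 0")
    if temperature_C <= -273.15:
        raise ValueError("temperature below absolute zero")
    t_kelvin = temperature_C + 273.15
    ln_rate = coeffs.ln_b0 + coeffs.a * np.log(mass_mg) - coeffs.E / (boltzmann_k * t_kelvin)
    return float(np.exp(ln_rate) * JPH_TO_MW)


def node_metabolic_demand(
    guild: Guild, temperature_C: float, config: Config
) -> float:
    """Community metabolic loss X of a guild, mW m^-2.

    X = (biomass g m^-2 * 1000 / mean mass mg) * individual rate mW.
    """
    if guild.mean_body_mass <= 0:
        raise ValueError(f"{guild.guild_id}: zero body mass")
    group = guild.phylo_group
    table = config.metabolic_coefficients
    raw = table.get(group) or table.get("invertebrate")
    if raw is None:
        raise KeyError(f"no metabolic coefficients for phylo group {group!r}")
    coeffs = MetabolicCoefficients(phylo_group=group, **raw)
    rate = individual_metabolic_rate(
        guild.mean_body_mass, temperature_C, coeffs, config.boltzmann_k
    )
    n_individuals = guild.biomass * 1000.0 / guild.mean_body_mass
    return float(n_individuals * rate)


def assimilation_efficiency(node: Resource | Guild, config: Config) -> float:
    """Diet-specific assimilation efficiency of a prey/resource node.

    Basal resources come from the configured table; animal prey scale
    linearly with tissue N%% between the configured bounds.  Missing N%%
    falls back to the bound midpoint (logged).
    """
    if isinstance(node, Resource):
        return float(config.efficiency_table[node.resource_id])
    lo, hi = config.animal_efficiency_bounds
    n_lo, n_hi = config.animal_efficiency_N_range
    if node.N_pct is None:
        log.warning(
            "guild %s has no N%%; using midpoint animal efficiency %.3f",
            node.guild_id, (lo + hi) / 2,
        )
        return (lo + hi) / 2
    frac = (node.N_pct - n_lo) / (n_hi - n_lo)
    return float(np.clip(lo + frac * (hi - lo), lo, hi))
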