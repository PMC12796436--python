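"""Core domain types for soil food-web reconstruction.

A food web is built from seven basal resources plus a set of consumer
guilds (trophic groups of soil invertebrates).  Each guild carries a
body-mass distribution (log10 scale), fresh biomass per layer, graded
feeding preferences, protection and microhabitat traits, and optionally a
litter-calibrated stable-isotope signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Basal resource identifiers: A algae, P living plants, B bacteria,
#: F fungi, L leaf litter, W deadwood, S soil organic matter.
RESOURCE_IDS = ("A", "P", "B", "F", "L", "W", "S")

RESOURCE_NAMES = {
    "A": "algae",
    "P": "plants",
    "B": "bacteria",
    "F": "fungi",
    "L": "litter",
    "W": "deadwood",
    "S": "soil_organic_matter",
}

#: Microhabitat strata used for the spatial-niche overlap.
HABITAT_LAYERS = ("soil", "litter", "ground", "aboveground")

#: Community-table layers (sampling strata for biomass only).
SAMPLE_LAYERS = ("litter", "soil")

FOREST_TYPES = ("taiga", "mixed_broadleaved", "beech", "monsoon", "rainforest")


class SchemaError(ValueError):
    """An input table violates its declared schema."""


class LinkageError(ValueError):
    """Guild identifiers fail to join across input tables."""


class InfeasibleWebError(ValueError):
    """A web cannot be reconstructed or energetically balanced."""


@dataclass
class Resource:
    """A basal resource node (trophic level 1, unlimited source)."""

    resource_id: str
    N_pct: float | None = None
    assimilation_efficiency: float = 0.5

    def __post_init__(self) -> None:
        if self.resource_id not in RESOURCE_IDS:
            raise ValueError(
                f"unknown resource {self.resource_id!r}; expected one of {RESOURCE_IDS}"
            )
        if not 0 < self.assimilation_efficiency <= 1:
            raise ValueError(
                f"assimilation efficiency for {self.resource_id} must be in (0, 1], "
                f"got {self.assimilation_efficiency}"
            )


@dataclass
class Guild:
    """A consumer guild: one trophic node with traits and biomass.

    Parameters
    ----------
    guild_id
        Unique identifier within a site.
    taxon_group
        Free-text taxon label (e.g. ``earthworm``, ``springtail``).
    layer_biomass
        Fresh biomass (g m^-2) per sampling layer (``litter``/``soil``).
    mean_body_mass
        Site-specific mean fresh body mass, mg.
    sigma_log_mass
        SD of the body-mass distribution on the log10 scale (default 1).
    preferences
        Graded feeding weights in [0, 1] keyed by the seven resource ids
        plus ``"animal"`` for predation on other invertebrates.
    protection
        Prey protection multiplier in [0, 1]; 1 = unprotected.
    habitat
        Microhabitat weights over soil/litter/ground/aboveground, sum 1.
    phylo_group
        Key into the metabolic-coefficient table.
    """

    guild_id: str
    taxon_group: str
    layer_biomass: dict[str, float]
    mean_body_mass: float
    preferences: dict[str, float]
    habitat: dict[str, float]
    phylo_group: str = "invertebrate"
    sigma_log_mass: float = 1.0
    protection: float = 1.0
    density: float | None = None
    d15N: float | None = None
    d13C: float | None = None
    C_pct: float | None = None
    N_pct: float | None = None
    is_earthworm: bool = False
    is_omnivore: bool = False

    def __post_init__(self) -> None:
        if self.mean_body_mass <= 0:
            raise ValueError(f"{self.guild_id}: mean body mass must be > 0")
        if self.sigma_log_mass <= 0:
            raise ValueError(f"{self.guild_id}: sigma_log_mass must be > 0")
        if not 0 <= self.protection <= 1:
            raise ValueError(f"{self.guild_id}: protection must be in [0, 1]")
        for layer, b in self.layer_biomass.items():
            if layer not in SAMPLE_LAYERS:
                raise ValueError(f"{self.guild_id}: unknown layer {layer!r}")
            if b < 0:
                raise ValueError(f"{self.guild_id}: negative biomass in {layer!r}")
        hsum = sum(self.habitat.get(h, 0.0) for h in HABITAT_LAYERS)
        if abs(hsum - 1.0) > 1e-9:
            raise ValueError(
                f"{self.guild_id}: habitat weights must sum to 1, got {hsum:.6g}"
            )
        for key, p in self.preferences.items():
            if key not in RESOURCE_IDS and key != "animal":
                raise ValueError(f"{self.guild_id}: unknown preference key {key!r}")
            if not 0 <= p <= 1:
                raise ValueError(f"{self.guild_id}: preference {key} out of [0, 1]")
        if not any(p > 0 for p in self.preferences.values()):
            raise ValueError(f"{self.guild_id}: at least one preference must be > 0")

    @property
    def biomass(self) -> float:
        """Total fresh biomass, g m^-2 (litter + soil layers summed)."""
        return float(sum(self.layer_biomass.values()))

    @property
    def log10_mass(self) -> float:
        """log10 of mean fresh body mass in mg."""
        return float(np.log10(self.mean_body_mass))

    def copy(self, **changes) -> "Guild":
        """Shallow-copied guild with dict fields duplicated."""
        out = replace(
            self,
            layer_biomass=dict(self.layer_biomass),
            preferences=dict(self.preferences),
            habitat=dict(self.habitat),
        )
        for k, v in changes.items():
            setattr(out, k, v)
        return out


@dataclass
class SiteContext:
    """Per-site environment: forest type, temperature, productivity."""

    site_id: str
    forest_type: str
    mean_annual_temperature: float
    NPP: float | None = None
    soil_pH: float | None = None
    litter_CN: float | None = None

    def __post_init__(self) -> None:
        if self.forest_type not in FOREST_TYPES:
            raise ValueError(
                f"unknown forest type {self.forest_type!r}; expected one of {FOREST_TYPES}"
            )
        if not np.isfinite(self.mean_annual_temperature):
            raise ValueError(f"{self.site_id}: temperature must be finite")
        if self.NPP is not None and self.NPP <= 0:
            raise ValueError(f"{self.site_id}: NPP must be > 0")


@dataclass
class SiteBundle:
    """One site's merged analysis inputs: context + guilds + QC flags."""

    context: SiteContext
    guilds: list[Guild]
    missing_isotopes: list[str] = field(default_factory=list)

    @property
    def guild_ids(self) -> list[str]:
        return [g.guild_id for g in self.guilds]

    def copy(self) -> "SiteBundle":
        return SiteBundle(
            context=self.context,
            guilds=[g.copy() for g in self.guilds],
            missing_isotopes=list(self.missing_isotopes),
        )
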