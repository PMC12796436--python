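"""Run configuration: niche-model constants, isotope thresholds, energetics.

All tunables of the reconstruction and flux pipeline live here so a run is
fully described by (input tables, Config, seed).  Defaults follow the
standard soil food-web parameterisation: optimum predator-prey mass ratio
100, trophic enrichment factors +3.4 per mill d15N and +0.4 per mill d13C per
trophic step, resource assimilation efficiencies increasing with nitrogen
content, and an energy density of 7e6 J per kg fresh biomass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Boltzmann constant, eV K^-1 (Arrhenius temperature correction).
BOLTZMANN_K = 8.617e-5

#: Seconds in a 365-day year; used for mW -> g fresh biomass y^-1.
SECONDS_PER_YEAR = 31_536_000

#: J per kg fresh biomass.
ENERGY_DENSITY_J_PER_KG = 7e6


def _default_efficiencies() -> dict[str, float]:
    # A (algae) defaults to the fungal value; see Config docstring.
    return {"P": 0.21, "L": 0.18, "S": 0.13, "B": 0.96, "F": 0.36, "A": 0.36, "W": 0.18}


def _default_metabolic() -> dict[str, dict[str, float]]:
    # General invertebrate regression ln I = ln_b0 + a ln M - E/(kT),
    # I in J h^-1, M fresh mass in mg (Ehnes et al. 2011 all-group fit).
    return {"invertebrate": {"ln_b0": 23.055, "a": 0.695, "E": 0.686}}


@dataclass
class Config:
    """All tunable constants of the reconstruction/flux pipeline.

    Attributes
    ----------
    ppmr_optimum
        Optimum predator-prey fresh-mass ratio (dimensionless), default 100.
    sigma_log_mass
        Default SD of guild body-mass distributions on the log10 scale.
    tef_d15N, tef_d13C
        Trophic enrichment factors, per mill per trophic step.
    isotope_bandwidth
        Gaussian kernel bandwidth (per mill) for the isotopic-distance
        link weight; default one d15N enrichment step (3.4).
    algivory_d15N_zero, algivory_d15N_full
        d15N endpoints of the algivory rescaling (0% at 2.0, 100% at -1.4).
    earthworm_d15N_litter, earthworm_d15N_soil
        d15N endpoints of the earthworm litter-vs-soil diet split.
    omnivory_parameter
        Either the string ``"as-given"`` (use trait-table preferences) or a
        float in [0, 1] scaling auxiliary resources against the main one.
    efficiency_table
        Assimilation efficiency per basal resource id.
    animal_efficiency_bounds
        Clip range for prey (animal) assimilation efficiencies.
    animal_efficiency_N_range
        N%% range linearly mapped onto the bounds.
    metabolic_coefficients
        Per phylo_group: ln_b0 (ln J h^-1), a (mass exponent), E (eV).
    """

    ppmr_optimum: float = 100.0
    sigma_log_mass: float = 1.0
    tef_d15N: float = 3.4
    tef_d13C: float = 0.4
    isotope_bandwidth: float = 3.4
    algivory_d15N_zero: float = 2.0
    algivory_d15N_full: float = -1.4
    earthworm_d15N_litter: float = 1.2
    earthworm_d15N_soil: float = 5.5
    omnivory_parameter: float | str = "as-given"
    efficiency_table: dict[str, float] = field(default_factory=_default_efficiencies)
    animal_efficiency_bounds: tuple[float, float] = (0.50, 0.99)
    animal_efficiency_N_range: tuple[float, float] = (5.0, 12.0)
    energy_density: float = ENERGY_DENSITY_J_PER_KG
    seconds_per_year: float = SECONDS_PER_YEAR
    metabolic_coefficients: dict[str, dict[str, float]] = field(
        default_factory=_default_metabolic
    )
    boltzmann_k: float = BOLTZMANN_K
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.omnivory_parameter, str):
            if self.omnivory_parameter != "as-given":
                raise ValueError(
                    f"omnivory_parameter must be a float or 'as-given', "
                    f"got {self.omnivory_parameter!r}"
                )
        elif not 0 <= float(self.omnivory_parameter) <= 1:
            raise ValueError("omnivory_parameter must lie in [0, 1]")
        for rid, e in self.efficiency_table.items():
            if not 0 < e <= 1:
                raise ValueError(f"efficiency for {rid!r} must be in (0, 1], got {e}")
        lo, hi = self.animal_efficiency_bounds
        if not (0 < lo <= hi <= 1):
            raise ValueError("animal efficiency bounds must satisfy 0 < lo <= hi <= 1")
        if self.ppmr_optimum <= 0 or self.sigma_log_mass <= 0:
            raise ValueError("ppmr_optimum and sigma_log_mass must be > 0")
        if self.isotope_bandwidth <= 0:
            raise ValueError("isotope_bandwidth must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "animal_efficiency_bounds" in raw:
            raw["animal_efficiency_bounds"] = tuple(raw["animal_efficiency_bounds"])
        if "animal_efficiency_N_range" in raw:
            raw["animal_efficiency_N_range"] = tuple(raw["animal_efficiency_N_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["animal_efficiency_bounds"] = list(self.animal_efficiency_bounds)
        data["animal_efficiency_N_range"] = list(self.animal_efficiency_N_range)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
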