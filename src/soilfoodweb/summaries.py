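"""Headline quantities from a solved web.

Trophic functions partition the total energy flux by the class of the
link's source node: herbivory (living plants), algivory, bacterivory,
fungivory, litter consumption, deadwood consumption, soil consumption,
and predation (all links whose source is an invertebrate node).  Because
every link source is exactly one of these eight classes, the eight
absolute fluxes sum to the total flux and the percentages to 100.

Body-mass spectra use five log10-width bins of fresh body mass
(0.05-1.6 ug, 1.6-50 ug, 0.05-1.6 mg, 1.6-50 mg, 0.05-1.6 g); the slope
of log10(bin total) on log10(bin geometric midpoint) is fitted on bins
1-4 only, since the largest bin is prone to undersampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import Config
from .fluxes import FluxSolution

log = logging.getLogger(__name__)

TROPHIC_FUNCTIONS = (
    "predation", "algivory", "herbivory", "bacterivory", "fungivory",
    "litter_consumption", "wood_consumption", "soil_consumption",
)

_RESOURCE_FUNCTION = {
    "A": "algivory", "P": "herbivory", "B": "bacterivory", "F": "fungivory",
    "L": "litter_consumption", "W": "wood_consumption", "S": "soil_consumption",
}

#: Body-mass bin edges in ug fresh mass, half-open [lo, hi); printed
#: (rounded) edges of 1.5-decade bins -- geometric midpoints are spaced
#: exactly 1.5 decades.
MASS_BIN_EDGES_UG = (0.05, 1.6, 50.0, 1600.0, 50_000.0, 1_600_000.0)

MASS_BIN_LABELS = (
    "microfauna",
    "large_microfauna_microarthropods",
    "small_macrofauna",
    "macrofauna",
    "large_macrofauna",
)

LOG_BIN_WIDTH = float(np.log10(MASS_BIN_EDGES_UG[1] / MASS_BIN_EDGES_UG[0]))


@dataclass
class TrophicFunctionSummary:
    """Absolute (mW m^-2) and percent-of-total flux per trophic function."""

    absolute: dict[str, float]
    percent: dict[str, float]
    total_flux: float


@dataclass
class BodyMassSpectrum:
    """Per-bin biomass and intake-flux totals with fitted log-log slopes."""

    bin_edges_ug: tuple[float, ...]
    biomass: np.ndarray  # g m^-2 per bin
    flux: np.ndarray  # mW m^-2 per bin (node intake F)
    biomass_slope: float | None = None
    flux_slope: float | None = None


def trophic_functions(solution: FluxSolution) -> TrophicFunctionSummary:
    """Sum outgoing link fluxes by source class; scale to percentages."""
    total = solution.total_flux
    if total == 0:
        raise ValueError("total flux is zero; percentages undefined")
    n_res = len(solution.node_ids) - len(solution.consumer_ids)
    absolute = {fn: 0.0 for fn in TROPHIC_FUNCTIONS}
    for i, node in enumerate(solution.node_ids):
        out = float(solution.L[i, :].sum())
        if i < n_res:
            absolute[_RESOURCE_FUNCTION[node]] += out
        else:
            absolute["predation"] += out
    percent = {fn: v / total * 100.0 for fn, v in absolute.items()}
    return TrophicFunctionSummary(absolute=absolute, percent=percent, total_flux=total)


def fb_ratio(summary: TrophicFunctionSummary) -> float | None:
    """Fungivory-to-bacterivory ratio of absolute fluxes; None if undefined."""
    b = summary.absolute["bacterivory"]
    if b == 0:
        log.warning("bacterivory flux is zero; fungivory:bacterivory undefined")
        return None
    return summary.absolute["fungivory"] / b


def bin_spectrum(
    masses_ug: np.ndarray, biomass: np.ndarray, flux: np.ndarray
) -> BodyMassSpectrum:
    """Sum biomass and intake flux into the five body-mass bins.

    Masses outside the binned range are clamped into the end bins with a
    warning.  Bins are half-open [lo, hi).
    """
    masses_ug = np.asarray(masses_ug, dtype=float)
    edges = np.array(MASS_BIN_EDGES_UG)
    if np.any(masses_ug < edges[0]) or np.any(masses_ug >= edges[-1]):
        log.warning("body masses outside [0.05 ug, 1.6 g]; clamped to end bins")
    idx = np.clip(np.searchsorted(edges, masses_ug, side="right") - 1, 0, 4)
    b_sum = np.zeros(5)
    f_sum = np.zeros(5)
    np.add.at(b_sum, idx, np.asarray(biomass, dtype=float))
    np.add.at(f_sum, idx, np.asarray(flux, dtype=float))
    return BodyMassSpectrum(
        bin_edges_ug=MASS_BIN_EDGES_UG, biomass=b_sum, flux=f_sum
    )


def spectrum_slope(spectrum: BodyMassSpectrum, quantity: str = "biomass") -> float:
    """OLS slope (per decade of body mass) of the log-binned spectrum.

    Fits log10(bin total) on log10(bin geometric midpoint mass) over bins
    1-4; the large-macrofauna bin is excluded.  Zero bins are dropped
    with a warning; fewer than 3 usable bins is an error.
    """
    values = getattr(spectrum, quantity)[:4]
    edges = np.array(spectrum.bin_edges_ug)
    midpoints = np.sqrt(edges[:-1] * edges[1:])[:4]
    usable = values > 0
    if usable.sum() < 3:
        raise ValueError(
            f"spectrum slope needs >= 3 nonzero bins among bins 1-4, "
            f"got {int(usable.sum())}"
        )
    if not usable.all():
        log.warning("zero bins dropped from spectrum slope fit")
    x = np.log10(midpoints[usable])
    y = np.log10(values[usable])
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def flux_to_fresh_biomass(flux_mW: float, config: Config | None = None) -> float:
    """Convert an energy flux (mW m^-2) to fresh biomass, g m^-2 y^-1.

    Uses the energy density of fresh biomass (7e6 J/kg by default) and a
    365-day year.
    """
    if flux_mW < 0:
        raise ValueError("flux must be >= 0")
    cfg = config or Config()
    joules_per_year = flux_mW * 1e-3 * cfg.seconds_per_year
    return joules_per_year / cfg.energy_density * 1e3


def npp_share(total_flux_mW: float, npp_g: float, config: Config | None = None) -> float:
    """Community consumption as a percentage of net primary production."""
    if npp_g <= 0:
        raise ValueError("NPP must be > 0")
    return flux_to_fresh_biomass(total_flux_mW, config) / npp_g * 100.0


def annual_mean_relative_biomass(monthly_percent: list[float]) -> float:
    """Mean of a monthly biomass series expressed as % of a reference month.

    Used to gauge the bias of snapshot sampling in seasonal forests: the
    annual mean relative to the sampling month.
    """
    series = np.asarray(monthly_percent, dtype=float)
    if not 1 <= series.size <= 12:
        raise ValueError("expected 1-12 monthly values")
    return float(series.mean())
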