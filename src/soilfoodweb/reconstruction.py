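"""Weighted diet-matrix reconstruction from traits, biomass and isotopes.

Each feeding link is scored by the product of independently scaled [0, 1]
plausibility factors:

* graded feeding preference of the consumer for the resource/prey class;
* body-mass niche: overlap of the prey's log10-mass distribution with the
  consumer's optimum-prey distribution (consumer mean shifted down by
  log10 of the optimum predator-prey mass ratio);
* spatial niche: overlap of microhabitat weight vectors;
* prey protection multiplier (1 = unprotected);
* biomass dependence: prey biomass relative to the most abundant feasible
  prey (encounter-rate argument);
* isotopic plausibility: Gaussian kernel on the distance between the
  consumer's signature and the prey's signature shifted by one trophic
  enrichment step.

Stable-isotope data additionally refine the preference budget itself:
algivory scales with low d15N, earthworm litter-vs-soil feeding scales
with d15N between the epigeic and endogeic endpoints, and omnivore
predation scales with d15N position between the web's extremes.  The
final matrix is column-stochastic: each consumer column sums to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .config import Config
from .model import Guild, InfeasibleWebError, SiteBundle, RESOURCE_IDS

log = logging.getLogger(__name__)


@dataclass
class DietMatrix:
    """Column-stochastic diet matrix over resource + guild nodes.

    Rows index all nodes (7 resources first, then guilds); columns index
    consumer guilds.  ``W[i, j]`` is the share of node *i* in consumer
    *j*'s diet.
    """

    node_ids: list[str]  # resources then guilds, row order
    consumer_ids: list[str]  # column order (== guild part of node_ids)
    W: np.ndarray

    def __post_init__(self) -> None:
        n_nodes, n_cons = self.W.shape
        if n_nodes != len(self.node_ids) or n_cons != len(self.consumer_ids):
            raise ValueError("matrix shape does not match node/consumer ids")
        colsums = self.W.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("diet columns must each sum to 1")
        if np.any(self.W < 0):
            raise ValueError("diet shares must be non-negative")

    @property
    def n_resources(self) -> int:
        return len(self.node_ids) - len(self.consumer_ids)

    def share(self, prey_id: str, consumer_id: str) -> float:
        return float(
            self.W[self.node_ids.index(prey_id), self.consumer_ids.index(consumer_id)]
        )


def ppmr_weight(
    mu_pred: float, mu_prey: float, sigma: float, ppmr_optimum: float
) -> float:
    """Body-mass niche weight in [0, 1].

    Overlap coefficient of two equal-variance normals on the log10-mass
    scale: the prey distribution N(mu_prey, sigma^2) against the
    consumer's optimum-prey distribution N(mu_pred - log10(R*), sigma^2).
    With d the distance between the means the overlap is 2*Phi(-d/(2*sigma)).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    d = abs(mu_prey - (mu_pred - np.log10(ppmr_optimum)))
    return float(2.0 * norm.cdf(-d / (2.0 * sigma)))


def habitat_overlap(h_pred: dict[str, float], h_prey: dict[str, float]) -> float:
    """Spatial-niche overlap: sum of stratum-wise minima of weight vectors."""
    keys = set(h_pred) | set(h_prey)
    return float(sum(min(h_pred.get(k, 0.0), h_prey.get(k, 0.0)) for k in keys))


def isotope_weight(
    pred: tuple[float | None, float | None],
    prey: tuple[float | None, float | None],
    config: Config,
) -> float:
    """Isotopic plausibility of a feeding link, in (0, 1].

    The prey signature is shifted by one trophic enrichment step
    (+tef_d15N, +tef_d13C); the weight is a Gaussian kernel
    exp(-D^2 / (2 b^2)) of the Euclidean distance D to the consumer
    signature.  Any missing value yields the neutral weight 1.
    """
    pred_n, pred_c = pred
    prey_n, prey_c = prey
    if None in (pred_n, pred_c, prey_n, prey_c):
        return 1.0
    dn = pred_n - (prey_n + config.tef_d15N)
    dc = pred_c - (prey_c + config.tef_d13C)
    dist_sq = dn * dn + dc * dc
    b = config.isotope_bandwidth
    return float(np.exp(-dist_sq / (2.0 * b * b)))


def refine_algivory(d15N: float, config: Config) -> float:
    """Algal diet fraction from d15N, linear between the configured endpoints.

    Full algivory (1.0) at the minimum observed d15N (-1.4 by default),
    none at the 2.0 per-mill threshold, clamped outside.
    """
    zero, full = config.algivory_d15N_zero, config.algivory_d15N_full
    return float(np.clip((zero - d15N) / (zero - full), 0.0, 1.0))


def refine_earthworm_soil(d15N: float, config: Config, *, is_earthworm: bool = True) -> float:
    """Soil fraction of an earthworm's detrital diet, from its d15N.

    0 at the epigeic (litter-feeding) endpoint, 1 at the endogeic
    (soil-feeding) endpoint, linear and clamped in between.
    """
    if not is_earthworm:
        raise ValueError("earthworm soil/litter refinement applies to earthworms only")
    lo, hi = config.earthworm_d15N_litter, config.earthworm_d15N_soil
    return float(np.clip((d15N - lo) / (hi - lo), 0.0, 1.0))


def refine_omnivore_predation(d15N: float, web_min: float, web_max: float) -> float:
    """Predation fraction for an omnivore from its d15N rank in the web."""
    if web_max <= web_min:
        log.warning("degenerate d15N range in web; omnivore predation set to 0.5")
        return 0.5
    return float(np.clip((d15N - web_min) / (web_max - web_min), 0.0, 1.0))


def apply_omnivory(guilds: list[Guild], omega: float) -> list[Guild]:
    """Rescale auxiliary feeding preferences to omega x the main preference.

    The main resource is each guild's maximum-preference diet class; every
    other *nonzero* preference is set to omega times the main preference.
    Zero preferences stay zero (no new feeding links are invented).
    """
    if not 0 <= omega <= 1:
        raise ValueError("omnivory parameter must lie in [0, 1]")
    out = []
    for g in guilds:
        g2 = g.copy()
        main_key = max(g.preferences, key=lambda k: g.preferences[k])
        main_val = g.preferences[main_key]
        for k, v in g.preferences.items():
            if k == main_key or v == 0:
                continue
            g2.preferences[k] = omega * main_val
        out.append(g2)
    return out


def refine_preferences(bundle: SiteBundle, config: Config) -> SiteBundle:
    """Apply the three isotope-based diet refinements to a bundle's guilds.

    Order: algivory (guilds with a nonzero algal preference), earthworm
    litter/soil split (within the detrital L+S mass), omnivore predation
    share (against the web-wide d15N range).  Guilds without isotope data
    are left untouched.
    """
    bundle = bundle.copy()
    d15n_values = [g.d15N for g in bundle.guilds if g.d15N is not None]
    web_min = min(d15n_values) if d15n_values else 0.0
    web_max = max(d15n_values) if d15n_values else 0.0

    for g in bundle.guilds:
        if g.d15N is None:
            continue
        prefs = g.preferences
        # Algivory: set the algal share, squeeze the rest proportionally.
        if prefs.get("A", 0.0) > 0:
            frac = refine_algivory(g.d15N, config)
            other = sum(v for k, v in prefs.items() if k != "A")
            if other > 0:
                scale = (1.0 - frac) / other
                for k in prefs:
                    prefs[k] = frac if k == "A" else prefs[k] * scale
            else:
                prefs["A"] = 1.0 if frac > 0 else prefs["A"]
        # Earthworms: split the detrital (litter + soil) preference mass.
        if g.is_earthworm:
            detrital = prefs.get("L", 0.0) + prefs.get("S", 0.0)
            if detrital > 0:
                soil_frac = refine_earthworm_soil(g.d15N, config)
                prefs["S"] = detrital * soil_frac
                prefs["L"] = detrital * (1.0 - soil_frac)
        # Omnivores: predation share from the web-wide d15N range.
        if g.is_omnivore and prefs.get("animal", 0.0) > 0:
            pred_frac = refine_omnivore_predation(g.d15N, web_min, web_max)
            basal = sum(v for k, v in prefs.items() if k != "animal")
            if basal > 0:
                scale = (1.0 - pred_frac) / basal
                for k in prefs:
                    prefs[k] = pred_frac if k == "animal" else prefs[k] * scale
            else:
                prefs["animal"] = pred_frac if pred_frac > 0 else prefs["animal"]
    return bundle


def build_diet_matrix(bundle: SiteBundle, config: Config) -> DietMatrix:
    """Assemble the column-stochastic diet matrix for one site.

    For consumer j the raw weight of an animal link i -> j is

        pref_j(animal) * ppmr * habitat * protection_i
                       * (B_i / max feasible prey B) * isotope,

    and of a resource link r -> j simply pref_j(r).  Within each column
    the basal and animal blocks are scaled to their refined preference
    budgets, then the column is normalised to sum one.
    """
    guilds = bundle.guilds
    node_ids = list(RESOURCE_IDS) + [g.guild_id for g in guilds]
    n_res = len(RESOURCE_IDS)
    n_guilds = len(guilds)
    W = np.zeros((n_res + n_guilds, n_guilds))

    for j, cons in enumerate(guilds):
        basal_prefs = np.array([cons.preferences.get(r, 0.0) for r in RESOURCE_IDS])
        animal_pref = cons.preferences.get("animal", 0.0)

        animal_raw = np.zeros(n_guilds)
        if animal_pref > 0:
            for i, prey in enumerate(guilds):
                if i == j:  # no self-predation
                    continue
                w = (
                    ppmr_weight(
                        cons.log10_mass, prey.log10_mass,
                        config.sigma_log_mass, config.ppmr_optimum,
                    )
                    * habitat_overlap(cons.habitat, prey.habitat)
                    * prey.protection
                )
                if w > 0:
                    w *= isotope_weight(
                        (cons.d15N, cons.d13C), (prey.d15N, prey.d13C), config
                    )
                animal_raw[i] = w
            # biomass dependence, scaled by the most abundant feasible prey
            feasible = animal_raw > 0
            if feasible.any():
                biomass = np.array([g.biomass for g in guilds])
                bmax = biomass[feasible].max()
                if bmax > 0:
                    animal_raw *= biomass / bmax
            animal_raw *= animal_pref

        basal_budget = basal_prefs.sum()
        animal_feasible = animal_raw.sum()
        if animal_pref > 0 and animal_feasible == 0:
            raise InfeasibleWebError(
                f"consumer {cons.guild_id!r} has animal preference but no feasible prey"
            )
        total_budget = basal_budget + animal_pref
        if total_budget == 0:
            raise InfeasibleWebError(
                f"consumer {cons.guild_id!r} has an all-zero diet column"
            )
        col = np.zeros(n_res + n_guilds)
        if basal_budget > 0:
            col[:n_res] = basal_prefs / total_budget
        if animal_pref > 0:
            col[n_res:] = animal_raw / animal_raw.sum() * (animal_pref / total_budget)
        W[:, j] = col / col.sum()

    return DietMatrix(node_ids=node_ids, consumer_ids=[g.guild_id for g in guilds], W=W)
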