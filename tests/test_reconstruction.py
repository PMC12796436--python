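"""Diet-matrix factors, isotope refinements and matrix assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from soilfoodweb import Config
from soilfoodweb.model import InfeasibleWebError, RESOURCE_IDS
from soilfoodweb.reconstruction import (
    apply_omnivory,
    build_diet_matrix,
    habitat_overlap,
    isotope_weight,
    ppmr_weight,
    refine_algivory,
    refine_earthworm_soil,
    refine_omnivore_predation,
    refine_preferences,
)
from soilfoodweb.synthetic import generate_fixture_web, generate_site

from conftest import make_bundle, make_guild


class TestPPMRWeight:
    def test_optimum_ratio_gives_full_weight(self):
        # prey exactly 100x lighter than the predator
        assert ppmr_weight(2.0, 0.0, 1.0, 100.0) == pytest.approx(1.0)

    def test_two_decade_offset(self):
        # d = 2, sigma = 1 -> 2*Phi(-1)
        assert ppmr_weight(2.0, 2.0, 1.0, 100.0) == pytest.approx(0.31731, abs=1e-5)

    def test_vanishes_at_extreme_distance(self):
        assert ppmr_weight(0.0, 40.0, 1.0, 100.0) < 1e-12

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(d=st.floats(0.0, 10.0), extra=st.floats(0.01, 5.0), sigma=st.floats(0.2, 3.0))
    def test_symmetric_and_strictly_decreasing(self, d, extra, sigma):
        base = 2.0  # optimum prey mean for a predator at mu = 2, R* = 100
        w_plus = ppmr_weight(base + 2.0, base + d, sigma, 100.0)
        w_minus = ppmr_weight(base + 2.0, base - d, sigma, 100.0)
        assert w_plus == pytest.approx(w_minus, rel=1e-9)
        assert ppmr_weight(base + 2.0, base + d + extra, sigma, 100.0) < w_plus


class TestHabitatOverlap:
    def test_identical_vectors(self):
        h = {"soil": 0.4, "litter": 0.6}
        assert habitat_overlap(h, h) == pytest.approx(1.0)

    def test_disjoint_strata(self):
        # ground predator cannot reach a strictly soil-dwelling prey
        assert habitat_overlap({"ground": 1.0}, {"soil": 1.0}) == 0.0

    def test_partial_overlap(self):
        assert habitat_overlap(
            {"soil": 0.5, "litter": 0.5}, {"soil": 1.0}
        ) == pytest.approx(0.5)


class TestIsotopeWeight:
    def test_exact_enrichment_step(self, config):
        assert isotope_weight((5.4, 0.4), (2.0, 0.0), config) == pytest.approx(1.0)

    def test_kernel_at_one_bandwidth(self, config):
        # distance D = b -> exp(-1/2)
        w = isotope_weight((2.0 + 3.4 + 3.4, 0.4), (2.0, 0.0), config)
        assert w == pytest.approx(np.exp(-0.5), abs=1e-9)

    def test_missing_value_is_neutral(self, config):
        assert isotope_weight((5.4, None), (2.0, 0.0), config) == 1.0
        assert isotope_weight((5.4, 0.4), (None, 0.0), config) == 1.0


class TestRefinements:
    @pytest.mark.parametrize(
        "d15n, expected", [(-1.4, 1.0), (2.0, 0.0), (0.3, 0.5), (-5.0, 1.0), (9.0, 0.0)]
    )
    def test_algivory_scaling(self, config, d15n, expected):
        assert refine_algivory(d15n, config) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "d15n, expected", [(1.2, 0.0), (5.5, 1.0), (3.35, 0.5), (0.0, 0.0), (8.0, 1.0)]
    )
    def test_earthworm_soil_scaling(self, config, d15n, expected):
        assert refine_earthworm_soil(d15n, config) == pytest.approx(expected)

    def test_earthworm_refinement_guards_flag(self, config):
        with pytest.raises(ValueError):
            refine_earthworm_soil(3.0, config, is_earthworm=False)

    @pytest.mark.parametrize(
        "d15n, lo, hi, expected",
        [(0.0, 0.0, 8.0, 0.0), (8.0, 0.0, 8.0, 1.0), (4.0, 0.0, 8.0, 0.5)],
    )
    def test_omnivore_predation_scaling(self, d15n, lo, hi, expected):
        assert refine_omnivore_predation(d15n, lo, hi) == pytest.approx(expected)

    def test_degenerate_web_range_falls_back_to_half(self):
        assert refine_omnivore_predation(3.0, 3.0, 3.0) == 0.5


class TestApplyOmnivory:
    def _guild(self):
        return make_guild("omni", prefs={"L": 0.8, "F": 0.4, "S": 0.2})

    def test_omega_zero_silences_auxiliaries(self):
        (g,) = apply_omnivory([self._guild()], 0.0)
        assert g.preferences == {"L": 0.8, "F": 0.0, "S": 0.0}

    def test_omega_one_equalises_with_main(self):
        (g,) = apply_omnivory([self._guild()], 1.0)
        assert g.preferences == {"L": 0.8, "F": 0.8, "S": 0.8}

    def test_intermediate_omega(self):
        (g,) = apply_omnivory([self._guild()], 0.5)
        assert g.preferences["F"] == pytest.approx(0.4)
        assert g.preferences["L"] == pytest.approx(0.8)

    def test_zero_preferences_stay_zero(self):
        g = make_guild("d", prefs={"L": 0.8, "F": 0.2})
        (out,) = apply_omnivory([g], 1.0)
        assert out.preferences.get("S", 0.0) == 0.0


def brute_force_diet_matrix(bundle, config):
    """Independent per-entry recomputation of the diet matrix.

    Plain nested loops over consumers and prey, evaluating each scaled
    plausibility factor from its closed form.
    """
    guilds = bundle.guilds
    ids = list(RESOURCE_IDS) + [g.guild_id for g in guilds]
    W = np.zeros((len(ids), len(guilds)))
    for j, c in enumerate(guilds):
        col = {}
        for r in RESOURCE_IDS:
            col[r] = c.preferences.get(r, 0.0)
        p_animal = c.preferences.get("animal", 0.0)
        raw = {}
        if p_animal > 0:
            for g in guilds:
                if g.guild_id == c.guild_id:
                    continue
                d = abs(
                    np.log10(g.mean_body_mass)
                    - (np.log10(c.mean_body_mass) - np.log10(config.ppmr_optimum))
                )
                w = 2 * norm.cdf(-d / (2 * config.sigma_log_mass))
                w *= sum(
                    min(c.habitat.get(h, 0), g.habitat.get(h, 0))
                    for h in ("soil", "litter", "ground", "aboveground")
                )
                w *= g.protection
                if w > 0 and None not in (c.d15N, c.d13C, g.d15N, g.d13C):
                    dn = c.d15N - (g.d15N + config.tef_d15N)
                    dc = c.d13C - (g.d13C + config.tef_d13C)
                    w *= np.exp(-(dn**2 + dc**2) / (2 * config.isotope_bandwidth**2))
                raw[g.guild_id] = w
            feasible = {k: v for k, v in raw.items() if v > 0}
            if feasible:
                bmax = max(
                    g.biomass for g in guilds if g.guild_id in feasible
                )
                for g in guilds:
                    if g.guild_id in raw:
                        raw[g.guild_id] *= g.biomass / bmax
        basal = sum(col.values())
        total = basal + p_animal
        raw_sum = sum(raw.values())
        column = np.zeros(len(ids))
        for i, rid in enumerate(RESOURCE_IDS):
            column[i] = col[rid] / total if total else 0.0
        if p_animal > 0 and raw_sum > 0:
            for i, g in enumerate(guilds):
                column[len(RESOURCE_IDS) + i] = (
                    raw.get(g.guild_id, 0.0) / raw_sum * (p_animal / total)
                )
        W[:, j] = column / column.sum()
    return ids, W


class TestBuildDietMatrix:
    def test_single_resource_consumer_unit_column(self, config):
        bundle = make_bundle([make_guild("d", prefs={"L": 1.0})])
        diet = build_diet_matrix(bundle, config)
        assert diet.share("L", "d") == 1.0

    def test_biomass_dependence_two_identical_prey(self, config):
        # prey identical except biomass 2:1 -> diet shares 2/3, 1/3
        prey_a = make_guild("prey_a", biomass=2.0, mass=1.0)
        prey_b = make_guild("prey_b", biomass=1.0, mass=1.0)
        pred = make_guild("pred", biomass=0.1, mass=100.0, prefs={"animal": 1.0})
        diet = build_diet_matrix(make_bundle([prey_a, prey_b, pred]), config)
        assert diet.share("prey_a", "pred") == pytest.approx(2 / 3)
        assert diet.share("prey_b", "pred") == pytest.approx(1 / 3)

    def test_star_shares_follow_biomass(self, config, star_web):
        diet = build_diet_matrix(star_web, config)
        shares = [diet.share(p, "predator") for p in ("prey_big", "prey_mid", "prey_small")]
        assert shares == pytest.approx([4 / 7, 2 / 7, 1 / 7])

    @pytest.mark.parametrize("kind", ["chain3", "loop", "star"])
    def test_matches_brute_force_on_fixtures(self, config, kind):
        bundle = generate_fixture_web(kind)
        diet = build_diet_matrix(bundle, config)
        ids, W = brute_force_diet_matrix(bundle, config)
        assert ids == diet.node_ids
        np.testing.assert_allclose(diet.W, W, atol=1e-12)

    def test_matches_brute_force_with_isotopes_and_protection(self, config):
        prey_a = make_guild(
            "prey_a", biomass=2.0, mass=1.0, protection=0.4,
            habitat={"litter": 0.7, "soil": 0.3},
        )
        prey_a.d15N, prey_a.d13C = 1.0, 0.2
        prey_b = make_guild(
            "prey_b", biomass=0.5, mass=0.2, habitat={"soil": 1.0},
        )
        prey_b.d15N, prey_b.d13C = 2.5, -0.3
        pred = make_guild(
            "pred", biomass=0.2, mass=50.0,
            prefs={"animal": 0.7, "L": 0.3},
            habitat={"litter": 0.6, "ground": 0.4},
        )
        pred.d15N, pred.d13C = 5.5, 0.6
        bundle = make_bundle([prey_a, prey_b, pred])
        diet = build_diet_matrix(bundle, config)
        ids, W = brute_force_diet_matrix(bundle, config)
        np.testing.assert_allclose(diet.W, W, atol=1e-12)

    def test_predator_without_feasible_prey_is_infeasible(self, config):
        soil_prey = make_guild("prey", habitat={"soil": 1.0})
        above_pred = make_guild(
            "pred", mass=100.0, prefs={"animal": 1.0}, habitat={"aboveground": 1.0}
        )
        with pytest.raises(InfeasibleWebError, match="pred"):
            build_diet_matrix(make_bundle([soil_prey, above_pred]), config)

    def test_factor_product_never_exceeds_single_factor(self, config):
        # monotone damping: every final animal raw weight <= preference
        bundle = generate_site("beech", 5)
        refined = refine_preferences(bundle, config)
        diet = build_diet_matrix(refined, config)
        for j, cons in enumerate(refined.guilds):
            animal_share = diet.W[diet.n_resources:, j].sum()
            total_pref = sum(cons.preferences.values())
            assert animal_share <= cons.preferences.get("animal", 0.0) / total_pref + 1e-12

    @pytest.mark.parametrize("omega", [0.0, 0.3, 0.7, 1.0])
    def test_columns_stochastic_across_omnivory_grid(self, omega):
        cfg = Config(omnivory_parameter=omega)
        bundle = generate_site("rainforest", 11)
        bundle.guilds = apply_omnivory(bundle.guilds, omega)
        refined = refine_preferences(bundle, cfg)
        diet = build_diet_matrix(refined, cfg)
        np.testing.assert_allclose(diet.W.sum(axis=0), 1.0, atol=1e-9)

    def test_no_self_predation(self, config, loop_web):
        diet = build_diet_matrix(loop_web, config)
        for j, cid in enumerate(diet.consumer_ids):
            assert diet.W[diet.node_ids.index(cid), j] == 0.0


class TestRefinePreferences:
    def test_algivory_applied_only_with_algal_capability(self, config):
        alg = make_guild("alg", prefs={"A": 0.4, "F": 0.6})
        alg.d15N, alg.d13C = -1.4, 0.0
        pred = make_guild("pred", mass=100.0, prefs={"animal": 1.0})
        pred.d15N, pred.d13C = -1.4, 0.0  # low but no algal preference
        out = refine_preferences(make_bundle([alg, pred]), config)
        g_alg = next(g for g in out.guilds if g.guild_id == "alg")
        g_pred = next(g for g in out.guilds if g.guild_id == "pred")
        assert g_alg.preferences["A"] == pytest.approx(1.0)
        assert g_alg.preferences["F"] == pytest.approx(0.0)
        assert g_pred.preferences.get("A", 0.0) == 0.0

    def test_earthworm_detrital_split_preserves_mass(self, config):
        ew = make_guild(
            "ew", mass=300.0, prefs={"L": 0.6, "S": 0.2}, is_earthworm=True
        )
        ew.d15N, ew.d13C = 3.35, 0.3  # midpoint -> 50:50 split
        out = refine_preferences(make_bundle([ew]), config)
        g = out.guilds[0]
        assert g.preferences["S"] == pytest.approx(0.4)
        assert g.preferences["L"] == pytest.approx(0.4)

    def test_omnivore_predation_share_from_web_range(self, config):
        low = make_guild("low", prefs={"L": 1.0})
        low.d15N, low.d13C = 0.0, 0.0
        high = make_guild("high", mass=100.0, prefs={"animal": 1.0})
        high.d15N, high.d13C = 8.0, 1.0
        omni = make_guild(
            "omni", mass=10.0, prefs={"L": 0.5, "animal": 0.5}, is_omnivore=True
        )
        omni.d15N, omni.d13C = 4.0, 0.5  # midpoint of [0, 8]
        out = refine_preferences(make_bundle([low, high, omni]), config)
        g = next(g for g in out.guilds if g.guild_id == "omni")
        assert g.preferences["animal"] == pytest.approx(0.5)
        assert g.preferences["L"] == pytest.approx(0.5)

    def test_guilds_without_isotopes_untouched(self, config):
        g = make_guild("plain", prefs={"L": 0.7, "F": 0.3})
        out = refine_preferences(make_bundle([g]), config)
        assert out.guilds[0].preferences == {"L": 0.7, "F": 0.3}
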