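"""Steady-state flux solver: analytic cases, oracle equivalence, balance."""

import numpy as np
import pytest

from soilfoodweb.fluxes import check_balance, solve_fluxes, trophic_levels
from soilfoodweb.model import RESOURCE_IDS, InfeasibleWebError
from soilfoodweb.reconstruction import DietMatrix, build_diet_matrix
from soilfoodweb.synthetic import generate_fixture_web

N_RES = len(RESOURCE_IDS)


def simple_diet(columns: dict[str, dict[str, float]]) -> DietMatrix:
    """DietMatrix from {consumer: {prey: share}} over resources + consumers."""
    consumers = list(columns)
    node_ids = list(RESOURCE_IDS) + consumers
    W = np.zeros((len(node_ids), len(consumers)))
    for j, c in enumerate(consumers):
        for prey, share in columns[c].items():
            W[node_ids.index(prey), j] = share
    return DietMatrix(node_ids=node_ids, consumer_ids=consumers, W=W)


def unit_e(diet: DietMatrix, **overrides) -> np.ndarray:
    e = np.ones(len(diet.node_ids))
    for k, v in overrides.items():
        e[diet.node_ids.index(k)] = v
    return e


def fixed_point_oracle(diet, X, e, damping=0.5, tol=1e-13, max_iter=100_000):
    """Damped fixed-point iteration from F = 0 (independent of the solver)."""
    n_res = diet.n_resources
    e_bar = np.asarray(e) @ diet.W
    C = diet.W[n_res:, :]
    F = np.zeros(len(X))
    for _ in range(max_iter):
        F_new = (1 - damping) * F + damping * (np.asarray(X) + C @ F) / e_bar
        if np.max(np.abs(F_new - F)) < tol * max(1.0, np.max(np.abs(F_new))):
            return F_new
        F = F_new
    raise RuntimeError("oracle did not converge")


def random_feasible_web(rng):
    """Random column-stochastic web (<= 8 nodes) with guaranteed feasibility.

    Each consumer takes >= 60%% of its diet from the two basal resources
    and efficiencies are >= 0.5, so the balance operator is a contraction.
    """
    n_cons = rng.integers(1, 7)
    consumers = [f"c{i}" for i in range(n_cons)]
    node_ids = ["L", "S"] + consumers
    W = np.zeros((2 + n_cons, n_cons))
    for j in range(n_cons):
        basal_share = rng.uniform(0.6, 1.0)
        W[:2, j] = basal_share * rng.dirichlet(np.ones(2))
        others = [i for i in range(n_cons) if i != j]
        if others and basal_share < 1.0:
            alloc = rng.dirichlet(np.ones(len(others)))
            for k, i in enumerate(others):
                W[2 + i, j] = (1 - basal_share) * alloc[k]
        else:
            W[:2, j] /= W[:2, j].sum()
    diet = DietMatrix(node_ids=node_ids, consumer_ids=consumers, W=W)
    X = rng.uniform(0.1, 2.0, size=n_cons)
    e = rng.uniform(0.5, 1.0, size=2 + n_cons)
    return diet, X, e


class TestSolveFluxes:
    def test_single_detritivore_analytic(self):
        # F = X / e exactly
        diet = simple_diet({"det": {"L": 1.0}})
        sol = solve_fluxes(diet, np.array([1.8]), unit_e(diet, L=0.18))
        assert sol.F[0] == pytest.approx(10.0, rel=1e-12)

    def test_two_level_chain_matches_oracle_value(self):
        diet = simple_diet({"det": {"L": 1.0}, "pred": {"det": 1.0}})
        e = unit_e(diet, L=0.18, det=0.9)
        sol = solve_fluxes(diet, np.array([2.0, 1.0]), e)
        assert sol.F[1] == pytest.approx(1.11111, abs=1e-5)
        assert sol.F[0] == pytest.approx(17.28395, abs=1e-5)

    def test_predator_without_prey_infeasible_at_reconstruction(self, config):
        from conftest import make_bundle, make_guild

        pred = make_guild("pred", mass=100.0, prefs={"animal": 1.0})
        with pytest.raises(InfeasibleWebError, match="pred"):
            build_diet_matrix(make_bundle([pred]), config)

    def test_oracle_equivalence_on_random_webs(self):
        rng = np.random.default_rng(1234)
        for _ in range(100):
            diet, X, e = random_feasible_web(rng)
            sol = solve_fluxes(diet, X, e)
            F_oracle = fixed_point_oracle(diet, X, e)
            np.testing.assert_allclose(sol.F, F_oracle, rtol=1e-8)
            assert sol.max_residual < 1e-9 * max(X.max(), 1.0)

    def test_loop_web_balances(self, config, loop_web):
        diet = build_diet_matrix(loop_web, config)
        e = np.ones(len(diet.node_ids))
        e[diet.node_ids.index("L")] = 0.18
        sol = solve_fluxes(diet, np.array([1.0, 1.0]), e)
        assert sol.max_residual < 1e-9
        report = check_balance(sol)
        assert report["__max_abs__"] < 1e-9

    def test_conservation_of_energy(self):
        # total assimilated intake - predation inflow == total metabolism
        rng = np.random.default_rng(7)
        diet, X, e = random_feasible_web(rng)
        sol = solve_fluxes(diet, X, e)
        e_bar = e @ diet.W
        predation = diet.W[diet.n_resources:, :] @ sol.F
        assert (e_bar * sol.F).sum() - predation.sum() == pytest.approx(
            X.sum(), rel=1e-12
        )

    def test_monotone_in_demand_and_linear_in_scale(self):
        rng = np.random.default_rng(99)
        diet, X, e = random_feasible_web(rng)
        base = solve_fluxes(diet, X, e)
        bumped = X.copy()
        bumped[0] += 0.5
        assert solve_fluxes(diet, bumped, e).total_flux >= base.total_flux
        scaled = solve_fluxes(diet, 3.0 * X, e)
        np.testing.assert_allclose(scaled.F, 3.0 * base.F, rtol=1e-12)
        np.testing.assert_allclose(scaled.L, 3.0 * base.L, rtol=1e-12)

    def test_perturbed_solution_reports_residual(self):
        diet = simple_diet({"det": {"L": 1.0}, "pred": {"det": 1.0}})
        e = unit_e(diet, L=0.18, det=0.9)
        sol = solve_fluxes(diet, np.array([2.0, 1.0]), e)
        sol.F[1] += 1.0
        sol.L = diet.W * sol.F[np.newaxis, :]
        report = check_balance(sol)
        assert abs(report["pred"]) > 0.1
        assert abs(report["det"]) > 0.1  # its prey column changes too


class TestTrophicLevels:
    def test_detritivore_and_predator(self):
        diet = simple_diet({"det": {"L": 1.0}, "pred": {"det": 1.0}})
        tl = trophic_levels(diet)
        assert tl[diet.node_ids.index("L")] == 1.0
        assert tl[diet.node_ids.index("det")] == pytest.approx(2.0)
        assert tl[diet.node_ids.index("pred")] == pytest.approx(3.0)

    def test_half_detrital_half_animal_diet(self):
        diet = simple_diet({"det": {"L": 1.0}, "omni": {"L": 0.5, "det": 0.5}})
        tl = trophic_levels(diet)
        assert tl[diet.node_ids.index("omni")] == pytest.approx(2.5)

    def test_mutual_predation_loop_is_finite(self, config, loop_web):
        diet = build_diet_matrix(loop_web, config)
        tl = trophic_levels(diet)
        # each omnivore: TL = 1 + 0.5*1 + 0.5*TL_other -> TL = 3
        consumers = tl[diet.n_resources:]
        np.testing.assert_allclose(consumers, [3.0, 3.0], rtol=1e-12)
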