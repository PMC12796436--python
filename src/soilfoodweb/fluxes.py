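"""Steady-state energy-flux balance on a reconstructed food web.

Under the steady-state assumption every consumer's assimilated intake
exactly covers its metabolic losses plus its losses to predation
("losses = gains").  With W the column-stochastic diet matrix, X the
metabolic demand vector (mW m^-2) and e the prey-specific assimilation
efficiencies, each consumer j satisfies

    (sum_i e_i W_ij) * F_j = X_j + sum_k W_jk F_k

which is the linear system (diag(e_bar) - C) F = X, where C is the
consumer-row submatrix of W and e_bar the diet-weighted mean efficiency.
Link fluxes follow as L_ij = W_ij * F_j.  Basal resources are unlimited
sources.  Trophic levels are the standard flow-weighted levels: 1 for
basal resources, 1 plus the diet-weighted mean prey level for consumers,
solved as a linear system so omnivory loops are handled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import InfeasibleWebError
from .reconstruction import DietMatrix


@dataclass
class FluxSolution:
    """Solved steady-state fluxes for one site's web."""

    node_ids: list[str]
    consumer_ids: list[str]
    F: np.ndarray  # per-consumer total intake, mW m^-2
    L: np.ndarray  # per-link flux, rows = all nodes, cols = consumers
    TL: np.ndarray  # per-node trophic level (resources first)
    X: np.ndarray  # per-consumer metabolic demand, mW m^-2
    efficiencies: np.ndarray  # per-node prey-specific efficiencies
    residuals: np.ndarray  # per-consumer balance error, mW m^-2

    @property
    def total_flux(self) -> float:
        """Total energy flux through the web: sum of all consumer intakes."""
        return float(self.F.sum())

    @property
    def max_residual(self) -> float:
        return float(np.abs(self.residuals).max()) if self.residuals.size else 0.0


def solve_fluxes(diet: DietMatrix, X: np.ndarray, e: np.ndarray) -> FluxSolution:
    """Solve the steady-state balance for consumer intakes and link fluxes.

    Parameters
    ----------
    diet
        Column-stochastic diet matrix (rows = nodes, columns = consumers).
    X
        Metabolic demands per consumer, mW m^-2, ordered as
        ``diet.consumer_ids``.
    e
        Assimilation efficiency per node (prey-specific), ordered as
        ``diet.node_ids``; all in (0, 1].

    Raises
    ------
    InfeasibleWebError
        If the balance system is singular ("structurally infeasible") or
        any solved intake is negative ("energetically infeasible").
    """
    W = diet.W
    n_res = diet.n_resources
    X = np.asarray(X, dtype=float)
    e = np.asarray(e, dtype=float)
    if X.shape != (len(diet.consumer_ids),):
        raise ValueError("X must have one entry per consumer")
    if e.shape != (len(diet.node_ids),):
        raise ValueError("e must have one entry per node")
    if np.any(X < 0):
        raise ValueError("metabolic demands must be non-negative")
    if np.any(e <= 0) or np.any(e > 1):
        raise ValueError("efficiencies must lie in (0, 1]")

    e_bar = e @ W  # diet-weighted mean efficiency per consumer
    C = W[n_res:, :]  # consumers as prey of consumers
    A = np.diag(e_bar) - C
    try:
        F = np.linalg.solve(A, X)
    except np.linalg.LinAlgError as exc:
        raise InfeasibleWebError(f"structurally infeasible web: {exc}") from exc
    if np.any(F < -1e-12 * max(X.max(), 1.0)):
        bad = [diet.consumer_ids[i] for i in np.where(F < 0)[0]]
        raise InfeasibleWebError(
            f"energetically infeasible web: negative intake for {bad}"
        )
    F = np.maximum(F, 0.0)
    L = W * F[np.newaxis, :]
    residuals = e_bar * F - X - C @ F
    TL = trophic_levels(diet)
    return FluxSolution(
        node_ids=list(diet.node_ids),
        consumer_ids=list(diet.consumer_ids),
        F=F, L=L, TL=TL, X=X, efficiencies=e, residuals=residuals,
    )


def trophic_levels(diet: DietMatrix) -> np.ndarray:
    """Flow-weighted trophic level per node; basal resources are level 1.

    TL_j = 1 + sum_i W_ij TL_i, solved as a linear system over consumers
    so loops (mutual predation, omnivory) are handled.
    """
    W = diet.W
    n_res = diet.n_resources
    n_cons = len(diet.consumer_ids)
    basal_contrib = W[:n_res, :].sum(axis=0)  # resources all have TL 1
    C = W[n_res:, :]
    A = np.eye(n_cons) - C.T
    try:
        tl_cons = np.linalg.solve(A, 1.0 + basal_contrib)
    except np.linalg.LinAlgError as exc:
        raise InfeasibleWebError(
            f"trophic levels undefined (pathological diet cycles): {exc}"
        ) from exc
    return np.concatenate([np.ones(n_res), tl_cons])


def check_balance(solution: FluxSolution) -> dict[str, float]:
    """Recompute per-consumer balance residuals from the solved fluxes.

    residual_j = assimilated inflow - predation outflow - X_j; all should
    vanish to solver precision on a valid solution.
    """
    n_res = len(solution.node_ids) - len(solution.consumer_ids)
    inflow = (solution.efficiencies[:, np.newaxis] * solution.L).sum(axis=0)
    outflow = solution.L[n_res:, :].sum(axis=1)
    residual = inflow - outflow - solution.X
    report = {
        cid: float(residual[j]) for j, cid in enumerate(solution.consumer_ids)
    }
    report["__max_abs__"] = float(np.abs(residual).max()) if residual.size else 0.0
    return report
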