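"""Optimisation front-ends: FBA, parsimonious FBA, FVA and MOMA.

FBA, pFBA and FVA delegate to COBRApy's LP machinery.  MOMA (minimisation of
metabolic adjustment) is solved here as a convex quadratic programme
``min ||v - v_ref||^2  s.t.  S v = 0,  lb <= v <= ub`` with SciPy's
``trust-constr`` solver, since the LP backend does not handle quadratic
objectives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
from cobra.flux_analysis import flux_variability_analysis as _cobra_fva
from cobra.flux_analysis import pfba as _cobra_pfba
from cobra.util.array import create_stoichiometric_matrix

logger = logging.getLogger(__name__)

#: requested solver tolerances, recorded in every result for provenance.
SOLVER_TOLERANCES = {"feasibility": 1e-9, "optimality": 1e-9}

#: |max - min| above which an FVA interval counts as non-degenerate.
VARIABILITY_THRESHOLD = 1e-6


class InfeasibleModelError(RuntimeError):
    """The optimisation problem has no feasible solution."""


@dataclass
class FluxDistribution:
    """A steady-state flux vector with its provenance."""

    fluxes: pd.Series
    objective_id: str
    objective_value: float
    status: str
    method: str
    variant: str = ""
    condition: str = ""
    tolerances: dict = field(default_factory=lambda: dict(SOLVER_TOLERANCES))
    notes: str = ""

    def __getitem__(self, reaction_id: str) -> float:
        return float(self.fluxes[reaction_id])

    @property
    def total_flux(self) -> float:
        return float(self.fluxes.abs().sum())

    def mass_balance_residual(self, network: cobra.Model) -> float:
        """Infinity norm of S v over the network's metabolites."""
        matrix = create_stoichiometric_matrix(network)
        order = [r.id for r in network.reactions]
        vec = self.fluxes.reindex(order).fillna(0.0).to_numpy()
        return float(np.abs(matrix @ vec).max())

    def to_frame(self) -> pd.DataFrame:
        return self.fluxes.rename("flux").to_frame()


@dataclass
class FluxRangeSet:
    """Per-reaction [min, max] flux intervals with a provenance tag."""

    ranges: pd.DataFrame  # columns: minimum, maximum
    provenance: str
    fraction_of_optimum: float | None = None

    def __post_init__(self) -> None:
        bad = self.ranges["minimum"] > self.ranges["maximum"] + 1e-9
        if bad.any():
            raise ValueError(f"min > max for {list(self.ranges.index[bad])}")

    @property
    def widths(self) -> pd.Series:
        return self.ranges["maximum"] - self.ranges["minimum"]

    def nondegenerate(self, threshold: float = VARIABILITY_THRESHOLD) -> pd.Index:
        return self.ranges.index[self.widths.abs() > threshold]

    def __len__(self) -> int:
        return len(self.ranges)


def _objective_reaction(network: cobra.Model) -> str:
    ids = [r.id for r in network.reactions if r.objective_coefficient]
    if len(ids) != 1:
        raise ValueError(f"expected a single objective reaction, found {ids}")
    return ids[0]


def optimize_fba(network: cobra.Model) -> FluxDistribution:
    """Maximise the network objective by flux balance analysis."""
    obj = _objective_reaction(network)
    solution = network.optimize()
    if solution.status != "optimal":
        raise InfeasibleModelError(
            f"FBA on {network.id or 'model'} returned status {solution.status!r}"
        )
    return FluxDistribution(
        fluxes=solution.fluxes.copy(), objective_id=obj,
        objective_value=float(solution.fluxes[obj]), status=solution.status,
        method="FBA", variant=network.name or network.id,
    )


def optimize_pfba(network: cobra.Model) -> FluxDistribution:
    """Parsimonious FBA: fix the objective optimum, minimise total |v|."""
    obj = _objective_reaction(network)
    try:
        solution = _cobra_pfba(network)
    except Exception as exc:
        raise InfeasibleModelError(f"pFBA failed on {network.id or 'model'}: {exc}") from exc
    return FluxDistribution(
        fluxes=solution.fluxes.copy(), objective_id=obj,
        objective_value=float(solution.fluxes[obj]), status=solution.status,
        method="pFBA", variant=network.name or network.id,
    )


def flux_variability(
    network: cobra.Model,
    fraction_of_optimum: float = 1.0,
    reactions: list[str] | None = None,
) -> FluxRangeSet:
    """Per-reaction flux minimisation/maximisation at a fixed objective fraction."""
    if not 0.0 < fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in (0, 1]")
    try:
        frame = _cobra_fva(
            network,
            reaction_list=reactions,
            fraction_of_optimum=fraction_of_optimum,
            processes=1,
        )
    except Exception as exc:
        raise InfeasibleModelError(f"FVA failed on {network.id or 'model'}: {exc}") from exc
    frame = frame.rename(columns={"minimum": "minimum", "maximum": "maximum"})
    return FluxRangeSet(frame[["minimum", "maximum"]], provenance="FVA",
                        fraction_of_optimum=fraction_of_optimum)


def moma_knockout(
    network: cobra.Model,
    reference: FluxDistribution,
    knockout_reaction: str,
    tolerance: float = 1e-9,
) -> FluxDistribution:
    """Knockout phenotype of minimal Euclidean distance to a reference state.

    The knockout reaction's bounds are closed and the quadratic programme
    ``min ||v - v_ref||^2`` over the steady-state polytope is solved.  A
    knockout that leaves no feasible flux space raises
    :class:`InfeasibleModelError`.
    """
    order = [r.id for r in network.reactions]
    missing = set(order) - set(reference.fluxes.index)
    if missing:
        raise ValueError(f"reference does not cover reactions: {sorted(missing)[:5]}")
    if not network.reactions.has_id(knockout_reaction):
        raise ValueError(f"unknown knockout reaction {knockout_reaction!r}")

    with network as model:
        model.reactions.get_by_id(knockout_reaction).bounds = (0.0, 0.0)
        if np.isnan(model.slim_optimize(error_value=float("nan"))):
            raise InfeasibleModelError(
                f"knockout of {knockout_reaction} leaves no feasible solution"
            )
        lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
        smat = create_stoichiometric_matrix(model)

    ref = reference.fluxes.reindex(order).to_numpy(dtype=float)
    feasible = (
        np.all(ref >= lb - 1e-9) and np.all(ref <= ub + 1e-9)
        and np.abs(smat @ ref).max() < 1e-9
    )
    if feasible:
        # the reference already satisfies the knockout model: distance zero
        fluxes = pd.Series(ref, index=order)
        obj = reference.objective_id
        return FluxDistribution(
            fluxes=fluxes, objective_id=obj,
            objective_value=float(fluxes.get(obj, np.nan)),
            status="optimal", method="MOMA",
            variant=network.name or network.id,
            notes=f"knockout={knockout_reaction}; distance=0",
        )
    # Every steady-state vector lies in the null space of S: v = N z with N
    # orthonormal.  Optimising over z keeps the equality constraints exact
    # and leaves only the bound inequalities, which conditions the QP well.
    nullsp = scipy.linalg.null_space(smat)

    def fun(z):
        d = nullsp @ z - ref
        return float(d @ d)

    def grad(z):
        return 2.0 * nullsp.T @ (nullsp @ z - ref)

    z0 = nullsp.T @ ref
    result = scipy.optimize.minimize(
        fun, z0, jac=grad, method="trust-constr",
        constraints=[scipy.optimize.LinearConstraint(nullsp, lb, ub)],
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 3000, "verbose": 0},
    )
    fluxes = pd.Series(nullsp @ result.x, index=order)
    distance = float(np.sqrt(result.fun))
    note = f"knockout={knockout_reaction}; distance={distance:.6g}"
    obj = reference.objective_id
    growthless = network.reactions.has_id(obj) and abs(fluxes[obj]) < 1e-9
    if growthless and abs(reference.objective_value) > 1e-9:
        note += "; objective collapsed to zero"
    return FluxDistribution(
        fluxes=fluxes, objective_id=obj,
        objective_value=float(fluxes.get(obj, np.nan)),
        status="optimal" if result.status in (1, 2) else f"trust-constr:{result.status}",
        method="MOMA", variant=network.name or network.id, notes=note,
    )


def loopless_mode(network: cobra.Model) -> FluxDistribution:
    """Delegated loop-free post-processing of an FBA optimum.

    Uses the backend's ``loopless_solution``.  Thermodynamically driven
    co-factor cycles may persist; when the backend routine is unavailable the
    function logs a warning and falls back to plain pFBA.
    """
    obj = _objective_reaction(network)
    try:
        from cobra.flux_analysis import loopless_solution
        solution = loopless_solution(network)
    except Exception as exc:
        warnings.warn(f"loopless backend unavailable ({exc}); falling back to pFBA")
        result = optimize_pfba(network)
        result.notes = "loopless unavailable; standard pFBA used"
        return result
    return FluxDistribution(
        fluxes=solution.fluxes.copy(), objective_id=obj,
        objective_value=float(solution.fluxes[obj]), status=solution.status,
        method="loopless", variant=network.name or network.id,
        notes="delegated loopless post-processing; cycles may persist",
    )
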