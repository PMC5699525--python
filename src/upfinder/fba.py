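"""Flux balance analysis: maximize c·v subject to S·v = 0 and lb <= v <= ub.

All solves go through the wrapped cobra model and its optlang/GLPK backend,
inside cobra's context manager so the caller's model is never mutated. Fixed
GLPK configuration keeps repeated runs bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import cobra
from cobra.exceptions import OptimizationError
from cobra.flux_analysis import pfba as _cobra_pfba

from .model_io import MetabolicModel

logger = logging.getLogger(__name__)

__all__ = [
    "FluxState",
    "solve_fba",
    "solve_patched",
    "solve_fixed",
    "lexicographic_opt",
    "pfba_solve",
]

#: Absolute tolerance (scaled by max(1, |optimum|)) used when the first
#: objective of a lexicographic solve is pinned before the second stage.
LEXICOGRAPHIC_FIX_TOL = 1e-6


@dataclass
class FluxState:
    """One LP solution: reaction fluxes, the objective, and solver status."""

    fluxes: Mapping[str, float]
    objective_id: str
    objective_value: Optional[float]
    status: str  # "optimal" | "infeasible" | "unbounded"

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def flux(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


def _status_of(solution) -> str:
    status = solution.status
    if status == "optimal":
        return "optimal"
    if status in ("unbounded", "infeasible"):
        return status
    # optlang may report "undefined" for either failure mode; GLPK tells
    # infeasible apart reliably, so fold the rest into "infeasible".
    logger.debug("solver returned status %r; reporting infeasible", status)
    return "infeasible"


def _optimize(cm: cobra.Model, objective_id: str, direction: str) -> FluxState:
    cm.objective = cm.reactions.get_by_id(objective_id)
    cm.objective_direction = direction
    try:
        solution = cm.optimize(raise_error=False)
    except OptimizationError:
        status = cm.solver.status
        return FluxState(
            {}, objective_id, None,
            status if status in ("infeasible", "unbounded") else "infeasible",
        )
    status = _status_of(solution)
    if status != "optimal":
        return FluxState({}, objective_id, None, status)
    return FluxState(
        fluxes=dict(solution.fluxes),
        objective_id=objective_id,
        objective_value=float(solution.fluxes[objective_id]),
        status="optimal",
    )


def solve_fba(
    model: MetabolicModel, objective_id: str, direction: str = "max"
) -> FluxState:
    """Plain FBA: optimize the flux of ``objective_id`` over the flux cone."""
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    model.reaction(objective_id)  # raises KeyError for unknown ids
    with model.cobra_model as cm:
        return _optimize(cm, objective_id, direction)


def solve_patched(
    model: MetabolicModel,
    objective_id: str,
    patches: Optional[Mapping[str, Tuple[Optional[float], Optional[float]]]] = None,
    direction: str = "max",
    use_pfba: bool = False,
) -> FluxState:
    """FBA with temporary ``(lb, ub)`` bound patches (``None`` keeps a side).

    Solves on the caller's model inside a reverting context, so consecutive
    calls share the solver instance: among degenerate alternate optima the
    simplex then stays close to the previously optimal basis, which keeps a
    sequence of related solves (wild type, then maximum yield) mutually
    consistent.
    """
    model.reaction(objective_id)
    with model.cobra_model as cm:
        for rid, (lb, ub) in (patches or {}).items():
            rxn = cm.reactions.get_by_id(rid)
            new_lb = rxn.lower_bound if lb is None else lb
            new_ub = rxn.upper_bound if ub is None else ub
            rxn.bounds = (new_lb, new_ub)
        if use_pfba:
            cm.objective = cm.reactions.get_by_id(objective_id)
            cm.objective_direction = direction
            try:
                solution = _cobra_pfba(cm, fraction_of_optimum=1.0)
            except Exception as exc:
                logger.debug("pfba failed: %s", exc)
                return FluxState({}, objective_id, None, "infeasible")
            return FluxState(
                dict(solution.fluxes), objective_id,
                float(solution.fluxes[objective_id]), "optimal",
            )
        return _optimize(cm, objective_id, direction)


def solve_fixed(
    model: MetabolicModel,
    fixed: Mapping[str, float],
    objective_id: str,
    direction: str = "max",
) -> FluxState:
    """FBA with selected reactions clamped (lb = ub = value).

    A fixed value outside the reaction's own bounds is a caller error and is
    rejected before any solve.
    """
    for rid, value in fixed.items():
        rec = model.reaction(rid)
        if not (rec.lower_bound - 1e-9 <= value <= rec.upper_bound + 1e-9):
            raise ValueError(
                f"fixed flux {value:g} for {rid} outside its bounds "
                f"[{rec.lower_bound:g}, {rec.upper_bound:g}]"
            )
    model.reaction(objective_id)
    with model.cobra_model as cm:
        for rid, value in fixed.items():
            rxn = cm.reactions.get_by_id(rid)
            rxn.bounds = (value, value)
        return _optimize(cm, objective_id, direction)


def lexicographic_opt(
    model: MetabolicModel,
    primary_id: str,
    secondary_id: str,
    fixed: Optional[Mapping[str, float]] = None,
    secondary_direction: str = "max",
    fix_tol: float = LEXICOGRAPHIC_FIX_TOL,
) -> Tuple[Optional[float], Optional[float], FluxState]:
    """Two-stage solve: maximize ``primary_id``, pin it, optimize ``secondary_id``.

    The primary optimum ``p`` is pinned via ``lb >= p - fix_tol * max(1, |p|)``
    rather than exactly, which keeps the second stage numerically feasible.
    Returns ``(primary_value, secondary_value, final_state)``; an infeasible
    first stage returns ``(None, None, state)``.
    """
    if primary_id == secondary_id:
        raise ValueError("primary and secondary objectives must differ")
    fixed = dict(fixed or {})
    for rid, value in fixed.items():
        rec = model.reaction(rid)
        if not (rec.lower_bound - 1e-9 <= value <= rec.upper_bound + 1e-9):
            raise ValueError(
                f"fixed flux {value:g} for {rid} outside its bounds "
                f"[{rec.lower_bound:g}, {rec.upper_bound:g}]"
            )
    model.reaction(primary_id)
    model.reaction(secondary_id)

    with model.cobra_model as cm:
        for rid, value in fixed.items():
            cm.reactions.get_by_id(rid).bounds = (value, value)
        first = _optimize(cm, primary_id, "max")
        if not first.ok:
            return None, None, first
        p = first.objective_value
        primary_rxn = cm.reactions.get_by_id(primary_id)
        slack = fix_tol * max(1.0, abs(p))
        primary_rxn.lower_bound = max(primary_rxn.lower_bound, p - slack)
        second = _optimize(cm, secondary_id, secondary_direction)
        if not second.ok:
            # numerically pathological pin; report the first-stage state
            logger.debug(
                "secondary stage %s after pinning %s=%g failed (%s)",
                secondary_id, primary_id, p, second.status,
            )
            return p, None, second
        return p, second.objective_value, second


def pfba_solve(model: MetabolicModel, objective_id: str) -> FluxState:
    """Parsimonious FBA: the objective-optimal flux vector of minimal total flux.

    Among all solutions attaining the FBA optimum of ``objective_id``, returns
    one minimizing the sum of absolute fluxes (the standard flux-split LP).
    """
    model.reaction(objective_id)
    with model.cobra_model as cm:
        cm.objective = cm.reactions.get_by_id(objective_id)
        cm.objective_direction = "max"
        try:
            solution = _cobra_pfba(cm, fraction_of_optimum=1.0)
        except Exception as exc:
            logger.debug("pfba failed: %s", exc)
            return FluxState({}, objective_id, None, "infeasible")
    return FluxState(
        fluxes=dict(solution.fluxes),
        objective_id=objective_id,
        objective_value=float(solution.fluxes[objective_id]),
        status="optimal",
    )
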