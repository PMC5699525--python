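"""Toy metabolic networks with analytically known optima, plus an LP oracle.

These generators provide small, fully understood fixtures for every stage of
the analysis without downloading genome-scale models:

``branch``
    Glucose uptake feeding node A, which splits into biomass precursor B and
    product P; biomass consumes both. Overproducing P requires up-regulating
    exactly the A->P branch reaction.
``linear``
    A single chain uptake -> m1 -> ... -> m_n -> biomass. Overproducing an
    interior metabolite needs only *down*-regulation downstream, so the
    up-regulation candidate set is empty.
``degradation``
    The branch network plus a forced degradation drain on P sized to the
    maximum producible amount, so no overexpression can accumulate product —
    the empty-result regime of targets with active degradation pathways.
``parallel``
    Two alternative routes (one short, one long) from A to B, for exercising
    parsimonious FBA's minimal-total-flux tie-break.

``oracle_solve`` is an exact rational-arithmetic LP solver by enumeration of
basic feasible points; it is deliberately independent of the solver stack
and is the reference the FBA layer is tested against.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Mapping, Optional, Tuple

import cobra

from .fba import FluxState
from .model_io import MetabolicModel

__all__ = [
    "ToySpec",
    "make_branch_model",
    "make_linear_model",
    "make_degradation_model",
    "make_parallel_model",
    "random_branch_variant",
    "oracle_solve",
]

BIG_BOUND = 1000.0


@dataclass(frozen=True)
class ToySpec:
    """Parameters of a generated toy network."""

    topology: str = "branch"  # branch | linear | degradation | parallel
    n_steps: int = 3
    uptake_limit: float = 10.0
    biomass_stoichiometry: Mapping[str, float] = field(
        default_factory=lambda: {"b_c": 0.8, "p_c": 0.2}
    )
    seed: int = 0


def _build(model_id: str, mets: Dict[str, str], reactions: List[tuple]) -> MetabolicModel:
    """Assemble a cobra model from (id, stoich, lb, ub, gpr, objective) rows."""
    cm = cobra.Model(model_id)
    cobra_mets = {}
    for mid, comp in mets.items():
        m = cobra.Metabolite(mid, compartment=comp)
        cobra_mets[mid] = m
    cm.add_metabolites(list(cobra_mets.values()))
    objective_id = None
    rxns = []
    for rid, stoich, lb, ub, gpr, obj in reactions:
        r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        rxns.append((r, stoich, gpr))
        if obj:
            objective_id = rid
    cm.add_reactions([r for r, _, _ in rxns])
    for r, stoich, gpr in rxns:
        r.add_metabolites({cobra_mets[k]: v for k, v in stoich.items()})
        if gpr:
            r.gene_reaction_rule = gpr
    if objective_id is not None:
        cm.objective = cm.reactions.get_by_id(objective_id)
    return MetabolicModel(cm)


def make_branch_model(spec: ToySpec = ToySpec()) -> MetabolicModel:
    """The canonical 6-reaction branch network (4 metabolites).

    EX_glc [-U, 1000] <-> glc_e; T1 glc_e -> a_c; RB a_c -> b_c;
    RP a_c -> p_c; BIO bB*b_c + bP*p_c -> (objective); DM_p p_c -> [0,1000].
    """
    bio_stoich = {k: -v for k, v in spec.biomass_stoichiometry.items() if v != 0}
    return _build(
        "BRANCH_1",
        {"glc_e": "e", "a_c": "c", "b_c": "c", "p_c": "c"},
        [
            ("EX_glc", {"glc_e": -1.0}, -spec.uptake_limit, BIG_BOUND, "", False),
            ("T1", {"glc_e": -1.0, "a_c": 1.0}, 0.0, BIG_BOUND, "gT1", False),
            ("RB", {"a_c": -1.0, "b_c": 1.0}, 0.0, BIG_BOUND, "gRB1 and gRB2", False),
            ("RP", {"a_c": -1.0, "p_c": 1.0}, 0.0, BIG_BOUND,
             "(gRP1 and gRP2) or gRP3", False),
            ("BIO", bio_stoich, 0.0, BIG_BOUND, "", True),
            ("DM_p", {"p_c": -1.0}, 0.0, BIG_BOUND, "", False),
        ],
    )


def make_linear_model(n_steps: int = 3, uptake_limit: float = 10.0) -> MetabolicModel:
    """LIN-n: uptake -> m1 -> ... -> m_n -> biomass; needs n_steps >= 2."""
    if n_steps < 2:
        raise ValueError("a linear chain needs at least 2 steps")
    mets = {"s_e": "e"}
    mets.update({f"m{i}": "c" for i in range(1, n_steps + 1)})
    reactions = [
        ("EX_s", {"s_e": -1.0}, -uptake_limit, BIG_BOUND, "", False),
        ("T1", {"s_e": -1.0, "m1": 1.0}, 0.0, BIG_BOUND, "gT1", False),
    ]
    for i in range(1, n_steps):
        reactions.append(
            (f"R{i}", {f"m{i}": -1.0, f"m{i + 1}": 1.0}, 0.0, BIG_BOUND, f"gR{i}", False)
        )
    reactions.append(("BIO", {f"m{n_steps}": -1.0}, 0.0, BIG_BOUND, "", True))
    return _build(f"LIN_{n_steps}", mets, reactions)


def make_degradation_model(spec: ToySpec = ToySpec()) -> MetabolicModel:
    """Branch network plus an always-on degradation drain on the product.

    The degradation reaction's lower bound equals the maximum producible P
    (the uptake limit), so every unit of forced extra production is consumed
    before it can reach the demand — the regime in which no overexpression
    target has a positive re-verified yield.
    """
    model = make_branch_model(spec)
    cm = model.cobra_model
    waste = cobra.Metabolite("waste_e", compartment="e")
    cm.add_metabolites([waste])
    deg = cobra.Reaction("DEG_p", lower_bound=spec.uptake_limit, upper_bound=BIG_BOUND)
    ex_w = cobra.Reaction("EX_waste", lower_bound=0.0, upper_bound=BIG_BOUND)
    cm.add_reactions([deg, ex_w])
    deg.add_metabolites({cm.metabolites.get_by_id("p_c"): -1.0, waste: 1.0})
    ex_w.add_metabolites({waste: -1.0})
    cm.id = "BRANCH_DEG"
    model._rebuild_records()
    return model


def make_parallel_model(uptake_limit: float = 10.0) -> MetabolicModel:
    """Two routes A -> B: direct (P1) and via intermediate C (P2a, P2b)."""
    return _build(
        "PARALLEL_1",
        {"s_e": "e", "a_c": "c", "b_c": "c", "c_c": "c"},
        [
            ("EX_s", {"s_e": -1.0}, -uptake_limit, BIG_BOUND, "", False),
            ("T1", {"s_e": -1.0, "a_c": 1.0}, 0.0, BIG_BOUND, "", False),
            ("P1", {"a_c": -1.0, "b_c": 1.0}, 0.0, BIG_BOUND, "gP1", False),
            ("P2a", {"a_c": -1.0, "c_c": 1.0}, 0.0, BIG_BOUND, "gP2", False),
            ("P2b", {"c_c": -1.0, "b_c": 1.0}, 0.0, BIG_BOUND, "gP2", False),
            ("BIO", {"b_c": -1.0}, 0.0, BIG_BOUND, "", True),
        ],
    )


def random_branch_variant(seed: int) -> MetabolicModel:
    """A branch network with randomized bounds and stoichiometric coefficients.

    Topology is fixed (so the oracle optimum stays a unique vertex); only the
    uptake limit, the biomass precursor split, and the conversion yields of
    the two branches vary.
    """
    rng = random.Random(seed)
    uptake = round(rng.uniform(4.0, 16.0), 3)
    bB = round(rng.uniform(0.5, 0.9), 3)
    bP = round(1.0 - bB, 3)
    yB = round(rng.uniform(0.5, 1.5), 3)  # a_c -> yB * b_c
    yP = round(rng.uniform(0.5, 1.5), 3)  # a_c -> yP * p_c
    return _build(
        f"BRANCH_R{seed}",
        {"glc_e": "e", "a_c": "c", "b_c": "c", "p_c": "c"},
        [
            ("EX_glc", {"glc_e": -1.0}, -uptake, BIG_BOUND, "", False),
            ("T1", {"glc_e": -1.0, "a_c": 1.0}, 0.0, BIG_BOUND, "gT1", False),
            ("RB", {"a_c": -1.0, "b_c": yB}, 0.0, BIG_BOUND, "gRB1 and gRB2", False),
            ("RP", {"a_c": -1.0, "p_c": yP}, 0.0, BIG_BOUND,
             "(gRP1 and gRP2) or gRP3", False),
            ("BIO", {"b_c": -bB, "p_c": -bP}, 0.0, BIG_BOUND, "", True),
            ("DM_p", {"p_c": -1.0}, 0.0, BIG_BOUND, "", False),
        ],
    )


# ---------------------------------------------------------------------------
# Exact LP oracle: enumeration of basic feasible points
# ---------------------------------------------------------------------------


def _row_reduce(rows: List[List[Fraction]]) -> List[List[Fraction]]:
    """Gauss-Jordan over the rationals; returns the nonzero reduced rows."""
    rows = [list(r) for r in rows]
    n_cols = len(rows[0]) if rows else 0
    pivot_row = 0
    for col in range(n_cols):
        sel = None
        for r in range(pivot_row, len(rows)):
            if rows[r][col] != 0:
                sel = r
                break
        if sel is None:
            continue
        rows[pivot_row], rows[sel] = rows[sel], rows[pivot_row]
        piv = rows[pivot_row][col]
        rows[pivot_row] = [x / piv for x in rows[pivot_row]]
        for r in range(len(rows)):
            if r != pivot_row and rows[r][col] != 0:
                f = rows[r][col]
                rows[r] = [a - f * b for a, b in zip(rows[r], rows[pivot_row])]
        pivot_row += 1
        if pivot_row == len(rows):
            break
    return [r for r in rows if any(x != 0 for x in r)]


def _solve_square(A: List[List[Fraction]], b: List[Fraction]) -> Optional[List[Fraction]]:
    """Solve A x = b exactly; None when A is singular."""
    n = len(A)
    M = [list(A[i]) + [b[i]] for i in range(n)]
    for col in range(n):
        sel = next((r for r in range(col, n) if M[r][col] != 0), None)
        if sel is None:
            return None
        M[col], M[sel] = M[sel], M[col]
        piv = M[col][col]
        M[col] = [x / piv for x in M[col]]
        for r in range(n):
            if r != col and M[r][col] != 0:
                f = M[r][col]
                M[r] = [a - f * b_ for a, b_ in zip(M[r], M[col])]
    return [M[i][n] for i in range(n)]


def oracle_solve(
    model: MetabolicModel,
    objective_id: str,
    direction: str = "max",
    _artificial_bound: Fraction = Fraction(10**6),
) -> FluxState:
    """Exact LP optimum of {S v = 0, lb <= v <= ub} by vertex enumeration.

    Every optimum of a bounded feasible LP is attained at a basic point where
    the non-basic variables sit on bounds; with at most 12 reactions all such
    points can be enumerated in exact rational arithmetic. Infinite bounds
    are replaced by a large artificial box; an optimum pressed against the
    artificial box on an originally unbounded side is reported ``unbounded``.
    Intended for test-sized models only.
    """
    n = len(model.reactions)
    if n > 12:
        raise ValueError("oracle_solve is restricted to models with <= 12 reactions")
    rids = [r.id for r in model.reactions]
    j_obj = rids.index(objective_id) if objective_id in rids else None
    if j_obj is None:
        raise KeyError(f"unknown reaction id {objective_id!r}")
    sign = Fraction(1) if direction == "max" else Fraction(-1)

    def frac_bound(x: float) -> Tuple[Fraction, bool]:
        if x == float("inf"):
            return _artificial_bound, True
        if x == float("-inf"):
            return -_artificial_bound, True
        return Fraction(x).limit_denominator(10**9), False

    lbs, ubs, artificial = [], [], []
    for rec in model.reactions:
        lo, alo = frac_bound(rec.lower_bound)
        hi, ahi = frac_bound(rec.upper_bound)
        lbs.append(lo)
        ubs.append(hi)
        artificial.append((alo, ahi))
    if any(lo > hi for lo, hi in zip(lbs, ubs)):
        return FluxState({}, objective_id, None, "infeasible")

    met_ids = [m.id for m in model.metabolites]
    S = [
        [Fraction(rec.stoichiometry.get(mid, 0.0)).limit_denominator(10**9)
         for rec in model.reactions]
        for mid in met_ids
    ]
    R = _row_reduce(S)
    rank = len(R)
    n_nonbasic = n - rank

    best_val: Optional[Fraction] = None
    best_v: Optional[List[Fraction]] = None
    for nonbasic in itertools.combinations(range(n), n_nonbasic):
        basic = [j for j in range(n) if j not in nonbasic]
        A = [[R[i][j] for j in basic] for i in range(rank)]
        for bounds_choice in itertools.product(*[(lbs[j], ubs[j]) for j in nonbasic]):
            rhs = [
                -sum(R[i][j] * val for j, val in zip(nonbasic, bounds_choice))
                for i in range(rank)
            ]
            x_basic = _solve_square(A, rhs) if rank else []
            if x_basic is None:
                break  # singular basis: no bound choice can fix it
            v = [Fraction(0)] * n
            for j, val in zip(nonbasic, bounds_choice):
                v[j] = val
            for j, val in zip(basic, x_basic):
                v[j] = val
            if any(not (lbs[j] <= v[j] <= ubs[j]) for j in range(n)):
                continue
            val = sign * v[j_obj]
            if best_val is None or val > best_val:
                best_val, best_v = val, v

    if best_val is None:
        return FluxState({}, objective_id, None, "infeasible")
    # optimum pinned to an artificial replacement of an infinite bound?
    for j in range(n):
        alo, ahi = artificial[j]
        if (alo and best_v[j] == lbs[j]) or (ahi and best_v[j] == ubs[j]):
            return FluxState({}, objective_id, None, "unbounded")
    fluxes = {rid: float(x) for rid, x in zip(rids, best_v)}
    return FluxState(fluxes, objective_id, float(sign * best_val), "optimal")
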