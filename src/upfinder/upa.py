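"""Up-regulated pathway analysis (UPA).

Given a genome-scale model and one target metabolite, UPA identifies the
reactions (and their genes) whose overexpression directly contributes to
overproducing the target:

1. Solve the wild-type model (biomass objective, product drain closed) and
   the maximum-yield model (product-demand objective); a reaction whose flux
   magnitude increases between the two states is an up-regulation candidate.
2. Re-verify each candidate by clamping it at its maximum-yield flux and
   asking how much product the growth-optimal network is then forced to
   make; candidates that do not force production (Yield ~ 0) are dropped.
3. Rank the survivors by their up-regulation Ratio = |flux_opt| / |flux_wt|
   (infinite for newly activated reactions) and group adjacent Ratio levels
   into metabolic modules.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Mapping, Optional, Tuple

import cobra

from .fba import FluxState, lexicographic_opt, solve_patched
from .model_io import MetabolicModel, normalize_metabolite_id

logger = logging.getLogger(__name__)

__all__ = [
    "UPAOptions",
    "CandidateRecord",
    "UPAResult",
    "ensure_demand",
    "select_biomass",
    "wild_type_fluxes",
    "optimum_fluxes",
    "detect_upregulated",
    "verify_yield",
    "rank_candidates",
    "genes_for",
    "group_modules",
    "run_upa",
]

INF = math.inf


class UPAError(RuntimeError):
    """Raised when a UPA run cannot proceed (infeasible wild type, etc.)."""


@dataclass(frozen=True)
class UPAOptions:
    """Tunable thresholds of the analysis.

    eps_flux
        Fluxes below this magnitude count as zero (so Ratio becomes INF).
    eps_yield
        Minimum re-verified Yield for a candidate to be kept.
    eps_rel
        Relative margin a finite Ratio must exceed 1 by.
    module_rel_tol
        Relative gap between consecutive Ratios that starts a new module.
    use_pfba
        Use parsimonious FBA for the wild-type and maximum-yield states
        instead of plain FBA.
    yield_mode
        ``"guaranteed"`` (default): Yield is the *minimum* product flux over
        all growth-optimal solutions with the candidate clamped — production
        the clamp forces. ``"potential"``: the maximum such flux.
    bound_overrides
        Reaction-id -> (lb, ub) overrides applied before any solve
        (``None`` keeps the model's own value for that side).
    """

    eps_flux: float = 1e-6
    eps_yield: float = 1e-6
    eps_rel: float = 1e-6
    module_rel_tol: float = 0.05
    use_pfba: bool = False
    yield_mode: str = "guaranteed"
    bound_overrides: Mapping[str, Tuple[Optional[float], Optional[float]]] = field(
        default_factory=dict
    )

    def __post_init__(self):
        for name in ("eps_flux", "eps_yield", "eps_rel", "module_rel_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.yield_mode not in ("guaranteed", "potential"):
            raise ValueError(f"unknown yield_mode {self.yield_mode!r}")

    def to_dict(self) -> dict:
        return {
            "eps_flux": self.eps_flux,
            "eps_yield": self.eps_yield,
            "eps_rel": self.eps_rel,
            "module_rel_tol": self.module_rel_tol,
            "use_pfba": self.use_pfba,
            "yield_mode": self.yield_mode,
            "bound_overrides": {k: list(v) for k, v in self.bound_overrides.items()},
        }


@dataclass
class CandidateRecord:
    """One overexpression candidate with its quantitative annotations."""

    reaction_id: str
    reaction_name: str
    genes: List[str]
    formula: str
    flux_wt: float
    flux_opt: float
    ratio: float  # math.inf for newly activated reactions
    yield_value: float
    rank: int = 0
    module: int = 0


@dataclass
class UPAResult:
    """Ranked candidate list plus run metadata."""

    model_id: str
    target_metabolite: str
    demand_id: str
    biomass_id: str
    theoretical_max_yield: float
    wild_type_growth: float
    candidates: List[CandidateRecord]
    options: UPAOptions

    @property
    def gene_set(self) -> frozenset:
        return frozenset(g for c in self.candidates for g in c.genes)

    @property
    def n_modules(self) -> int:
        return max((c.module for c in self.candidates), default=0)


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def ensure_demand(
    model: MetabolicModel, metabolite_id: str
) -> Tuple[MetabolicModel, str]:
    """Return a model with an irreversible drain for the target metabolite.

    An existing demand/sink that consumes exactly this metabolite with bounds
    ``[0, U]`` is reused; otherwise ``DM_<met>`` with bounds ``[0, 1000]`` is
    appended to a copy. Idempotent either way.
    """
    if metabolite_id not in {m.id for m in model.metabolites}:
        raise KeyError(f"unknown metabolite id {metabolite_id!r}")
    for rec in model.reactions:
        if (
            rec.boundary_kind in ("demand", "sink", "exchange")
            and set(rec.stoichiometry) == {metabolite_id}
            and rec.stoichiometry[metabolite_id] < 0
            and rec.lower_bound == 0
            and rec.upper_bound > 0
        ):
            return model, rec.id
    new = model.copy()
    demand_id = f"DM_{metabolite_id}"
    rxn = cobra.Reaction(demand_id, lower_bound=0.0, upper_bound=1000.0)
    new.cobra_model.add_reactions([rxn])
    rxn.add_metabolites({new.cobra_model.metabolites.get_by_id(metabolite_id): -1.0})
    new._rebuild_records()
    logger.debug("added demand reaction %s for %s", demand_id, metabolite_id)
    return new, demand_id


def select_biomass(model: MetabolicModel, biomass_id: Optional[str] = None) -> str:
    """The biomass reaction: explicit id, or the unique objective reaction."""
    if biomass_id is not None:
        model.reaction(biomass_id)
        return biomass_id
    objective_ids = model.objective_reactions()
    if len(objective_ids) == 1:
        return objective_ids[0]
    if not objective_ids:
        raise UPAError(
            "model declares no objective reaction; pass an explicit biomass id"
        )
    raise UPAError(
        f"model declares several objective reactions {objective_ids}; "
        "pass an explicit biomass id (e.g. autotrophic vs heterotrophic growth)"
    )


def wild_type_fluxes(
    model: MetabolicModel,
    biomass_id: str,
    options: UPAOptions = UPAOptions(),
    demand_id: Optional[str] = None,
) -> FluxState:
    """Growth-optimal flux state of the unengineered network (flux_wt).

    The target's demand reaction, if given, is closed (ub = 0) for this solve
    only, so the drain added for the analysis cannot perturb the wild-type
    solution. The solve happens on the caller's model (bounds reverted
    afterwards) so that the subsequent maximum-yield solve shares the solver
    basis — the flux comparison is then made between two mutually consistent
    states rather than two arbitrary vertices of degenerate optima.
    """
    patches = {demand_id: (None, 0.0)} if demand_id is not None else {}
    state = solve_patched(model, biomass_id, patches, use_pfba=options.use_pfba)
    if not state.ok:
        raise UPAError(f"wild-type model is {state.status}; check bounds/medium")
    return state


def optimum_fluxes(
    model: MetabolicModel, demand_id: str, options: UPAOptions = UPAOptions()
) -> FluxState:
    """Maximum-yield flux state (flux_opt); objective is the product drain."""
    state = solve_patched(model, demand_id, use_pfba=options.use_pfba)
    if state.status == "unbounded":
        raise UPAError(
            "maximum-yield LP is unbounded; review exchange bounds of the model"
        )
    if not state.ok:
        raise UPAError(f"maximum-yield model is {state.status}")
    return state


def detect_upregulated(
    flux_wt: FluxState,
    flux_opt: FluxState,
    model: MetabolicModel,
    options: UPAOptions = UPAOptions(),
) -> List[str]:
    """Internal reactions whose flux magnitude increases toward the optimum.

    A reaction qualifies when |flux_opt| > |flux_wt| + eps_flux and the two
    fluxes do not point in strictly opposite directions (a reversal is a
    rewiring, not an overexpression). Exchange, demand, sink and biomass
    reactions are never candidates.
    """
    eps = options.eps_flux
    out = []
    for rec in model.reactions:
        if rec.boundary_kind != "internal":
            continue
        vw = flux_wt.fluxes.get(rec.id, 0.0)
        vo = flux_opt.fluxes.get(rec.id, 0.0)
        if vw * vo < 0 and abs(vw) > eps and abs(vo) > eps:
            continue
        if abs(vo) > abs(vw) + eps:
            out.append(rec.id)
    return out


def verify_yield(
    model: MetabolicModel,
    candidate_id: str,
    v_opt: float,
    biomass_id: str,
    demand_id: str,
    options: UPAOptions = UPAOptions(),
) -> float:
    """Product yield when the candidate is clamped at its optimum flux.

    Lexicographic solve: maximize growth with the candidate fixed at
    ``v_opt`` (both bounds), then read the product-demand flux at the growth
    optimum. In ``guaranteed`` mode the demand flux is minimized in the
    second stage, so a positive value means the clamp *forces* production;
    in ``potential`` mode it is maximized. An infeasible clamp yields 0.
    """
    direction = "min" if options.yield_mode == "guaranteed" else "max"
    try:
        _, secondary, state = lexicographic_opt(
            model,
            primary_id=biomass_id,
            secondary_id=demand_id,
            fixed={candidate_id: v_opt},
            secondary_direction=direction,
        )
    except ValueError:
        raise
    if secondary is None or not state.ok:
        logger.debug("clamping %s at %g infeasible; yield 0", candidate_id, v_opt)
        return 0.0
    return max(0.0, secondary)


def genes_for(model: MetabolicModel, reaction_id: str) -> List[str]:
    """Sorted, duplicate-free gene ids of a reaction's GPR association."""
    return sorted(model.reaction(reaction_id).gpr.genes())


def _sort_key(c: CandidateRecord):
    return (-c.ratio, -c.yield_value, c.reaction_id)


def rank_candidates(
    records: List[CandidateRecord],
    options: UPAOptions = UPAOptions(),
    *,
    model_id: str = "",
    target_metabolite: str = "",
    demand_id: str = "",
    biomass_id: str = "",
    theoretical_max_yield: float = 0.0,
    wild_type_growth: float = 0.0,
) -> UPAResult:
    """Filter by Yield, sort by Ratio (INF first) and assign 1-based ranks."""
    kept = [
        c
        for c in records
        if c.yield_value > options.eps_yield
        and (math.isinf(c.ratio) or c.ratio > 1.0 + options.eps_rel)
    ]
    if not kept and records:
        logger.warning("all %d up-regulated reactions were filtered by the "
                       "Yield re-verification", len(records))
    kept.sort(key=_sort_key)
    for i, c in enumerate(kept, start=1):
        c.rank = i
    return UPAResult(
        model_id=model_id,
        target_metabolite=target_metabolite,
        demand_id=demand_id,
        biomass_id=biomass_id,
        theoretical_max_yield=theoretical_max_yield,
        wild_type_growth=wild_type_growth,
        candidates=kept,
        options=options,
    )


def group_modules(result: UPAResult, options: Optional[UPAOptions] = None) -> UPAResult:
    """Label candidates with metabolic-module numbers by Ratio level.

    Walking the ranked list, a new module starts whenever the relative gap
    between consecutive finite Ratios exceeds ``module_rel_tol``; all INF
    Ratios form the leading module. Labels are 1-based.
    """
    options = options or result.options
    module = 0
    prev_ratio: Optional[float] = None
    for cand in result.candidates:
        if math.isinf(cand.ratio):
            if module == 0:
                module = 1
            cand.module = 1
            continue
        if prev_ratio is None:
            module += 1
        elif (prev_ratio - cand.ratio) / prev_ratio > options.module_rel_tol:
            module += 1
        cand.module = module
        prev_ratio = cand.ratio
    return result


def run_upa(
    model: MetabolicModel,
    target_metabolite: str,
    options: UPAOptions = UPAOptions(),
    biomass_id: Optional[str] = None,
) -> UPAResult:
    """Full analysis for one target metabolite; returns the ranked result."""
    met_id = normalize_metabolite_id(target_metabolite, model)
    work = model
    if options.bound_overrides:
        work = model.copy()
        work.apply_bounds(options.bound_overrides)
    biomass = select_biomass(work, biomass_id)
    work, demand_id = ensure_demand(work, met_id)

    wt = wild_type_fluxes(work, biomass, options, demand_id=demand_id)
    opt = optimum_fluxes(work, demand_id, options)
    theoretical_max = opt.objective_value
    logger.info(
        "target %s: wild-type growth %.6g, theoretical max yield %.6g",
        met_id, wt.objective_value, theoretical_max,
    )

    def empty(reason: str) -> UPAResult:
        logger.warning("%s; returning empty result", reason)
        return group_modules(
            rank_candidates(
                [],
                options,
                model_id=work.id,
                target_metabolite=met_id,
                demand_id=demand_id,
                biomass_id=biomass,
                theoretical_max_yield=theoretical_max,
                wild_type_growth=wt.objective_value,
            )
        )

    if theoretical_max <= options.eps_yield:
        return empty(f"target {met_id} is not producible under the given bounds")

    candidate_ids = detect_upregulated(wt, opt, work, options)
    logger.info("%d up-regulated reactions detected", len(candidate_ids))
    if not candidate_ids:
        return empty("no up-regulated internal reaction found")

    records = []
    for rid in candidate_ids:
        rec = work.reaction(rid)
        vw = wt.fluxes.get(rid, 0.0)
        vo = opt.fluxes.get(rid, 0.0)
        y = verify_yield(work, rid, vo, biomass, demand_id, options)
        ratio = INF if abs(vw) <= options.eps_flux else abs(vo) / abs(vw)
        logger.debug("candidate %s: wt=%.6g opt=%.6g ratio=%.6g yield=%.6g",
                     rid, vw, vo, ratio, y)
        records.append(
            CandidateRecord(
                reaction_id=rid,
                reaction_name=rec.name,
                genes=genes_for(work, rid),
                formula=rec.formula,
                flux_wt=vw,
                flux_opt=vo,
                ratio=ratio,
                yield_value=y,
            )
        )

    result = rank_candidates(
        records,
        options,
        model_id=work.id,
        target_metabolite=met_id,
        demand_id=demand_id,
        biomass_id=biomass,
        theoretical_max_yield=theoretical_max,
        wild_type_growth=wt.objective_value,
    )
    return group_modules(result)
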