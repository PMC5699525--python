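"""Model input/output: SBML reading, GPR parsing, identifier handling, reports.

The in-memory representation wraps a :class:`cobra.Model` (cobrapy handles both
SBML Level 3 + fbc and Level 2 with ``GENE_ASSOCIATION`` notes) and exposes
plain-record views of metabolites and reactions so the analysis layer never
touches solver objects directly.
"""

from __future__ import annotations

import difflib
import json
import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import cobra
import cobra.io

logger = logging.getLogger(__name__)

__all__ = [
    "GPRSyntaxError",
    "MetaboliteLookupError",
    "ModelReadError",
    "GPRExpression",
    "MetaboliteRecord",
    "ReactionRecord",
    "MetabolicModel",
    "parse_gpr",
    "read_sbml",
    "write_sbml",
    "normalize_metabolite_id",
    "write_report",
]

#: Preferred LP backend; GLPK is deterministic for a fixed model/problem.
DEFAULT_SOLVER = "glpk"


class ModelReadError(Exception):
    """Raised when an SBML file cannot be turned into a usable model."""


class GPRSyntaxError(ValueError):
    """Raised for malformed gene-association strings; carries the offset."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class MetaboliteLookupError(KeyError):
    """Raised when a user-supplied metabolite id cannot be resolved."""


# ---------------------------------------------------------------------------
# Gene-protein-reaction expressions
# ---------------------------------------------------------------------------

# A GPR tree node is either a gene id (str) or a tuple (op, children) with
# op in {"and", "or"} and children a tuple of nodes.
GPRNode = Union[str, tuple]


@dataclass(frozen=True)
class GPRExpression:
    """Boolean AND/OR tree over gene identifiers; ``root=None`` means empty."""

    root: Optional[GPRNode] = None

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def genes(self) -> frozenset:
        """Flattened, duplicate-free set of gene ids in the expression."""
        out: set = set()
        stack = [] if self.root is None else [self.root]
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                out.add(node)
            else:
                stack.extend(node[1])
        return frozenset(out)

    def to_string(self) -> str:
        def fmt(node: GPRNode, parent_op: Optional[str] = None) -> str:
            if isinstance(node, str):
                return node
            op, children = node
            inner = f" {op} ".join(fmt(c, op) for c in children)
            if parent_op is not None and parent_op != op:
                return f"({inner})"
            return inner

        return "" if self.root is None else fmt(self.root)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str):
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(text: str) -> GPRExpression:
    """Parse a gene-association string into a :class:`GPRExpression`.

    Grammar (case-insensitive keywords)::

        expr  := term ("or" term)*
        term  := atom ("and" atom)*
        atom  := "(" expr ")" | GENE_ID

    An empty or whitespace-only string yields the empty expression.
    """
    tokens = _tokenize(text or "")
    if not tokens:
        return GPRExpression(None)
    idx = 0

    def peek():
        return tokens[idx] if idx < len(tokens) else (None, len(text))

    def parse_expr() -> GPRNode:
        nonlocal idx
        children = [parse_term()]
        while peek()[0] is not None and peek()[0].lower() == "or":
            idx += 1
            children.append(parse_term())
        return children[0] if len(children) == 1 else ("or", tuple(children))

    def parse_term() -> GPRNode:
        nonlocal idx
        children = [parse_atom()]
        while peek()[0] is not None and peek()[0].lower() == "and":
            idx += 1
            children.append(parse_atom())
        return children[0] if len(children) == 1 else ("and", tuple(children))

    def parse_atom() -> GPRNode:
        nonlocal idx
        tok, pos = peek()
        if tok is None:
            raise GPRSyntaxError("unexpected end of expression", pos)
        if tok == "(":
            idx += 1
            node = parse_expr()
            tok2, pos2 = peek()
            if tok2 != ")":
                raise GPRSyntaxError("unbalanced parenthesis: missing ')'", pos2)
            idx += 1
            return node
        if tok == ")":
            raise GPRSyntaxError("unbalanced parenthesis: unexpected ')'", pos)
        if tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"unexpected operator {tok!r}", pos)
        idx += 1
        return tok

    node = parse_expr()
    tok, pos = peek()
    if tok is not None:
        raise GPRSyntaxError(f"unexpected token {tok!r}", pos)
    return GPRExpression(node)


# ---------------------------------------------------------------------------
# Model records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetaboliteRecord:
    id: str
    name: str
    compartment: str


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction of the stoichiometric model.

    ``boundary_kind`` is one of ``internal``, ``exchange``, ``demand``,
    ``sink`` or ``biomass``; only ``internal`` reactions are candidates for
    overexpression.
    """

    id: str
    name: str
    stoichiometry: Mapping[str, float]
    lower_bound: float
    upper_bound: float
    gpr: GPRExpression
    objective_coefficient: float
    boundary_kind: str

    @property
    def formula(self) -> str:
        lhs, rhs = [], []
        for met, coef in sorted(self.stoichiometry.items()):
            part = met if abs(abs(coef) - 1.0) < 1e-12 else f"{abs(coef):g} {met}"
            (lhs if coef < 0 else rhs).append(part)
        arrow = "<=>" if self.lower_bound < 0 < self.upper_bound else "-->"
        return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


def _classify_boundary(reaction: cobra.Reaction, objective_ids: set) -> str:
    if reaction.id in objective_ids:
        return "biomass"
    coeffs = list(reaction.metabolites.values())
    single_sided = bool(coeffs) and (all(c < 0 for c in coeffs) or all(c > 0 for c in coeffs))
    if not coeffs:
        single_sided = True  # degenerate free reaction behaves like a boundary
    if not single_sided:
        return "internal"
    rid = reaction.id
    for prefix, kind in (("DM_", "demand"), ("SK_", "sink"), ("EX_", "exchange")):
        if rid.startswith(prefix) or rid.startswith("R_" + prefix):
            return kind
    return "exchange"


class MetabolicModel:
    """Stoichiometric model with bounds, objective and GPR associations.

    Thin wrapper around :class:`cobra.Model`; the wrapped model is reachable
    as :attr:`cobra_model` and is what the FBA layer actually solves.
    """

    def __init__(self, cobra_model: cobra.Model):
        cobra_model.solver = DEFAULT_SOLVER
        self.cobra_model = cobra_model
        self._rebuild_records()

    # -- construction ------------------------------------------------------
    def _rebuild_records(self) -> None:
        cm = self.cobra_model
        objective_ids = {
            r.id for r in cm.reactions if getattr(r, "objective_coefficient", 0.0)
        }
        self.metabolites = [
            MetaboliteRecord(m.id, m.name or "", m.compartment or "")
            for m in cm.metabolites
        ]
        self.reactions = []
        for r in cm.reactions:
            gpr = parse_gpr(r.gene_reaction_rule or "")
            self.reactions.append(
                ReactionRecord(
                    id=r.id,
                    name=r.name or "",
                    stoichiometry={m.id: c for m, c in r.metabolites.items()},
                    lower_bound=float(r.lower_bound),
                    upper_bound=float(r.upper_bound),
                    gpr=gpr,
                    objective_coefficient=float(getattr(r, "objective_coefficient", 0.0)),
                    boundary_kind=_classify_boundary(r, objective_ids),
                )
            )
        self.genes = sorted(g.id for g in cm.genes)
        self._reaction_index = {r.id: r for r in self.reactions}
        self._metabolite_index = {m.id: m for m in self.metabolites}

    # -- basic access ------------------------------------------------------
    @property
    def id(self) -> str:
        return self.cobra_model.id or ""

    def reaction(self, reaction_id: str) -> ReactionRecord:
        try:
            return self._reaction_index[reaction_id]
        except KeyError:
            raise KeyError(f"unknown reaction id {reaction_id!r}") from None

    def has_reaction(self, reaction_id: str) -> bool:
        return reaction_id in self._reaction_index

    def metabolite_ids(self) -> list:
        return [m.id for m in self.metabolites]

    def objective_reactions(self) -> list:
        return [r.id for r in self.reactions if r.objective_coefficient != 0.0]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(self.cobra_model.copy())

    def apply_bounds(self, overrides: Mapping[str, tuple]) -> None:
        """Set ``(lb, ub)`` bound overrides in place; ``None`` keeps a side."""
        for rid, (lb, ub) in overrides.items():
            rxn = self.cobra_model.reactions.get_by_id(rid)
            new_lb = rxn.lower_bound if lb is None else lb
            new_ub = rxn.upper_bound if ub is None else ub
            rxn.bounds = (new_lb, new_ub)  # atomic: avoids transient lb > ub
        self._rebuild_records()


def read_sbml(path) -> MetabolicModel:
    """Read an SBML file (L3+fbc preferred, L2 with notes tolerated)."""
    path = Path(path)
    if not path.exists():
        raise ModelReadError(f"no such file: {path}")
    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # libsbml reports line numbers in its message
        raise ModelReadError(f"could not parse SBML file {path}: {exc}") from exc
    if len(cm.reactions) == 0:
        raise ModelReadError(f"model in {path} contains no reactions")
    model = MetabolicModel(cm)
    if not model.objective_reactions():
        logger.warning(
            "model %s declares no objective reaction; biomass must be chosen "
            "explicitly", model.id or path.name,
        )
    return model


def write_sbml(model: MetabolicModel, path) -> None:
    """Serialize a (toy-sized) model to SBML L3 + fbc."""
    cobra.io.write_sbml_model(model.cobra_model, str(path))


# ---------------------------------------------------------------------------
# Metabolite identifier normalization
# ---------------------------------------------------------------------------

_BRACKET_RE = re.compile(r"^(?P<base>.+)\[(?P<comp>[^\[\]]+)\]$")


def _strip_prefix(met_id: str) -> str:
    return met_id[2:] if met_id.startswith("M_") else met_id


def _dialect_forms(text: str) -> list:
    """Equivalent spellings of a metabolite id across the two dialects."""
    text = text.strip()
    forms = [text]
    m = _BRACKET_RE.match(text)
    if m:
        forms.append(f"{m.group('base')}_{m.group('comp')}")
    stripped = _strip_prefix(text)
    if stripped != text:
        forms.append(stripped)
        m2 = _BRACKET_RE.match(stripped)
        if m2:
            forms.append(f"{m2.group('base')}_{m2.group('comp')}")
    return forms


def normalize_metabolite_id(text: str, model: MetabolicModel) -> str:
    """Resolve a user-supplied metabolite id against the model namespace.

    Accepts both the bracket dialect (``frdp[c]``) and the suffix dialect
    (``frdp_c``), with or without an ``M_`` prefix; returns the id exactly as
    the model spells it.
    """
    forms = set(_dialect_forms(text))
    matches = []
    for met in model.metabolites:
        keys = {met.id, _strip_prefix(met.id)}
        if keys & forms:
            matches.append(met.id)
    if len(matches) == 1:
        return matches[0]
    if len(matches) > 1:
        raise MetaboliteLookupError(
            f"metabolite id {text!r} is ambiguous: matches {sorted(matches)}"
        )
    pool = [_strip_prefix(m.id) for m in model.metabolites]
    close: list = []
    for form in sorted(forms, key=len):
        for hit in difflib.get_close_matches(form, pool, n=5, cutoff=0.4):
            if hit not in close:
                close.append(hit)
    close = close[:5]
    raise MetaboliteLookupError(
        f"no metabolite matching {text!r} in model {model.id!r}; "
        f"closest ids: {close}" if close else
        f"no metabolite matching {text!r} in model {model.id!r}"
    )


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "rank", "reaction_id", "reaction_name", "genes", "formula",
    "flux_wt", "flux_opt", "ratio", "yield", "module",
]


def _fmt_num(x: float) -> str:
    if math.isinf(x):
        return "Inf"
    return f"{x:.6g}"


def _candidate_row(cand) -> list:
    return [
        str(cand.rank),
        cand.reaction_id,
        cand.reaction_name,
        ";".join(cand.genes),
        cand.formula,
        _fmt_num(cand.flux_wt),
        _fmt_num(cand.flux_opt),
        _fmt_num(cand.ratio),
        _fmt_num(cand.yield_value),
        str(cand.module),
    ]


def report_lines(result) -> list:
    """The TSV report as a list of lines (header first)."""
    lines = ["\t".join(REPORT_COLUMNS)]
    for cand in result.candidates:
        lines.append("\t".join(_candidate_row(cand)))
    return lines


def result_to_dict(result) -> dict:
    """JSON-ready dictionary mirroring the TSV report plus run metadata."""
    return {
        "metadata": {
            "model_id": result.model_id,
            "target_metabolite": result.target_metabolite,
            "demand_id": result.demand_id,
            "biomass_id": result.biomass_id,
            "theoretical_max_yield": result.theoretical_max_yield,
            "wild_type_growth": result.wild_type_growth,
            "options": result.options.to_dict(),
        },
        "candidates": [
            {
                "rank": c.rank,
                "reaction_id": c.reaction_id,
                "reaction_name": c.reaction_name,
                "genes": list(c.genes),
                "formula": c.formula,
                "flux_wt": c.flux_wt,
                "flux_opt": c.flux_opt,
                "ratio": "Inf" if math.isinf(c.ratio) else c.ratio,
                "yield": c.yield_value,
                "module": c.module,
            }
            for c in result.candidates
        ],
    }


def write_report(result, path, format: str = "tsv") -> None:
    """Write a ranked candidate report as TSV or JSON.

    Infinite up-regulation ratios are serialized as the literal ``Inf`` in
    both formats. An empty candidate list produces a header-only TSV and a
    logged warning.
    """
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown report format {format!r}")
    path = Path(path)
    if not result.candidates:
        logger.warning(
            "no overexpression candidates for target %s; writing empty report",
            result.target_metabolite,
        )
    try:
        if format == "tsv":
            path.write_text("\n".join(report_lines(result)) + "\n")
        else:
            path.write_text(json.dumps(result_to_dict(result), indent=2) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
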