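# Methods

## Model representation and FBA

Models are read with cobrapy (SBML Level 3 + fbc preferred; Level 2 with
`GENE_ASSOCIATION` notes tolerated) and wrapped in a `MetabolicModel` that
exposes plain records — stoichiometry, bounds, objective coefficient, a GPR
expression tree — while all LPs are solved on the wrapped cobra model
through optlang/GLPK. GLPK's simplex is deterministic for a fixed problem,
which makes whole runs reproducible bit-for-bit.

Reactions are classified once at load time: the objective reaction is
`biomass`; single-sided reactions (metabolites on one side only) are
`demand`/`sink`/`exchange` by id prefix (`DM_`, `SK_`, else exchange);
everything else is `internal`. Only internal reactions can become
overexpression candidates — boundary fluxes and the biomass pseudo-reaction
are not enzymes.

Gene associations are parsed by a small recursive-descent parser
(`and`/`or`/parentheses, case-insensitive) into an AND/OR tree; reports use
the flattened, sorted gene set. Gene ids are reported verbatim from the
model (b-numbers for iJO1366); mapping to common names is a user-side alias
table (`upfinder.datasets.ISOPRENOID_GENE_ALIASES` ships the E. coli
isoprenoid aliases used in the examples).

Target metabolites are accepted in both circulating dialects
(`frdp[c]` ⇄ `frdp_c`, optional `M_` prefix) and resolved against the model
namespace; failed lookups list the closest ids.

## The analysis pipeline

For target metabolite *m*:

1. **Demand augmentation.** An irreversible drain for *m* is reused when the
   model has one (bounds `[0, U]`, consuming exactly *m*), otherwise
   `DM_<m>` with bounds `[0, 1000]` is appended. Maximizing production of an
   internal metabolite is only meaningful at steady state through such a
   drain.
2. **Wild type.** FBA with the biomass objective and the drain *closed*
   (ub = 0): the drain added for the analysis must not perturb the
   unengineered network. This gives flux_wt.
3. **Maximum yield.** FBA with the drain as objective (drain open) gives
   flux_opt and the theoretical maximum yield.
4. **Detection.** Candidate iff internal, |flux_opt| > |flux_wt| + ε_flux,
   and the fluxes do not have strictly opposite signs. A sign reversal is a
   rewiring of the network, not something overexpression achieves, so
   reversed reactions are excluded. Ratio = |flux_opt|/|flux_wt|, defined as
   infinite when |flux_wt| ≤ ε_flux (a newly activated pathway is maximally
   up-regulated; INF sorts above every finite Ratio).
5. **Re-verification.** The candidate is clamped (both bounds) at its
   flux_opt; growth is maximized; the growth optimum is pinned (lower bound
   at optimum − 10⁻⁶·max(1, |optimum|)); and the product-drain flux is then
   **minimized**. This minimum is the Yield: the production the clamp
   *guarantees* at the growth optimum. An infeasible clamp maps to Yield 0
   rather than aborting the run. Candidates need Yield > ε_yield to
   survive.
6. **Ranking and modules.** Sort by (Ratio desc, INF first; Yield desc;
   reaction id asc), assign 1-based ranks, then walk the list grouping
   candidates whose consecutive finite-Ratio relative gap stays within
   `module_rel_tol`; all INF-Ratio candidates form the leading module.

### Why the guaranteed (minimum) yield

The natural alternative — maximize the product flux after pinning growth —
is not a usable filter at genome scale: the pinning slack (10⁻⁶ of the
growth optimum) lets *every* candidate trade a sliver of biomass for ~10⁻⁶
units of product, so spurious candidates (pentose-phosphate, glycolysis,
phosphate transport…) leak past any threshold of the same order. Minimizing
instead asks whether the clamp *forces* production, which is exactly the
"directly contributes to overproduction" notion the filter is meant to
capture: on iJO1366/FPP the genuine pathway reactions have guaranteed
Yield equal to the full theoretical maximum (2.688) while every spurious
candidate drops to 0. The maximizing variant remains available
(`yield_mode="potential"`, CLI `--potential-yield`).

### Degenerate alternate optima

Plain FBA solutions are generally non-unique, and the candidate set can
depend on which optimal vertex the solver returns. Two mitigations are
built in:

- All solves of one run happen sequentially on a single working copy of the
  model (bounds patched inside reverting contexts). The simplex then
  warm-starts each solve from the previous basis, so the maximum-yield
  state stays as close as possible to the wild-type state it is compared
  against. Concretely, at the FPP optimum in iJO1366 the HMBPP branch point
  admits two equivalent routes (direct DMAPP synthesis vs IPP synthesis
  plus the *idi* isomerase); the wild type uses the isomerase route, and
  the warm-started max-yield solve keeps it, yielding the canonical
  9-gene target set. Each `run_upa` call starts from a fresh copy, so
  repeated runs are identical.
- Parsimonious FBA (`use_pfba=True`, CLI `--pfba`) replaces both flux
  states with minimal-total-flux optima. Note that pFBA resolves the HMBPP
  degeneracy the *other* way (the direct route is one reaction shorter), so
  on iJO1366/FPP it reports the DMPPS route and drops *idi*; neither answer
  is wrong — they are alternate optima — but the default reproduces the
  published target set.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `eps_flux` | 10⁻⁶ | flux magnitudes below this count as zero (Ratio → INF); also the minimum up-regulation margin. LP reporting precision. |
| `eps_yield` | 10⁻⁶ | minimum guaranteed Yield (mmol·gDW⁻¹·h⁻¹) to keep a candidate |
| `eps_rel` | 10⁻⁶ | relative margin a finite Ratio must exceed 1 by |
| `module_rel_tol` | 0.05 | relative Ratio gap that starts a new module; 5 % separates the pathway blocks cleanly in both worked examples |
| `use_pfba` | off | parsimonious flux states |
| `yield_mode` | guaranteed | see above |

All fluxes are in the model's units, conventionally mmol·gDW⁻¹·h⁻¹; Yields
are demand-reaction fluxes in the same units. Bound overrides (`--bound`)
express growth/uptake conditions. The biomass reaction is auto-selected
only when the model declares exactly one objective reaction; otherwise an
explicit `--biomass`/`--growth` id is required (e.g. autotrophic vs
heterotrophic growth in cyanobacterial models), since a silent choice
would change every number downstream.

## Synthetic fixtures and the exact oracle

The generators in `upfinder.synthetic` produce the regimes the method must
get right, not realistic biochemistry:

- **branch** — one overexpression target with known Ratio/Yield (the
  canonical instance: uptake 10, biomass = 0.8 B + 0.2 P, so flux_wt = 2,
  flux_opt = 10, Ratio = 5, Yield = 10);
- **linear** — overproduction achievable only by down-regulation: the
  correct answer is an empty report;
- **degradation** — a forced drain sized to the maximum producible product,
  reproducing the known failure mode for heavily degraded metabolites
  (again an empty report);
- **parallel** — tied alternate routes, exercising pFBA's tie-break;
- **random branch variants** — seeded perturbations of bounds and
  stoichiometric coefficients (never topology, so optima stay unique
  vertices).

Default magnitudes (uptake 10, cap 1000) mirror genome-scale conventions.
These toys have none of the degeneracy, compartmentalization, cofactor
coupling or GPR complexity of real reconstructions — passing them shows the
pipeline's logic is right, not that a genome-scale prediction is
biologically attainable; the iJO1366 acceptance check covers the
genome-scale behavior.

`oracle_solve` is the independent reference: it enumerates all basic points
of {S·v = 0, lb ≤ v ≤ ub} in exact rational arithmetic (`fractions`),
restricted to ≤ 12 reactions. Infinite bounds are boxed at ±10⁶ and an
optimum pressed against an artificial box face is reported unbounded. The
GLPK path must agree with it to 10⁻⁸ relative on every fixture.

## Problem sizes

The default test suite and the acceptance script use the 5–8-reaction
fixtures, 50 seeded variants, and one genome-scale run (iJO1366, 2583
reactions; ~35 LPs, a few seconds); the whole acceptance script completes
in well under a minute on one CPU.

## Known limitations

- Single-reaction evaluation only: the tool ranks individual overexpression
  targets and does not search for the best *combination* of targets.
- Metabolites with obligatory degradation pathways return empty reports
  (the forced flux is consumed before it can accumulate) — mirrored by the
  degradation fixture.
- Results inherit the quality of the reconstruction, and gene sets are
  GPR-flattened: complexes and isozymes appear as the full flattened set
  (e.g. iJO1366's ispG reaction carries its flavodoxin partners *fldA*/
  *fldB* in the GPR, so the FPP report lists 11 locus tags for the 9
  pathway genes).
- Plain-FBA flux *values* for individual reactions are alternate-optimum
  dependent; candidate/gene sets are stabilized as described above, but
  cross-solver comparisons should expect identical sets rather than
  identical flux vectors.
- The SBML writer is exercised only for toy-sized fixtures; writing edited
  genome-scale models is out of scope.
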