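# upfinder

Identify gene **overexpression** targets for overproducing a metabolite in a
genome-scale metabolic model.

Knockout-oriented strain-design tools answer "what should I delete?"; this
package answers the complementary question metabolic engineers ask first:
*which enzymes must carry more flux — and how much more — if the cell is to
make the maximum possible amount of my product, and which of them actually
force product formation when up-regulated on their own?* It is aimed at
metabolic engineers and systems biologists working with constraint-based
(SBML/fbc) reconstructions such as the BiGG models.

## Method

All computation is flux balance analysis (FBA): linear programs over the
steady-state flux cone {v : S·v = 0, lb ≤ v ≤ ub}. For a chosen target
metabolite a demand drain is added and three quantities are computed per
reaction:

- **flux_wt** — the reaction's flux in the wild-type solution
  (biomass objective, product drain closed);
- **flux_opt** — its flux in the maximum-yield solution
  (product-drain objective); the drain's optimum is the
  *theoretical maximum yield*;
- **Ratio = |flux_opt| / |flux_wt|** — the up-regulation level
  (infinite for reactions silent in the wild type).

The up-regulated pathway analysis (UPA) then proceeds in three steps:

1. **Detection.** Internal reactions with |flux_opt| > |flux_wt| (same
   direction) are up-regulation candidates. Exchange, demand, sink and
   biomass reactions are never candidates.
2. **Re-verification.** Each candidate is clamped at its flux_opt in the
   wild-type network, growth is maximized, and the **Yield** — the product
   flux the clamp *forces* at the growth optimum — is recorded. Candidates
   with Yield ≈ 0 (e.g. central-carbon reactions whose up-regulation does
   not by itself push flux into the product pathway, or targets drained by
   degradation reactions) are discarded.
3. **Ranking & modules.** Survivors are ranked by Ratio, high to low; runs
   of similar Ratio (relative gap ≤ 5 % by default) are grouped into
   metabolic modules, which in practice coincide with functional pathway
   blocks.

The output is a table of reactions with their genes (from the model's GPR
associations), formulas, flux_wt, flux_opt, Ratio, Yield and module label.

## Worked example

A 6-reaction branch network (shipped as a generator) routes glucose through
node A into biomass precursor B and product P, with biomass = 0.8 B + 0.2 P:

```sh
$ python -c "import upfinder; upfinder.write_sbml(upfinder.make_branch_model(), 'branch1.xml')"
$ upfinder run --model branch1.xml --target "p[c]" --method upa
rank  reaction_id  reaction_name  genes           formula      flux_wt  flux_opt  ratio  yield  module
1     RP                          gRP1;gRP2;gRP3  a_c --> p_c  2        10        5      10     1
```

Reading the row: in the wild type the P branch carries 2 flux units (just
the biomass requirement); reaching the theoretical maximum yield of 10
requires it to carry all 10 (Ratio 5), and clamping it there indeed forces
10 units of product — so overexpressing the `RP` genes is a complete,
single-step overproduction strategy. The upstream transporter `T1` is *not*
reported: it already runs at capacity in the wild type.

On the E. coli genome-scale reconstruction iJO1366 (bundled with cobrapy),
targeting farnesyl pyrophosphate (`frdp[c]`, the lycopene precursor):

```python
from upfinder import run_upa
from upfinder.datasets import load_ecoli_ijo1366

result = run_upa(load_ecoli_ijo1366(), "frdp[c]")
print(len(result.candidates), result.n_modules, f"{result.theoretical_max_yield:.3f}")
# 10 3 2.688
```

The 10 reactions cover the nine MEP/isoprenoid-pathway genes (*dxs, dxr,
ispD, ispE, ispF, ispG, ispH, idi, ispA*) and fall into 3 Ratio modules:
FPP synthesis (*idi, ispA*; Ratio ≈ 9844), the isoprenoid-unit module
(*dxr … ispH*; Ratio ≈ 3437) and the pathway entry (*dxs*; Ratio ≈ 2896) —
the higher the Ratio, the closer the enzyme sits to the product.

`--method fba` prints just the growth rate, with `--bound RXN=LB[,UB]`
overrides for uptake/growth conditions; see `upfinder run --help`.

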