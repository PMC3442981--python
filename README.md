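# budstrain

Constraint-based strain design for growth-coupled chemical production in
*Saccharomyces cerevisiae*, built around the question: **which reaction
knockouts force a yeast cell that maximizes growth to secrete
2,3-butanediol?**

The package is aimed at metabolic engineers and systems biologists who want
a self-contained, fully testable implementation of the classic in-silico
design loop:

1. **FBA** — flux balance analysis, the LP
   `max c·v  s.t.  S·v = 0, lb ≤ v ≤ ub`, with the environment given as
   uptake bounds (glucose −10, oxygen −2 mmol·gDCW⁻¹·h⁻¹) and an ATP
   maintenance demand (ATPM ≥ 1).
2. **FVA and production envelopes** — per-reaction flux ranges at a fixed
   fraction of maximal growth, and the min/max product flux as a function of
   growth. A collapsed envelope at maximal growth means production is
   growth-coupled.
3. **GPR logic** — boolean gene–protein–reaction rules (OR = isozymes,
   AND = complex subunits), with minimal gene deletion sets computed as
   minimal hitting sets over the rule DNF, including side-effect reports for
   shared genes.
4. **OptKnock** — the bilevel program
   `max_y (product flux)  s.t.  v solves the cell's own growth-FBA under
   knockouts y`, reformulated to a single-level MILP via LP strong duality
   with big-M linearization, integer-cut enumeration of alternative
   strategies, candidate screening (exchange/transport/essential/blocked
   reactions excluded) and an iterative ban-and-re-solve refinement loop.
   Every returned strategy is re-verified with independent LPs.

Because genome-scale models are large and externally distributed, the
package ships **PYRCORE**, a 23-reaction, 2-compartment, 7-gene fermentation
model of the yeast pyruvate branch point (ethanol via ADH, glycerol via GPD,
acetoin → 2,3-butanediol via BDH, respiration, maintenance). Its optima are
small rational numbers that were derived by hand, so every pipeline stage is
testable offline against exact values. A seeded random-model generator and a
brute-force design oracle provide ground truth for the MILP on arbitrary
instances.

## Worked example

Design a single-knockout butanediol producer on the fixture:

```sh
$ budstrain optknock --model pyrcore --target EX_bdo_e -k 1 --out-dir run
S1  ADH  ADH1+ADH3+ADH5  10.6364  0.909091  0.909091  0.0454762  0
```

Reading the row: deleting the lumped alcohol-dehydrogenase reaction (which
at the gene level requires knocking out all three isozymes *ADH1, ADH3,
ADH5*) gives a mutant whose maximal growth drops from 11 to 117/11 ≈ 10.636
(arbitrary fixture units) while the butanediol export at that growth is
pinned to 10/11 ≈ 0.909 mmol·gDCW⁻¹·h⁻¹ — max and min coincide, so
production is fully growth-coupled — for a mass yield of 0.045 g per g
glucose. The production envelope shows the coupling:

```sh
$ budstrain envelope --model pyrcore --knockout-reactions ADH \
      --target EX_bdo_e --points 2 --out-dir run
0.0000   0.0000  8.0000
10.6364  0.9091  0.9091
```

With a budget of two knockouts the optimizer additionally removes
respiration, which forces all NADH reoxidation through the glycerol and
butanediol branches: growth 7, butanediol 2 — the fixture's analogue of
fermentative (anaerobic) redox forcing.

The published genome-scale predictions can be re-run against a
user-supplied iMM904 SBML file (never bundled or downloaded):

```sh
budstrain reproduce-table1 --model iMM904.xml --out-dir run
```

which evaluates each fixed published deletion strategy under the standard
environment and tabulates computed vs printed growth rates and butanediol
yields with relative deviations.

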