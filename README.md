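# cbakit

Co-factor balance assessment for constraint-based models of engineered
*Escherichia coli*.

Metabolic engineers grafting a synthetic pathway onto a host inevitably
perturb the cell's energy (ATP) and redox (NADH/NADPH) economy: a route that
demands more electrons than glycolysis supplies, or that leaves an ATP
surplus, forces the network to compensate through respiration, overflow
products, futile cycles or growth — and every compensation costs carbon.
`cbakit` is a toolkit for quantifying that co-factor economy on the
*E. coli* core network, aimed at strain designers choosing between pathway
variants before going to the bench.

It provides, on top of COBRApy:

* a reduced 77-reaction / 63-metabolite wild-type core model and eight
  engineered butanol / butanol-precursor variants (CoA-dependent AtoB and
  NphT7 routes, thioesterase + carboxylic-acid-reductase exits, and a fatty
  acid synthesis route), built from declarative, balanced reaction
  definitions;
* FBA, parsimonious FBA, FVA, MOMA (a null-space quadratic programme — no
  commercial QP solver required) and delegated loopless post-processing;
* the **co-factor balance assessment**: per-reaction co-factor flux scores
  CFS = S_cofactor,j · v_j, partitioned into production / biomass / target /
  waste / maintenance categories that close to zero exactly at steady state;
* iterative **futile-cycle curation** ("whack-a-mole"): cap the maintenance
  reaction at the wild-type value, then repeatedly detect cycle members
  (PFK/FBP, PPC/PPCK, PYK/PPS, transhydrogenases, malic enzymes, the
  glutamine cycle, ATP-synthase reversal) whose flux escapes the wild-type
  envelope and cap them to it, until no cycle remains;
* ingestion of measured (¹³C-MFA-shaped) reaction × knockout-strain flux
  tables as hard bounds, with FVA/MOMA range comparison;
* the closed-form degree-of-reductance yield chain
  Y^E → Y^P → Y^P,G → Y^P,G,X → η (NADPH via PPP at 2 per C-mol, ATP
  deficits via respiration at 4.82 per C-mol, NADH surplus via a glycerol
  sink, ATP surplus via biomass);
* co-factor ratio landscapes: sweep artificial NADH (X) and ATP (Y)
  coefficients on the terminal aldehyde-reductase step over [−10, 10]² and
  record the yield/biomass surface.

See `docs/methods.md` for the model, the accounting rules and the numerical
choices.

## Worked example

Profile the NphT7+AdhE2 butanol producer (BuOH-1) under aerobic minimal
glucose:

```text
$ cbakit cba --variant BuOH-1 --condition aerobic
cofactor    category  net_flux  fraction
     ATP  production      30.0  1.000000
     ATP     biomass       0.0  0.000000
     ATP      target     -10.0 -0.333333
     ATP       waste     -10.0 -0.333333
     ATP maintenance     -10.0 -0.333333
 NAD(P)H  production      20.0  0.500000
 NAD(P)H     biomass       0.0  0.000000
 NAD(P)H      target     -40.0 -1.000000
 NAD(P)H       waste      20.0  0.500000
 NAD(P)H maintenance       0.0  0.000000
carbon yield: 66.67%
```

Reading: at the unconstrained optimum the model hits the 66.67%
stoichiometric carbon ceiling (1 butanol per glucose, the other two carbons
leaving as CO₂). Glycolysis makes 30 ATP; one third is consumed by the
introduced route (the malonyl-CoA step), one third by glycolytic kinases
(maintenance), and one third is *burned* by the maintenance reaction —
surplus energy the pathway cannot use. All 40 NADH consumed by the route
(target) come half from glycolysis and half from pyruvate dehydrogenase,
which is booked as waste because its NADH arrives with CO₂ release. No
biomass forms at all.

Curation caps that energy spilling against the wild-type reference and
forces the surplus into growth:

```text
$ cbakit curate --variant BuOH-1 --condition aerobic
BuOH-1 aerobic: converged after 10 caps; yield 64.59%, biomass 0.0386
```

The analytic chain ranks the same routes without any LP:

```text
$ cbakit dugar
pathway   Y_E  Y_Ea   Y_P  Y_PG  Y_PGX   eta
 BuOH-0 1.000 0.411 1.000 1.000  0.844 0.844
 BuOH-1 1.000 0.411 1.000 1.000  0.915 0.915
tpcBuOH 1.000 0.411 0.923 0.632  0.632 0.632
 BuOH-2 1.000 0.411 0.923 0.618  0.618 0.618
fasBuOH 1.000 0.411 0.857 0.447  0.447 0.447
   CROT 1.333 0.637 1.000 0.395  0.395 0.296
  BUTYR 1.200 0.587 1.000 0.500  0.500 0.417
  BUTAL 1.091 0.437 1.000 0.667  0.628 0.576
```

Both views agree: the NphT7+AdhE2 route (BuOH-1), which consumes one of the
two glycolytic ATP and diverts the least surplus to biomass, is the most
yield-efficient butanol design.

Other subcommands: `build` (write variant SBML), `pfba`, `fva`,
`mfa-constrain`, `moma-scan`, `landscape`, `fixture` — see `cbakit --help`.

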