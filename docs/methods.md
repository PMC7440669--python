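# Methods

## The problem

When a synthetic production pathway is grafted onto a host's central carbon
metabolism, it changes the cell's ATP and NAD(P)H economy. A route that burns
more redox than glycolysis supplies, or that leaves an ATP surplus with
nowhere to go, forces the host to compensate — through respiration, overflow
metabolism, futile cycling or biomass formation — and every compensation
costs carbon that would otherwise become product. `cbakit` quantifies this
co-factor economy for eight engineered butanol and butanol-precursor routes
in the *E. coli* core network, using flux balance analysis (FBA) and its
relatives, and compares the network-wide picture against a closed-form,
pathway-only yield framework.

## The wild-type network

All variants are built on a reduced *E. coli* core model with 77 reactions
and 63 metabolites: the standard textbook core network (bundled with
COBRApy) minus its nine alternative-substrate uptake systems (fructose,
glutamine, glutamate, 2-oxoglutarate, L-malate, fumarate, acetaldehyde,
pyruvate and D-lactate exchange/transport pairs). Glucose is then the only
carbon source; acetate, formate, ethanol and succinate remain as overflow
and fermentation products. The non-growth-associated maintenance reaction
ATPM (ATP → ADP + Pi) is given a lower bound of 7.6 mmol gDW⁻¹ hr⁻¹, the
classic chemostat estimate for glucose-grown *E. coli*; this bound matters,
because it is what forces ATP-tight pathway variants below the stoichiometric
yield ceiling.

Media are exchange-bound presets: minimal glucose at −10 mmol gDW⁻¹ hr⁻¹,
aerobic (oxygen uptake capped at 10) or anaerobic (zero oxygen).

## Engineered variants

Eight pathway definitions (`data/pathways.yml`) layer CoA- or ACP-dependent
butanol chemistry onto the wild type. All share the redox-dependent,
ATP-neutral C4 backbone (acetoacetyl-CoA → 3-hydroxybutyryl-CoA →
crotonyl-CoA → butyryl-CoA, consuming 2 NADH), and differ in their entry
step (AtoB condensation, or NphT7 via malonyl-CoA at a cost of 1 ATP), their
exit chemistry (AdhE2-type NADH reductions, or thioesterase + carboxylic
acid reductase consuming 1 ATP→AMP and 1 NADPH), and, for the FAS route, an
acyl-carrier-protein cycle with NADPH-specific ketoreduction. Every equation
is elementally and charge balanced in BiGG nomenclature; each variant's
declared net ATP and NAD(P)H route coefficients are validated against the
actual stoichiometry at build time, and the reaction/metabolite counts of
all nine models are fixed invariants. Products leave through irreversible
export and sink reactions; the sink is the production objective.

Two reconstruction details are worth flagging. The carboxylic-acid-reductase
step is written with lumped pyrophosphate hydrolysis in the thioesterase
routes and with explicit PPi plus inorganic pyrophosphatase in the FAS route;
and the FAS cycle initiates through acetyl-ACP. Both choices are constrained
by the fixed model dimensions rather than by published reaction lists, which
are not available in machine-readable form.

## Optimisation

* **FBA / pFBA** — delegated to COBRApy on the GLPK backend. pFBA is the
  canonical two-stage formulation: fix the objective at its optimum, then
  minimise total absolute flux. All reported "optimal phenotypes" are pFBA
  solutions.
* **FVA** — per-reaction minimisation/maximisation at a configurable
  fraction of the optimum (default 1.0). An interval counts as
  non-degenerate when |max − min| > 10⁻⁶ mmol gDW⁻¹ hr⁻¹.
* **MOMA** — the minimal-adjustment knockout phenotype
  min ‖v − v_ref‖² subject to S·v = 0 and bounds. GLPK cannot solve
  quadratic programmes, so the QP is solved directly: the steady-state
  constraint is eliminated by optimising over the null space of S
  (orthonormal basis from SVD), leaving a well-conditioned
  bound-constrained problem for SciPy's `trust-constr`. When the reference
  vector is already feasible for the knockout model it is returned exactly
  (distance zero).
* **Loopless mode** — a delegated wrapper over COBRApy's `loopless_solution`;
  it post-processes an optimum and does not remove thermodynamically driven
  co-factor cycles, which is precisely why the capping procedure below
  exists. If the backend routine is unavailable the wrapper warns and falls
  back to plain pFBA.

Requested solver tolerances (10⁻⁹ feasibility/optimality) are recorded in
every result object and written table.

## Co-factor balance assessment

For a co-factor with member metabolites M (ATP = {atp_c}; the NAD(P)H pool =
{nadh_c, nadph_c}, treated as interchangeable), the co-factor flux score of
reaction j is CFS_j = (Σ_{i∈M} S_ij) · v_j — positive for production,
negative for consumption. Scores are partitioned into five id-based
categories (`data/categories.yml`):

* **target** — the introduced pathway reactions;
* **biomass** — the growth reaction;
* **waste** — ATP hydrolysis/recycling (ATPM, ADK1), ATP formed on the
  acetate overflow branch (ACKr), dehydrogenases that make NAD(P)H while
  releasing CO₂ (GND, PDH, AKGDH, ICDHyr), and fermentative NAD(P)H
  re-oxidation (ethanol/lactate branches);
* **production** — any other reaction with a positive score;
* **maintenance** — any other reaction with a negative score.

Mixed-sign categories report their net. Because Σ_j CFS_j = Σ_i Σ_j S_ij v_j
= 0 for any mass-balanced flux vector, the five category nets close to zero
exactly; this closure is asserted in the test suite at 10⁻⁶. Waste-list ids
absent from a given model (e.g. genome-scale fermentation reaction names)
are skipped with a warning. "Total production" is the sum of positive scores
outside the target category; the share of NAD(P)H production contributed by
the oxidative PPP counts the positive scores of G6PDH2r and GND — their
simultaneous waste classification does not remove them from the production
total. A split accounting (NADH and NADPH as separate co-factors) is
available via the same configuration file.

Carbon yield is reported as 100 · (product carbons × sink flux) /
(6 × glucose uptake).

## Futile-cycle curation

Unconstrained production optima dissipate surplus ATP and redox through
high-flux cycle pairs: PFK/FBP, PPC/PPCK, PYK/PPS, the two
transhydrogenases, the malic enzymes (closing PEP→OAA→MAL→PYR loops), the
glutamine cycle (GLNS/GLUN, GLUSy), the SUCDi/FRD7 loop, and reversal of
ATP synthase. Curation formalises the manual detect-and-cap procedure:

1. cap ATPM at the wild-type maintenance value (7.6);
2. re-optimise by pFBA and compare each candidate cycle member
   (`data/curation.yml`) against the wild-type flux envelope
   [min(0, v_wt), max(0, v_wt)] widened by a threshold (default
   1.0 mmol gDW⁻¹ hr⁻¹ — the procedure targets *high-flux* cycles, and the
   published protocol names no number);
3. cap the designated member — the partner that does not itself consume the
   co-factor, or that the wild type leaves inactive — to the wild-type
   envelope (zero when inactive);
4. repeat until no candidate escapes, capping the largest violation first
   (ties broken lexicographically) so the otherwise manual order is
   deterministic.

The ATP-spilling optimum is typically degenerate: a single pFBA vertex can
hide an escape route that an alternate vertex uses. When the solution scan
comes up empty, the candidate set is therefore probed by FVA at the fixed
optimum, which is vertex-independent; the loop converges because every
iteration permanently tightens one bound from a finite set. The probe is
skipped when the curated model shares the reference's objective (curating
the wild type itself is a no-op). Caps that render the model infeasible are
rolled back and flagged in the audit log.

Curated production optima divert their remaining surplus into biomass: the
NphT7+AdhE2 butanol model, whose route consumes 1 of the 2 glycolytic ATP,
converges at 64.6% carbon yield with a small positive growth rate, against
66.67% (zero biomass) before curation.

## Measured-flux constraints

A reaction-by-strain flux table (the shape of a published ¹³C-MFA compendium
of single-knockout strains) is formatted by collapsing isozyme families to
their single model reaction (mean), averaging wild-type replicates,
restricting rows to model reactions and rescaling every strain to the model
glucose uptake of 10. Per-reaction extrema across strains become hard
bounds, or comparison ranges against FVA and MOMA scans. No isotopomer
fitting is performed — measured ranges are consumed, never estimated. The
bundled fixture generator emits a seeded synthetic table in this shape (15
retained reactions, pfkA/pfkB and maeA/maeB families, designated plastic
glycolytic and rigid anaplerotic rows) so that the whole path runs offline;
a real table in the same layout drops in unchanged.

## Analytic yield chain

For a CHO product the chain uses degree-of-reductance bookkeeping
(γ = 4C + H − 2O; glucose γ = 24, κ_biomass = 4.2):

* Y^E = γ_S/γ_P per C-mol (energetic maximum), Y^Ea its mass-basis form;
* route coefficients a (NADPH demand), b (product), c (ATP), d (NADH),
  e (CO₂) per C-mol glucose, including the glycolytic premise of 2 ATP and
  4 NADH per glucose catabolised to two acetyl-CoA; the NADH/NADPH split is
  read from the built network's stoichiometry;
* Y^P divides the stoichiometric yield by 1 + a/2 (+|c|/4.82 when the route
  is net ATP-negative): NADPH costs PPP carbon at 2 NADPH per C-mol, ATP
  deficits cost respiration at 4.82 ATP per C-mol;
* Y^P,G drains surplus NADH into a glycerol sink (⅓ ATP and ⅓ NADH per
  C-mol glycerol), respiring any ATP deficit the sink creates;
* Y^P,G,X diverts the remaining ATP surplus into biomass formation, whose
  excess electrons are drained by further glycerol; the coupled ATP/NADH
  balance is a 2×2 linear solve. This stage depends on an energetics
  parameter ε (C-mol glucose respired per C-mol biomass) and a biomass ATP
  coefficient α, neither of which has a canonical value; both must be given
  explicitly. η = Y^P,G,X / Y^E.

The chain is monotone by construction (each stage only adds non-negative
terms to the denominator). The two ATP-surplus butanol routes constrain the
(ε, α) pair only jointly; ε = 0.2, α = 3.49 reproduces their published
efficiency pair and is used as the CLI default, with the ranking of routes
insensitive to the choice.

## Co-factor ratio landscapes

The terminal butyraldehyde→butanol step is rewritten as
btal + X NADH + (X+Y) H⁺ + Y ADP + Y Pi → btoh + X NAD + Y ATP + Y H₂O,
so the native reaction is (X, Y) = (1, 0), positive coefficients mean the
step releases a co-factor surplus and negative ones an extra demand (the
balanced form adds the water of ATP formation). Sweeping X, Y over
[−10, 10] at step 1 (441 pFBA solutions per surface, a few tens of
milliseconds each) maps carbon yield and biomass rate against the route's
co-factor balance; infeasible cells are recorded as zero yield with a flag.
On the curated aerobic models the two AdhE2 routes hold a plateau at the
66.67% stoichiometric ceiling across growing ATP demand and redox surplus,
while the CAR-dependent routes fall off a cliff — their AMP recycling and
NADPH demand leave no slack.

## What the synthetic fixtures do and do not show

The toy co-factor network (9 reactions) has hand-set, mass-balanced fluxes
with analytically known category totals and a planted PFK/FBP cycle; it
pins the accounting and detection arithmetic exactly, but exercises none of
the degeneracy or proton economics of the real network. The synthetic flux
table reproduces the layout and plastic/rigid contrast of the measured
compendium, not its values; tests against it validate formatting, range
extraction and constraint application, not biological agreement.

## Numerical choices and limitations

* GLPK is the LP backend; requested tolerances 10⁻⁹, closure and mass
  balance asserted at 10⁻⁶.
* pFBA vertex selection among exactly degenerate optima is
  solver-dependent; category splits of a profile (though not objective
  values or yields) can differ between LP implementations. The curation
  probe exists for this reason.
* The wild-type growth optimum is degenerate under the 10 mmol gDW⁻¹ hr⁻¹
  oxygen cap; under non-limiting oxygen it is unique up to the
  SUCDi/FRD7 loop, and wild-type uniqueness statements refer to that state.
* The curation outcome depends on the capping order for some variants; the
  default (largest violation first) makes runs reproducible, and a custom
  candidate list or order can be supplied.
* Landscapes are defined for butanol-producing variants (they modify the
  terminal aldehyde reductase); precursor models have no such step.
* Only CHO products are supported by the yield chain; nitrogen-containing
  products would need an extended reductance convention.
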