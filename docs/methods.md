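# Methods

## Scope and model form

`rumenflux` analyzes communities of genome-scale (here: toy-scale)
metabolic models under the steady-state, constraint-based assumptions of
flux balance analysis: intracellular metabolite pools are at steady
state (`S v = 0`), fluxes are bounded (`LB ≤ v ≤ UB`, in mmol/gDCW/hr),
and cellular behaviour is summarized by a biomass reaction whose flux
(1/hr) is the growth rate. No kinetics, regulation, or thermodynamic
(ΔG-based) constraints are modelled; thermodynamic plausibility enters
only through the infeasible-cycle diagnostic below.

All LPs and MILPs are solved with HiGHS through
`scipy.optimize.linprog` / `scipy.optimize.milp`. Feasibility tolerance
is 1e-9 and the reporting tolerance 1e-6 (fluxes within 1e-6 of zero are
reported as zero); both are fixed rather than solver defaults so results
reproduce across versions. HiGHS's MIP integrality tolerance is pinned
to 1e-9 as well: with the default 1e-6 a big-M of 1000 lets a nominally
zero binary leak exactly epsilon-sized flux, which can fabricate
zero-cardinality gap fills.

FBA returns an arbitrary optimal vertex under degeneracy, so every
cross-stage decision in the package depends only on objective values and
FVA ranges, never on one particular flux vector.

## Curation diagnostics

*Balance.* Element and charge bookkeeping is exact (rationals over
integer-scaled coefficients). Exchange and biomass reactions are skipped
— they move mass across the system boundary by construction — and a
reaction touching a metabolite with unknown formula is reported as
"unbalanceable" rather than imbalanced. A reaction whose only imbalance
is n hydrogens and n charges gets a suggested n-proton fix; anything
else is left to the curator.

*Thermodynamically infeasible cycles (TICs).* With every exchange closed
no net conversion is possible, so any flux must circulate in a
stoichiometric null-space cycle with zero net driving force. FVA under
closed exchanges flags reactions reaching ≥ 0.999 × the artificial bound
(the margin absorbs solver round-off near the bound). Flagged reactions
are grouped by the support of an exact rational null-space basis of the
internal stoichiometric matrix (SymPy over `Fraction`-lifted
coefficients — floating-point null spaces produce spurious supports).
Repair is a report plus a helper, not an automatic edit: which member of
a loop group to disable is a curation judgment (cofactor specificity,
lumped reactions). The helper disables a deterministic representative
outright, because a *directed* cycle circulates even when every member
is irreversible — restricting directionality is not generally
sufficient. A user-supplied whitelist exempts loops deemed harmless
(e.g. nucleotide-degradation artifacts).

*Blocked reactions* are those with FVA range exactly (0, 0) under fully
open exchanges. *Duplicates* are reactions with identical (or
sign-flipped identical) stoichiometry; with a cofactor-pair config
(NAD↔NADP style) pairs differing only by the swap are flagged as
cofactor variants. For *augmentation* (gap fills, AMG sets) a stricter,
direction-aware notion is used: a reverse-written copy of an
irreversible reaction is *not* redundant — it contributes the missing
direction, and treating it as a duplicate would hide exactly the
loop-forming additions the infeasible-cycle gate must catch.

## GapFind / GapFill

A metabolite is *producible* when some flux distribution makes at least
ε = 0.001 of it. As in the original MILP formulation, the balance is
relaxed one-sidedly to `S v ≥ 0` so that missing *downstream* demand
never masks an existing production route; a terminal dead-end metabolite
is therefore a no-consumption problem, not a no-production one. The
consumption run mirrors this with an external supply term per
metabolite: a metabolite is consumable when some reaction can drain ≥ ε
of it given supply. Production indicators are coupled per
(metabolite, reaction) pair with `S_ij v_j ≥ ε w_ij − M_ij (1 − w_ij)`,
where `M_ij` scales with `|S_ij|` so large coefficients cannot truncate
the flux space, and the MILP maximizes the number of producible
metabolites in one distribution. ε and M = 1000 follow the method's
established convention. Gaps are additionally split into root vs
downstream by metabolite-graph reachability, purely as a reporting aid.

GapFill adds binary-gated database reactions (`LB_j y_j ≤ v_j ≤ UB_j
y_j`) plus a sink forcing ≥ ε of the target, and minimizes Σ y_j.
Equal-cardinality ties break lexicographically by reaction id via an
objective perturbation three orders below the unit cost; alternates are
enumerated with integer cuts until the cardinality exceeds the optimum
(plus a configurable slack) or a cap is reached. An empty result —
"no fill exists in this database" — is a normal outcome. Offering the
reverse of irreversible model reactions is a config toggle, off by
default (transport solutions are emphasized instead); auto-generated
transporter candidates are unnecessary when the universal database
already carries them, as the emitted bundles do.

## Community model (bilevel)

Members are namespaced and joined through a shared pool compartment. For
each shared metabolite a member touches, its exchange reaction is
replaced by two non-negative pseudo-fluxes (uptake from / export to the
pool) pinned by equality to outer-level allocations; exchanges for
non-shared metabolites become secretion-only, so the pool and diet are
the community's only nutrient source. Diet caps bound the community
uptake `e[i]` — never individual members, who compete freely for the
pooled supply.

The inner problem of each member (maximize own biomass given the
allocations) is replaced by its KKT system: stationarity, primal
feasibility, dual bounds (|λ|, μ ≤ 1000), and complementary slackness
linearized with binaries using the variable's own bound span as the
primal big-M. Because allocations enter only the primal right-hand
sides, the reformulation is an exact MILP. Every solution is re-checked
post hoc by fixing the allocations and re-solving each inner LP; a
mismatch (e.g. a true dual exceeding the big-M certificate) is surfaced
in the solution object rather than silently accepted. A "joint" mode
drops inner optimality (single LP) for cross-checking and speed; on the
cooperative toy fixtures both modes agree.

The community growth rate is reported as the unweighted sum of member
biomass fluxes; an abundance-weighted variant is available through the
objective weights since no canonical weighting exists. Community FVA
re-solves the MILP per query with the outer objective pinned at its
optimum. Raw allocation variables admit a futile pool circulation
(simultaneous uptake and export of the same metabolite), so the
transaction table queries *net* member exchange (`net[i,k]` = export −
uptake), which is invariant to it.

## Interaction discovery

For each member, problem metabolites are identified with exchanges open
— a gap reflects missing network capability, not the medium — and gap
fills are sought in each other member's internal+transport reactions and
in the universal database. Candidates pass through three gates in fixed,
cheapest-first order:

1. **transport plausibility** — a transport suggestion requires
   knowledgebase evidence for (receiver, metabolite) at level
   `ortholog` or better ("clear ortholog of an experimentally
   characterized transporter");
2. **taxonomic likelihood** — some source taxon of the suggestion must
   rank at or below the threshold in the receiver's relatedness list
   (table-driven; the curator's judgment is encoded as config, no live
   taxonomy service);
3. **infeasible-cycle check** — tentatively adding the reactions must
   not increase the set of unbounded reactions under closed exchanges.

A surviving transport suggestion becomes a *de novo* interaction when at
least one other member's standalone FVA shows positive maximum export of
the metabolite; that member is the donor (all qualifying donors are
recorded and flagged ambiguous when several qualify — the attribution
rule is this package's choice, since export capability is the only
model-level evidence available). Any other surviving suggestion is an
accepted network fix. Classification is a pure function of its inputs;
records are deduplicated on (metabolite, donor, receiver), keeping the
strongest status. Re-running discovery on AMG-augmented models and
diffing the de novo sets yields the retained/lost/gained report.

## AMG augmentation and flux shifts

AMG sets are an input contract: reaction lists per host member with
phage/e-value provenance (the e-value < 1e-34 filter is validated, not
computed — alignment searches against live databases are not
reproducible at this scale and are out of scope). Augmentation skips
direction-aware redundant reactions and logs them. Since adding
reactions only enlarges the flux polytope, every FVA interval must be
weakly wider afterwards — this superset-monotonicity property is
enforced by test. A reaction is *widened* when its post range contains
the pre range with one strictly wider endpoint, and *significant* when
the standard deviation of its minimum or maximum flux across the
objective simulations exceeds 1; an absolute-delta rule (> 1e-3) serves
single-context runs.

## Objectives and robustness

The five community objectives are: maximize total growth, maximize pool
release of SCFAs, maximize feed uptake, minimize methane + CO2 release,
and maximize small-sugar release. Membership of the SCFA/feed/gas/sugar
sets is a config file (emitted with each synthetic bundle); all five
runs share one diet so differences are attributable to the objective
alone. Robustness is the per-reaction population SD (1/n — the five
objectives are the whole population of conditions studied; the sample
variant is a switch) of the FVA minimum and maximum across runs,
aggregated per member, with a Gaussian-kernel density summary
(Silverman's bandwidth, floored so constant input yields a narrow point
mass rather than a singular estimate; the density integrates to 1 within
1e-3 on its grid).

## Synthetic communities and what they do (not) show

The generator emits linear-fermenter members — substrate in, conversion
chain to biomass, branch to an exportable byproduct — and plants, only
on branches whose removal does not zero biomass: production gaps,
cross-feeding pairs (receiver lacking a transporter that the universal
database and knowledgebase carry), three-reaction reversible cycles,
terminal dead-ends, and capacity bottlenecks with AMG bypass sets. The
named TOY3 fixture mirrors the rumen's guild structure — a
polysaccharide degrader fermenting glucose to acetate and hydrogen, a
secondary consumer, and a hydrogenotrophic methanogen consuming H2 + CO2
from the pool and releasing CH4 — with hand-solvable optima (degrader
standalone 20/hr on 10 glucose/hr; community growth 25/hr). Same seed,
same spec ⇒ byte-identical output.

These toys are deliberately *not* realistic in topology: no cofactor
coupling, no alternate pathways beyond those planted, pathway lengths of
a few steps, and yields chosen for hand-solvability. Passing tests
therefore demonstrate algorithmic correctness (planted features are
recovered exactly, optima match independent oracles) — not that any
particular biological community exhibits these exchanges. Problem sizes
throughout the suite (3-member communities, ≤ ~20 reactions per member,
50 seeded replicates, 100 random augmentations) were chosen so the full
pipeline, including the MILP-heavy stages, runs in minutes on one CPU.

## Known limitations

- The bilevel big-M (1000) is a certificate, not a proof: a pathological
  inner dual exceeding it would cut the true optimum. The post-hoc
  re-solve check reports this; it has not been observed on the emitted
  fixtures.
- GapFind's single-MILP form asks for simultaneous production of all
  metabolites; with ε = 0.001 against bounds of 1000 this is benign, but
  extremely tight capacity caps could in principle couple indicators.
- Loop grouping uses one rational null-space basis; overlapping cycles
  can share basis vectors, so groups are a cover of the loop set, not a
  canonical decomposition.
- The taxonomic gate is as good as its config; it encodes curator
  judgment, not live phylogeny.
- Dynamic community simulation, abundance-coupled constraint
  formulations, parsimonious FBA, and ΔG-based thermodynamics are out of
  scope.
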