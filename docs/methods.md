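# Methods

## Model and formulation

All analyses operate on a stoichiometric metabolic model: metabolites,
reactions with signed coefficients, and flux bounds in mmol/gCDW/h.
Steady-state flux vectors satisfy S·v = 0 with lb ≤ v ≤ ub; reversibility is
encoded purely by bounds (irreversible means lower bound 0), and exchange
reactions are boundary pseudo-reactions touching exactly one metabolite with
the uptake-negative sign convention. Uptake rates supplied through a medium
specification are stored as positive magnitudes and applied as equality
bounds (−rate, −rate); exchanges declared free open to ±1000; all other
exchanges are closed to uptake. The default bound magnitude of
1000 mmol/gCDW/h stands in for "unbounded".

Flux balance analysis maximizes a linear objective over this polytope.
Because the optimal face is usually not a single point, every *reported* flux
distribution is canonicalized by parsimonious FBA: a second LP minimizes
Σ|v| (split-variable formulation) subject to c·v ≥ f × optimum, f = 1 by
default. Flux variability analysis brackets per-reaction alternate optima at
a stated objective fraction and is used to flag non-unique fluxes.

The producer formulation first maximizes the biomass reaction (growth rate
μ*), then imposes biomass ≥ fraction × μ* as a lower bound (default fraction
0.2) and maximizes product export. The multiplier scan fixes the aconitase
flux by equality at k × its wild-type pFBA flux; the biomass floor for scan
cells is computed once from the *unconstrained* producer model ("20% of the
theoretical maximum") rather than re-derived per multiplier, so all cells
share one floor. The standalone producer call, by contrast, derives μ* from
whatever model it is given. Overexpression edits in strain scripts use the
same equality-at-k× convention (default k = 2), because a promoter swap in a
stoichiometric model is only expressible as a flux constraint; knockouts fix
bounds to (0, 0) while retaining the reaction so that delta maps and strain
tables keep a fixed reaction universe.

The double-robustness surface fixes growth and one TCA flux (AKGDH or
SUCOAS) by equality per grid cell and maximizes product flux; a bound mode
(constrained flux as an upper bound) is available as an option. Grids default
to 21 evenly spaced growth values in [0, μ*] and 21 flux values in
[0, FVA maximum]. Infeasible cells are masked and reported as such, never
interpolated.

Node splits report, for a chosen metabolite, each consuming reaction's share
of total stoichiometry-weighted consumption (direction-aware, so a reversible
reaction running backward counts on the correct side); shares sum to 1. A
second accounting, `export_share`, reports the fraction of node turnover that
leaves as exported product — the two views answer different questions about a
branch point and are both provided.

## Solvers and numerics

Two LP backends are wired in: scipy's HiGHS (default) and GLPK through
swiglpk. Both receive the identical matrix formulation and the test suite
requires their objective values to agree within 1e-6 on the fixture suite.
Solver feasibility tolerance is 1e-9; the reporting/assertion tolerance is
1e-6 (both configurable at the call sites that expose them). Infeasible and
unbounded problems are reported through a status field rather than raised,
so scans and surfaces can record gaps. Delta-map direction classification
uses the 1e-6 tolerance: `reversed` requires both fluxes nonzero with
opposite signs beyond tolerance; otherwise signed changes beyond tolerance
are `up`/`down`. Ties in the scan's best multiplier break toward the smallest
multiplier. TSV outputs round floats to six significant digits so repeated
runs are byte-identical; JSON keeps full precision and embeds a SHA-256 hash
of the run configuration.

An independent brute-force oracle solves small instances by enumerating
basic solutions: with r = rank(S), every subset of (n − r) reactions is fixed
at a lower or upper bound and the remaining square system is solved; the
best feasible candidate is the LP optimum because a bounded nonempty
polyhedron attains its optimum at a vertex. The oracle requires finite
bounds, defaults to a 12-active-reaction cap (the cost scales with
C(n, n−r)·2^(n−r)), and shares no code with the LP path.

## The synthetic core model

The packaged model (`cglutamicum_core`, 36 metabolites, 39 reactions)
emulates glucose-grown *C. glutamicum* central metabolism: PTS uptake
(glucose + PEP → G6P + pyruvate), EMP at three-stage resolution (so the
EMP/PPP split remains visible in heatmaps), a lumped oxidative PPP
(G6P → Ru5P + CO2 + 2 NADPH) with the classic non-oxidative return
(3 Ru5P → 2 F6P + G3P), pyruvate dehydrogenase, the full TCA cycle
(CS, ACN, ICD with NADPH, AKGDH, SUCOAS, SDH, FUM, MDH), the glyoxylate
shunt (aceA/aceB), PEP carboxylase anaplerosis, NADPH-dependent glutamate
dehydrogenase, reversible GAD, GABA export plus a separate uptake
transporter (gadP analog) so transport rewiring is expressible as
independent edits, the GABA shunt (gadT: GABA + α-KG → SSA + glutamate;
gadD: SSA → succinate + NADH), a lactate overflow valve, a lumped oxidative
phosphorylation honoring a configurable P/O ratio (default 2), ATP
maintenance (default 2 mmol/gCDW/h), and a biomass reaction. Every species
carries an elemental formula (reduced nicotinamide carriers absorb the
proton, i.e. NADH ≡ NAD + H2) and every non-exchange reaction except biomass
is elementally balanced; the balance checker skips reactions touching the
formula-free biomass pseudo-metabolite and says so.

Biomass drains G6P 2.4, pyruvate 3.6, OAA 1.5, glutamate 2.0, succinyl-CoA
0.6 (the CoA carrier is recycled — the succinyl moiety demand makes AKGDH
flux obligatory for growth), ATP 24 and NADPH 4.8 per unit growth. These are
toy-scale coefficients, not a measured biomass equation; they were chosen so
that (i) the wild type grows at a realistic ~0.56 h⁻¹ at the reference
glucose uptake of 4.67 mmol/gCDW/h, and (ii) the wild-type aconitase flux
leaves at least threefold headroom inside the fixed carbon budget, since the
multiplier scan probes up to 3×. The lactate valve exists because a model
whose only pyruvate sink is PDH→CS renders low-growth/fixed-ACN producer
states infeasible — every glucose forces one pyruvate through the PTS — which
is an artifact of lumping, not a property of the organism.

Emergent behavior worth noting (computed, not fitted): on this model the
producer reroutes flux into the TCA entry (citrate synthase up), raises EMP
and lowers oxidative PPP flux relative to the wild type, the scan's product
trace peaks at the 2.0 multiplier, and beyond it flux spills into the GABA
shunt while export declines. The 21×21 robustness surface over
growth × SUCOAS flux attains its maximum at the zero-growth, zero-SUCOAS
corner.

What the synthetic model does **not** emulate: genome-scale redundancy
(isozymes, alternative pathways, transhydrogenases), regulation and enzyme
kinetics, maintenance scaling with growth, byproduct spectra beyond lactate,
and any fitted biomass composition. Passing tests on it demonstrate that the
algorithms are implemented correctly and that the qualitative design logic
holds on a balanced network — not that numerical fluxes transfer to a real
genome-scale model. For external models (e.g. a published *C. glutamicum*
reconstruction) the user must supply an id/role map; printed fluxes from
other studies may additionally depend on their solver's vertex choice, which
is why FVA brackets accompany any such comparison.

## Mini fixtures

Four-to-twelve-reaction fixtures with independently derived optima support
oracle-based testing: `M1` (uptake 10 splits equally into two biomass
precursors, μ* = 5), `M1_product` (adds a product exchange; at a 0.2 floor
the optimum is exactly biomass 1, product 8), `cycle` (an isolated
two-reaction loop that pFBA must silence), `akg_node` (a six-reaction α-KG
branch point whose producer solution sends 80% of node consumption to the
GABA branch), and `shunt_leak` (a twelve-reaction producer abstraction whose
NADPH stoichiometry couples the oxidative TCA lump to glutamate synthesis;
its closed-form wild-type optimum is μ* = 125/18 with reference branch flux
27.5/18, and forcing the branch to 3× recruits the GABA shunt because the
carbon budget can no longer supply PPP-derived NADPH). The `shunt_leak`
biomass NADPH coefficient (0.48) was set from the closed-form analysis so
that all five scan multipliers are feasible and the shunt recruitment
appears within them; the fixture exists precisely to make that qualitative
mechanism oracle-checkable.

Knockout sanity checks that require *no* α-KG→succinate bypass (growth must
hit zero when SUCOAS, the glyoxylate shunt, and anaplerosis are all removed)
run on the core variant built without the GABA shunt, because
GAD + gadT + gadD otherwise form exactly such a bypass — a real property of
the network, not a test artifact.

## Limitations

Deletions can never increase an FBA optimum, so the in-vivo benefit of
removing GABA catabolism or rewiring transport is outside what this
formulation can show; those effects are kinetic/regulatory. Dynamic
(fed-batch) behavior, thermodynamic constraints, loopless FBA and
MILP-based design methods are out of scope. Experimental titers (g/L) and
volumetric productivities are not model quantities; the only unit bridge
provided is the empirical CDW (g/L) = 0.27 × OD600 conversion.
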