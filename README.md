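# gabaflux

Constraint-based flux analysis for designing GABA- and butyrolactam-producing
*Corynebacterium glutamicum* strains.

γ-aminobutyric acid (GABA) is made from L-glutamate in a single decarboxylation
catalyzed by glutamate decarboxylase (GAD), and butyrolactam
(2-pyrrolidinone) follows from GABA via an acetyl-CoA-dependent CoA transfer
with spontaneous cyclization. Designing a producer strain is a flux-routing
problem at the TCA cycle: the α-ketoglutarate node splits between the
oxidative branch (α-ketoglutarate dehydrogenase, AKGDH, then succinyl-CoA
synthetase, SUCOAS) and the glutamate/GABA branch (glutamate dehydrogenase,
then GAD). This package implements the model-guided analyses a metabolic
engineer runs to decide where to push and where to cut, for anyone who wants
to reproduce or extend that workflow on their own stoichiometric model.

## What it computes

Given a stoichiometric model S with flux bounds, flux balance analysis (FBA)
solves

    maximize  c·v   subject to   S·v = 0,  lb ≤ v ≤ ub

Reported distributions are canonicalized by parsimonious FBA (pFBA): among
near-optimal solutions, the one minimizing Σ|v| — so outputs do not depend on
which optimal vertex a particular solver returns. On top of this engine:

- **Producer formulation** — maximize GABA export with growth constrained to
  ≥ 20% of the maximal growth rate μ* (the fraction is configurable).
- **Aconitase multiplier scan** — fix the aconitase (ACN) flux at
  k × its wild-type pFBA value for k ∈ {1.0, 1.5, 2.0, 2.5, 3.0}, re-optimize
  the producer per k, and report uptake-normalized flux changes
  (v_k − v_wt)/|v_glc| plus the product-flux trace.
- **Double-robustness surface** — optimal GABA flux over a grid of
  (growth rate × AKGDH/SUCOAS flux), both fixed by equality per cell.
- **Strain series** — ordered edit scripts (promoter-swap overexpression as a
  flux equality at k × wild type, knockouts as zero bounds, transporter
  rewiring, pathway additions) evaluated for maximal growth and producer flux.
- **Node accounting** — stoichiometry-weighted consumption fractions at any
  branch-point metabolite (e.g. the α-KG node).

Two LP backends (scipy/HiGHS and GLPK via swiglpk) are supported and must
agree; a brute-force vertex-enumeration oracle independently verifies optima
on small fixtures. Models are read and written in a documented JSON dialect
and in SBML Level 3 with FBC bounds.

The package ships a carbon- and element-balanced synthetic core model of
*C. glutamicum* central metabolism (39 reactions: PTS uptake, EMP, oxidative
PPP, full TCA, glyoxylate shunt, PEP carboxylase, GDH/GAD, GABA transport and
shunt, oxidative phosphorylation, ATP maintenance, biomass with an explicit
succinyl-CoA demand) so every analysis runs end to end without downloads.
External genome-scale models can be supplied as SBML/JSON with a role map.

## Worked example

```
$ gabaflux producer --out demo_out
[gabaflux] config_hash=058babb904f4a1c3 version=0.1.0 product_flux=3.736 biomass_floor=0.11208
```

`demo_out/producer_summary.json` then contains

```json
{
 "biomass_floor": 0.11208000000000001,
 "mu_star": 0.5604,
 "product_flux": 3.735999999996265,
 "status": "optimal"
}
```

Reading: on the packaged core model with glucose uptake fixed at
4.67 mmol/gCDW/h, the wild type grows at μ* = 0.5604 h⁻¹; with growth floored
at 20% of that (0.1121 h⁻¹) and GABA export as the objective, the producer
exports 3.736 mmol GABA/gCDW/h — a yield of 0.80 mol GABA per mol glucose
(the zero-growth theoretical maximum on this model is 1.0 mol/mol).

```
$ gabaflux scan --out demo_scan
[gabaflux] config_hash=8040e18d834ba38f version=0.1.0 best_multiplier=2.0
$ head -4 demo_scan/scan_product_trace.tsv
multiplier      product_flux
1       1.59527
1.5     2.53861
2       3.48195
```

Fixing aconitase flux at multiples of its wild-type value, GABA productivity
peaks at the twofold multiplier and declines beyond it, where flux spills
into the GABA shunt (gadT/gadD) instead of export. The same library calls are
available in Python (`gabaflux.acn_scan`, `gabaflux.double_robustness`, ...),
and `gabaflux strains` evaluates the packaged GABA-1..6 / BLM-1..3 edit
series.

## Layout

- `src/gabaflux/metnet.py` — model structures, JSON/SBML I/O, edits, medium,
  elemental balance checking
- `src/gabaflux/lp.py`, `fba.py` — LP backends; FBA, pFBA, FVA, producer mode,
  yields
- `src/gabaflux/design.py` — scans, delta maps, node splits, robustness
  surfaces, strain series
- `src/gabaflux/synthetic.py` — core-model builder, mini fixtures, vertex
  oracle, perturbations
- `src/gabaflux/cli.py`, `report.py`, `units.py` — CLI, deterministic writers,
  conversions
- `docs/methods.md` — model assumptions, parameter choices, numerical details
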