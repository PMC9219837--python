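"""Synthetic carbon-balanced core model of C. glutamicum central metabolism,
mini fixtures with hand-enumerable optima, a brute-force LP oracle, and a
seeded bound-perturbation helper.

The core model covers glucose PTS uptake, a three-stage EMP lump, the
oxidative pentose phosphate lump with its non-oxidative return, pyruvate
dehydrogenase, the full TCA cycle (CS, ACN, ICD, AKGDH, SUCOAS, SDH, FUM,
MDH), the glyoxylate shunt (aceA/aceB), PEP carboxylase anaplerosis,
glutamate dehydrogenase, glutamate decarboxylase (GAD), GABA transport and
exchange, the GABA shunt (gadT/gadD), a lumped oxidative phosphorylation
honoring a configurable P/O ratio, ATP maintenance, and a biomass reaction
with an explicit succinyl-CoA demand.  Every species carries an elemental
formula and every non-exchange reaction except biomass is elementally
balanced by construction.

The lumping granularity is the coarsest at which each heatmap row group of
interest (EMP, PPP, TCA, glyoxylate, GABA shunt) still maps to a distinct
reaction.  Biomass coefficients and the P/O ratio are order-of-magnitude
toy values; they carry no claim of matching any genome-scale biomass
equation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np

from .fba import FluxState
from .metnet import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    add_butyrolactam_pathway,
    parse_formula,
)

__all__ = [
    "CoreModelParams",
    "FixtureSpec",
    "OracleScopeError",
    "build_core_model",
    "build_mini_model",
    "MINI_MODEL_NAMES",
    "mini_fixture_spec",
    "oracle_solve",
    "perturb_model",
]


class OracleScopeError(ModelError):
    """The brute-force oracle was asked to solve a too-large instance."""


@dataclass
class CoreModelParams:
    """Knobs of the synthetic core model.

    ``biomass_stoich`` drains precursors per unit growth; the succinyl-CoA
    demand must be positive (the moiety is consumed and the CoA carrier is
    recycled), mirroring its essential role in biomass formation.  Rates are
    mmol/gCDW/h; ``glucose_uptake`` defaults to the reference uptake rate of
    4.67 mmol/gCDW/h.
    """

    biomass_stoich: dict[str, float] = field(
        default_factory=lambda: {
            "g6p_c": 2.4,
            "pyr_c": 3.6,
            "oaa_c": 1.5,
            "glu_c": 2.0,
            "succoa_c": 0.6,
            "atp_c": 24.0,
            "nadph_c": 4.8,
        }
    )
    atp_maintenance: float = 2.0
    po_ratio: float = 2.0
    include_glyoxylate: bool = True
    include_gaba_shunt: bool = True
    include_gaba_uptake: bool = True
    include_act_branch: bool = False
    include_gad: bool = True
    glucose_uptake: float = 4.67

    def validate(self) -> None:
        for met, coef in self.biomass_stoich.items():
            if coef < 0:
                raise ModelError(f"biomass coefficient for {met!r} must be >= 0")
        if self.biomass_stoich.get("succoa_c", 0.0) <= 0:
            raise ModelError("biomass must include a positive succinyl-CoA demand")
        if self.atp_maintenance < 0:
            raise ModelError("atp_maintenance must be >= 0")
        if self.po_ratio < 0:
            raise ModelError("po_ratio must be >= 0")
        if self.glucose_uptake < 0:
            raise ModelError("glucose_uptake must be >= 0")
        if self.include_act_branch and not self.include_gad:
            raise ModelError("the butyrolactam branch requires the GAD route")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FixtureSpec:
    """Machine-checkable expectations shipped with a fixture model."""

    name: str
    description: str
    expected_properties: list[dict]


# ---------------------------------------------------------------------------
# core model

_F = parse_formula

_SPECIES = [
    # (id, name, compartment, formula)
    ("glc_e", "D-glucose (extracellular)", "e", "C6H12O6"),
    ("g6p_c", "glucose-6-phosphate", "c", "C6H13O9P"),
    ("f6p_c", "fructose-6-phosphate", "c", "C6H13O9P"),
    ("g3p_c", "glyceraldehyde-3-phosphate", "c", "C3H7O6P"),
    ("ru5p_c", "ribulose-5-phosphate", "c", "C5H11O8P"),
    ("pep_c", "phosphoenolpyruvate", "c", "C3H5O6P"),
    ("pyr_c", "pyruvate", "c", "C3H4O3"),
    ("accoa_c", "acetyl-CoA", "c", "C23H38N7O17P3S"),
    ("coa_c", "coenzyme A", "c", "C21H36N7O16P3S"),
    ("cit_c", "citrate", "c", "C6H8O7"),
    ("icit_c", "isocitrate", "c", "C6H8O7"),
    ("akg_c", "alpha-ketoglutarate", "c", "C5H6O5"),
    ("succoa_c", "succinyl-CoA", "c", "C25H40N7O19P3S"),
    ("succ_c", "succinate", "c", "C4H6O4"),
    ("fum_c", "fumarate", "c", "C4H4O4"),
    ("mal_c", "malate", "c", "C4H6O5"),
    ("oaa_c", "oxaloacetate", "c", "C4H4O5"),
    ("glx_c", "glyoxylate", "c", "C2H2O3"),
    ("glu_c", "L-glutamate", "c", "C5H9NO4"),
    ("4aba_c", "4-aminobutyrate (GABA)", "c", "C4H9NO2"),
    ("4aba_e", "4-aminobutyrate (extracellular)", "e", "C4H9NO2"),
    ("ssa_c", "succinic semialdehyde", "c", "C4H6O3"),
    ("atp_c", "ATP", "c", "C10H16N5O13P3"),
    ("adp_c", "ADP", "c", "C10H15N5O10P2"),
    ("pi_c", "phosphate", "c", "H3O4P"),
    # the reduced nicotinamide carriers absorb the proton (NAD + H2)
    ("nad_c", "NAD+", "c", "C21H27N7O14P2"),
    ("nadh_c", "NADH", "c", "C21H29N7O14P2"),
    ("nadp_c", "NADP+", "c", "C21H28N7O17P3"),
    ("nadph_c", "NADPH", "c", "C21H30N7O17P3"),
    ("lac_c", "L-lactate", "c", "C3H6O3"),
    ("nh3_c", "ammonia", "c", "H3N"),
    ("co2_c", "carbon dioxide", "c", "CO2"),
    ("o2_c", "oxygen", "c", "O2"),
    ("h2o_c", "water", "c", "H2O"),
    ("so3_c", "sulfite", "c", "O3S"),
]


def build_core_model(params: CoreModelParams | None = None) -> MetabolicModel:
    """Build the packaged core-carbon model from ``params``.

    A pure function of its parameters: equal params give byte-identical JSON
    serializations.
    """
    p = params or CoreModelParams()
    p.validate()
    model = MetabolicModel("cglutamicum_core")
    for met_id, name, comp, formula in _SPECIES:
        model.add_metabolite(Metabolite(met_id, name, comp, _F(formula)))
    model.add_metabolite(Metabolite("biomass_c", "biomass", "c", None))

    def rxn(id, stoich, lb, ub, name="", role=None, subsystem=None):
        model.add_reaction(
            Reaction(id, dict(stoich), name=name, lower_bound=lb, upper_bound=ub,
                     role=role, subsystem=subsystem)
        )

    B = DEFAULT_BOUND
    g = p.glucose_uptake
    # exchanges: glucose fixed; small molecules freely transported
    rxn("EX_glc_e", {"glc_e": -1}, -g, -g, "glucose exchange", "GLC_UPTAKE", "exchange")
    for met in ("o2_c", "co2_c", "nh3_c", "pi_c", "h2o_c", "so3_c"):
        rxn(f"EX_{met}", {met: -1}, -B, B, f"{met} exchange", None, "exchange")
    # EMP at three-stage resolution so the EMP/PPP split stays visible
    rxn("PTS", {"glc_e": -1, "pep_c": -1, "g6p_c": 1, "pyr_c": 1}, 0, B,
        "glucose PTS uptake", None, "emp")
    rxn("PGI", {"g6p_c": -1, "f6p_c": 1}, -B, B, "phosphoglucose isomerase", None, "emp")
    rxn("PFK_ALD", {"f6p_c": -1, "atp_c": -1, "g3p_c": 2, "adp_c": 1}, 0, B,
        "upper glycolysis lump (PFK + aldolase + TPI)", None, "emp")
    rxn("GAPDH_ENO",
        {"g3p_c": -1, "adp_c": -1, "pi_c": -1, "nad_c": -1,
         "pep_c": 1, "atp_c": 1, "nadh_c": 1, "h2o_c": 1},
        -B, B, "lower glycolysis lump (GAPDH..enolase)", None, "emp")
    rxn("PYK", {"pep_c": -1, "adp_c": -1, "pyr_c": 1, "atp_c": 1}, 0, B,
        "pyruvate kinase", None, "emp")
    # overflow valve: lactate secretion decouples glycolytic rate from the TCA
    rxn("LDH", {"pyr_c": -1, "nadh_c": -1, "lac_c": 1, "nad_c": 1}, 0, B,
        "lactate dehydrogenase (overflow)", None, "overflow")
    rxn("EX_lac_c", {"lac_c": -1}, 0, B, "lactate exchange", None, "exchange")
    # pentose phosphate pathway
    rxn("PPP_OX",
        {"g6p_c": -1, "nadp_c": -2, "h2o_c": -1, "ru5p_c": 1, "co2_c": 1, "nadph_c": 2},
        0, B, "oxidative PPP lump (G6PDH + 6PGDH)", None, "ppp")
    rxn("PPP_NONOX", {"ru5p_c": -3, "f6p_c": 2, "g3p_c": 1}, -B, B,
        "non-oxidative PPP return", None, "ppp")
    # pyruvate dehydrogenase and TCA cycle
    rxn("PDH", {"pyr_c": -1, "coa_c": -1, "nad_c": -1,
                "accoa_c": 1, "co2_c": 1, "nadh_c": 1}, 0, B,
        "pyruvate dehydrogenase", None, "tca")
    rxn("CS", {"accoa_c": -1, "oaa_c": -1, "h2o_c": -1, "cit_c": 1, "coa_c": 1}, 0, B,
        "citrate synthase (gltA)", None, "tca")
    rxn("ACN", {"cit_c": -1, "icit_c": 1}, -B, B, "aconitase (acn)", "ACN", "tca")
    rxn("ICD", {"icit_c": -1, "nadp_c": -1, "akg_c": 1, "co2_c": 1, "nadph_c": 1}, 0, B,
        "isocitrate dehydrogenase (icd, NADPH)", None, "tca")
    rxn("AKGDH", {"akg_c": -1, "coa_c": -1, "nad_c": -1,
                  "succoa_c": 1, "co2_c": 1, "nadh_c": 1}, 0, B,
        "alpha-ketoglutarate dehydrogenase complex", "AKGDH", "tca")
    rxn("SUCOAS", {"succoa_c": -1, "adp_c": -1, "pi_c": -1,
                   "succ_c": 1, "atp_c": 1, "coa_c": 1}, -B, B,
        "succinyl-CoA synthetase (sucCD)", "SUCOAS", "tca")
    rxn("SDH", {"succ_c": -1, "nad_c": -1, "fum_c": 1, "nadh_c": 1}, 0, B,
        "succinate dehydrogenase (lumped to NAD)", None, "tca")
    rxn("FUM", {"fum_c": -1, "h2o_c": -1, "mal_c": 1}, -B, B, "fumarase", None, "tca")
    rxn("MDH", {"mal_c": -1, "nad_c": -1, "oaa_c": 1, "nadh_c": 1}, -B, B,
        "malate dehydrogenase", None, "tca")
    if p.include_glyoxylate:
        rxn("ICL", {"icit_c": -1, "succ_c": 1, "glx_c": 1}, 0, B,
            "isocitrate lyase (aceA)", "ACEA", "glyoxylate")
        rxn("MS", {"glx_c": -1, "accoa_c": -1, "h2o_c": -1, "mal_c": 1, "coa_c": 1},
            0, B, "malate synthase (aceB)", "ACEB", "glyoxylate")
    # anaplerosis and nitrogen assimilation
    rxn("PPC", {"pep_c": -1, "co2_c": -1, "h2o_c": -1, "oaa_c": 1, "pi_c": 1}, 0, B,
        "PEP carboxylase", None, "anaplerosis")
    rxn("GDH", {"akg_c": -1, "nh3_c": -1, "nadph_c": -1,
                "glu_c": 1, "nadp_c": 1, "h2o_c": 1}, 0, B,
        "glutamate dehydrogenase (gdh)", None, "nitrogen")
    # GABA route: decarboxylation, transport, exchange
    if p.include_gad:
        rxn("GAD", {"glu_c": -1, "4aba_c": 1, "co2_c": 1}, -B, B,
            "glutamate decarboxylase (heterologous gad)", "GAD", "gaba")
    rxn("GABAt_out", {"4aba_c": -1, "4aba_e": 1}, 0, B,
        "GABA export transport (potE-like)", None, "gaba")
    if p.include_gaba_uptake:
        rxn("GABAt_in", {"4aba_e": -1, "4aba_c": 1}, 0, B,
            "GABA uptake symporter (gadP)", "GABA_UPTAKE", "gaba")
    rxn("EX_4aba_e", {"4aba_e": -1}, 0, B, "GABA exchange", "GABA_EXPORT", "exchange")
    if p.include_gaba_shunt:
        rxn("GABA_TA", {"4aba_c": -1, "akg_c": -1, "ssa_c": 1, "glu_c": 1}, 0, B,
            "GABA aminotransferase (gadT)", "GABA_SHUNT_T", "gaba_shunt")
        rxn("SSADH", {"ssa_c": -1, "nad_c": -1, "h2o_c": -1, "succ_c": 1, "nadh_c": 1},
            0, B, "succinate-semialdehyde dehydrogenase (gadD)", "GABA_SHUNT_D",
            "gaba_shunt")
    # energy metabolism
    po = p.po_ratio
    rxn("OXPHOS",
        {"nadh_c": -1, "o2_c": -0.5, "adp_c": -po, "pi_c": -po,
         "nad_c": 1, "atp_c": po, "h2o_c": 1 + po},
        0, B, f"oxidative phosphorylation lump (P/O = {po:g})", None, "energy")
    rxn("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
        p.atp_maintenance, B, "ATP maintenance", None, "energy")
    # biomass: drain precursors, recycle the carriers
    bs = p.biomass_stoich
    biomass_stoich: dict[str, float] = {m: -c for m, c in bs.items() if c > 0}
    atp = bs.get("atp_c", 0.0)
    biomass_stoich["h2o_c"] = biomass_stoich.get("h2o_c", 0.0) - atp
    biomass_stoich["adp_c"] = atp
    biomass_stoich["pi_c"] = atp
    biomass_stoich["coa_c"] = bs.get("succoa_c", 0.0)
    biomass_stoich["nadp_c"] = bs.get("nadph_c", 0.0)
    biomass_stoich["biomass_c"] = 1.0
    biomass_stoich = {m: c for m, c in biomass_stoich.items() if c != 0}
    rxn("BIOMASS", biomass_stoich, 0, B, "biomass formation", "BIOMASS", "biomass")
    rxn("EX_biomass_c", {"biomass_c": -1}, 0, B, "biomass sink", None, "exchange")
    model.objective = {"BIOMASS": 1.0}
    if p.include_act_branch:
        model = add_butyrolactam_pathway(model)
        model.objective = {"BIOMASS": 1.0}
    model.validate()
    return model


# ---------------------------------------------------------------------------
# mini fixtures

MINI_MODEL_NAMES = ("M1", "M1_product", "cycle", "akg_node", "shunt_leak")


def _abstract_met(mid: str) -> Metabolite:
    return Metabolite(mid, mid, "c", None)


def _mini_m1(with_product: bool) -> MetabolicModel:
    model = MetabolicModel("M1_product" if with_product else "M1")
    for mid in "ABC":
        model.add_metabolite(_abstract_met(mid))
    model.add_reaction(Reaction("EX_A", {"A": -1}, lower_bound=-10, upper_bound=0))
    model.add_reaction(Reaction("R_AB", {"A": -1, "B": 1}, lower_bound=0))
    model.add_reaction(Reaction("R_AC", {"A": -1, "C": 1}, lower_bound=0))
    model.add_reaction(
        Reaction("BIOMASS", {"B": -1, "C": -1}, lower_bound=0, role="BIOMASS")
    )
    if with_product:
        model.add_reaction(
            Reaction("EX_C", {"C": -1}, lower_bound=0, role="GABA_EXPORT")
        )
    model.objective = {"BIOMASS": 1.0}
    return model


def _mini_cycle() -> MetabolicModel:
    model = _mini_m1(False)
    model.id = "cycle"
    model.add_metabolite(_abstract_met("D"))
    model.add_metabolite(_abstract_met("E"))
    model.add_reaction(Reaction("R_DE", {"D": -1, "E": 1}, lower_bound=0))
    model.add_reaction(Reaction("R_ED", {"E": -1, "D": 1}, lower_bound=0))
    return model


def _mini_akg_node() -> MetabolicModel:
    model = MetabolicModel("akg_node")
    for mid in ("akg", "succ", "gaba"):
        model.add_metabolite(_abstract_met(mid))
    model.add_reaction(Reaction("EX_akg", {"akg": -1}, lower_bound=-10, upper_bound=0,
                                role="GLC_UPTAKE",
                                name="substrate uptake (alpha-KG supply lump)"))
    model.add_reaction(
        Reaction("RED", {"akg": -1, "succ": 1}, lower_bound=0, role="AKGDH",
                 name="oxidative branch lump (AKGDH+SUCOAS)")
    )
    model.add_reaction(Reaction("EX_succ", {"succ": -1}, lower_bound=0))
    model.add_reaction(
        Reaction("GADL", {"akg": -1, "gaba": 1}, lower_bound=0, role="GAD",
                 name="glutamate branch lump (GDH+GAD)")
    )
    model.add_reaction(
        Reaction("EX_gaba", {"gaba": -1}, lower_bound=0, role="GABA_EXPORT")
    )
    model.add_reaction(
        Reaction("BIOMASS", {"akg": -0.5, "succ": -0.5}, lower_bound=0, role="BIOMASS")
    )
    model.objective = {"BIOMASS": 1.0}
    return model


def _mini_shunt_leak() -> MetabolicModel:
    """Twelve-reaction producer abstraction whose NADPH/carbon coupling makes
    forced high oxidative-branch flux spill into the GABA shunt."""
    model = MetabolicModel("shunt_leak")
    for mid in ("s", "accoa", "oaa", "akg", "glu", "gaba", "ssa", "succ", "nadph"):
        model.add_metabolite(_abstract_met(mid))
    R = Reaction
    model.add_reaction(R("EX_s", {"s": -1}, lower_bound=-10, upper_bound=0,
                         role="GLC_UPTAKE"))
    model.add_reaction(R("EMP", {"s": -1, "accoa": 1}, lower_bound=0))
    model.add_reaction(R("PPC", {"s": -1, "oaa": 1}, lower_bound=0))
    model.add_reaction(R("PPP", {"s": -1, "accoa": 1, "nadph": 2}, lower_bound=0))
    model.add_reaction(R("TCA1", {"accoa": -1, "oaa": -1, "akg": 1, "nadph": 1},
                         lower_bound=0, role="ACN",
                         name="oxidative TCA lump (CS+ACN+ICD)"))
    model.add_reaction(R("GDH", {"akg": -1, "nadph": -1, "glu": 1}, lower_bound=0))
    model.add_reaction(R("GAD", {"glu": -1, "gaba": 1}, lower_bound=0, role="GAD"))
    model.add_reaction(R("EX_gaba", {"gaba": -1}, lower_bound=0, role="GABA_EXPORT"))
    model.add_reaction(R("GABA_TA", {"gaba": -1, "akg": -1, "glu": 1, "ssa": 1},
                         lower_bound=0, role="GABA_SHUNT_T"))
    model.add_reaction(R("SSADH", {"ssa": -1, "succ": 1}, lower_bound=0,
                         role="GABA_SHUNT_D"))
    model.add_reaction(R("SDHMDH", {"succ": -1, "oaa": 1}, lower_bound=0))
    model.add_reaction(R("BIOMASS",
                         {"glu": -0.17, "oaa": -1.0, "nadph": -0.48, "succ": -0.05},
                         lower_bound=0, role="BIOMASS"))
    model.objective = {"BIOMASS": 1.0}
    return model


def build_mini_model(name: str) -> MetabolicModel:
    """Return a named mini fixture with oracle-verifiable structure."""
    builders = {
        "M1": lambda: _mini_m1(False),
        "M1_product": lambda: _mini_m1(True),
        "cycle": _mini_cycle,
        "akg_node": _mini_akg_node,
        "shunt_leak": _mini_shunt_leak,
    }
    if name not in builders:
        raise ModelError(f"unknown mini model {name!r}; choose from {MINI_MODEL_NAMES}")
    model = builders[name]()
    model.validate()
    return model


def mini_fixture_spec(name: str) -> FixtureSpec:
    """Expected, independently derived properties of each mini fixture."""
    specs = {
        "M1": FixtureSpec(
            "M1",
            "uptake capped at 10 splits equally over two biomass precursors",
            [{"check": "max_objective", "value": 5.0, "tol": 1e-6}],
        ),
        "M1_product": FixtureSpec(
            "M1_product",
            "producer formulation: floor 0.2 leaves 8 units for the product",
            [
                {"check": "max_objective", "value": 5.0, "tol": 1e-6},
                {"check": "production_at_floor", "product_rxn": "EX_C",
                 "biomass_fraction": 0.2, "value": 8.0, "tol": 1e-6},
            ],
        ),
        "cycle": FixtureSpec(
            "cycle",
            "M1 plus an isolated 2-reaction loop carrying no objective",
            [
                {"check": "max_objective", "value": 5.0, "tol": 1e-6},
                {"check": "pfba_flux", "reaction": "R_DE", "value": 0.0, "tol": 1e-6},
            ],
        ),
        "akg_node": FixtureSpec(
            "akg_node",
            "alpha-KG branch point: biomass needs both branches, the producer "
            "sends 80% of node consumption to the GABA branch",
            [
                {"check": "max_objective", "value": 10.0, "tol": 1e-6},
                {"check": "production_at_floor", "product_rxn": "EX_gaba",
                 "biomass_fraction": 0.2, "value": 8.0, "tol": 1e-6},
            ],
        ),
        "shunt_leak": FixtureSpec(
            "shunt_leak",
            "NADPH stoichiometry couples the oxidative branch to glutamate "
            "synthesis; forcing the branch high spills flux into the GABA shunt "
            "(closed-form optimum: mu* = 125/18, reference branch flux 27.5/18)",
            [
                {"check": "max_objective", "value": 125.0 / 18.0, "tol": 1e-6},
                {"check": "wt_pfba_flux", "reaction": "TCA1",
                 "value": 27.5 / 18.0, "tol": 1e-6},
            ],
        ),
    }
    if name not in specs:
        raise ModelError(f"unknown mini model {name!r}")
    return specs[name]


# ---------------------------------------------------------------------------
# brute-force LP oracle


def oracle_solve(model: MetabolicModel, max_reactions: int = 12) -> FluxState:
    """Solve the model's LP by exhaustive enumeration of basic solutions.

    Every bounded, nonempty flux polytope attains its optimum at a vertex;
    vertices are enumerated by fixing (n - rank(S)) fluxes at a bound and
    solving the remaining square steady-state system.  Reactions whose bounds
    are fixed at zero are removed first.  Independent of the LP backends by
    construction; intended for fixtures only.
    """
    if not model.objective:
        raise ModelError("oracle requires a model objective")
    S, _met_ids, rxn_ids = model.stoichiometric_matrix()
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    active = [j for j in range(len(rxn_ids)) if not (lb[j] == 0 and ub[j] == 0)]
    n = len(active)
    if n > max_reactions:
        raise OracleScopeError(
            f"{n} active reactions exceed the oracle limit of {max_reactions}"
        )
    if not np.all(np.isfinite(lb[active])) or not np.all(np.isfinite(ub[active])):
        raise OracleScopeError("oracle requires finite bounds on active reactions")
    Sa = S[:, active]
    la, ua = lb[active], ub[active]
    c_full = np.zeros(len(rxn_ids))
    for rxn_id, w in model.objective.items():
        c_full[rxn_ids.index(rxn_id)] = w
    ca = c_full[active]
    rank = np.linalg.matrix_rank(Sa)
    n_fix = n - rank
    scale = max(1.0, float(np.max(np.abs(ua))), float(np.max(np.abs(la))))
    feas_tol = 1e-9 * scale
    best_obj = None
    best_v = None
    indices = range(n)
    for fixed in itertools.combinations(indices, n_fix):
        free = [j for j in indices if j not in fixed]
        S_free = Sa[:, free]
        S_fixed = Sa[:, fixed]
        for choice in itertools.product((0, 1), repeat=n_fix):
            v_fixed = np.array(
                [la[j] if side == 0 else ua[j] for j, side in zip(fixed, choice)]
            )
            rhs = -S_fixed @ v_fixed if n_fix else np.zeros(Sa.shape[0])
            if free:
                v_free, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
            else:
                v_free = np.zeros(0)
            v = np.empty(n)
            v[list(fixed)] = v_fixed
            v[free] = v_free
            if np.max(np.abs(Sa @ v), initial=0.0) > feas_tol:
                continue
            if np.any(v < la - feas_tol) or np.any(v > ua + feas_tol):
                continue
            obj = float(ca @ v)
            if best_obj is None or obj > best_obj + 0.0:
                best_obj = obj
                best_v = v.copy()
            if n_fix == 0:
                break
        if n_fix == 0 and best_obj is not None:
            break
    if best_obj is None:
        return FluxState({}, None, "infeasible", dict(model.objective),
                         {"oracle": True})
    fluxes = {r: 0.0 for r in rxn_ids}
    for j, col in enumerate(active):
        fluxes[rxn_ids[col]] = float(np.clip(best_v[j], lb[col], ub[col]))
    return FluxState(
        fluxes=fluxes,
        objective_value=best_obj,
        status="optimal",
        objective=dict(model.objective),
        meta={"oracle": True, "vertices_considered": True},
    )


# ---------------------------------------------------------------------------
# perturbations


def perturb_model(model: MetabolicModel, seed: int, magnitude: float = 0.1) -> MetabolicModel:
    """Deterministically jitter finite flux bounds by up to ``magnitude``.

    Bounds are scaled multiplicatively so zero bounds (irreversibility) and
    equality bounds (fixed exchanges) keep their structure; stoichiometry is
    untouched.  The same seed always yields the same model.
    """
    if magnitude < 0:
        raise ModelError("magnitude must be >= 0")
    rng = np.random.default_rng(seed)
    new = model.copy()
    for rxn in new.reactions.values():
        if rxn.lower_bound == rxn.upper_bound:
            factor = 1.0 + magnitude * rng.uniform(-1, 1)
            rxn.lower_bound *= factor
            rxn.upper_bound = rxn.lower_bound
            continue
        for attr in ("lower_bound", "upper_bound"):
            value = getattr(rxn, attr)
            if np.isfinite(value) and value != 0.0:
                setattr(rxn, attr, value * (1.0 + magnitude * rng.uniform(-1, 1)))
        if rxn.lower_bound > rxn.upper_bound:
            rxn.lower_bound, rxn.upper_bound = rxn.upper_bound, rxn.lower_bound
    return new
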