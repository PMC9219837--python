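"""Stoichiometric model data structures, I/O and the model-editing vocabulary.

The in-memory representation is deliberately small: a :class:`MetabolicModel`
is an ordered collection of :class:`Metabolite` and :class:`Reaction` objects
plus a linear objective.  Reversibility is encoded purely by flux bounds
(lower bound < 0), exchange reactions are boundary pseudo-reactions touching
exactly one metabolite, and strain edits (:class:`ModelEdit`) are applied
non-destructively so that a base model can be re-used across a strain series.

Two serializations are supported: a canonical JSON dialect (used for all
packaged fixtures) and SBML Level 3 with FBC-style flux bounds, read and
written through python-libsbml.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelEdit",
    "MediumSpec",
    "BalanceReport",
    "ModelError",
    "ParseError",
    "ConfigurationError",
    "EditError",
    "ROLES",
    "DEFAULT_BOUND",
    "load_model",
    "save_model",
    "add_gaba_pathway",
    "add_butyrolactam_pathway",
    "apply_edits",
    "set_medium",
    "check_mass_balance",
]

#: Canonical reaction role tags used to address reactions independent of id.
ROLES = frozenset(
    {
        "BIOMASS",
        "GLC_UPTAKE",
        "ACN",
        "AKGDH",
        "SUCOAS",
        "GAD",
        "GABA_EXPORT",
        "GABA_UPTAKE",
        "GABA_SHUNT_T",
        "GABA_SHUNT_D",
        "ACEA",
        "ACEB",
        "ACT",
    }
)

#: Default magnitude for otherwise unbounded fluxes (mmol/gCDW/h).
DEFAULT_BOUND = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelError(Exception):
    """Base class for model construction and validation failures."""


class ParseError(ModelError):
    """Raised when a model file does not parse in the named dialect."""


class ConfigurationError(ModelError):
    """Raised when a pathway edit cannot resolve required species ids."""


class EditError(ModelError):
    """Raised when a :class:`ModelEdit` does not validate against a model."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: dict[str, int] | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if self.formula is not None:
            for element, count in self.formula.items():
                if not (isinstance(count, int) and count >= 0):
                    raise ModelError(
                        f"metabolite {self.id!r}: formula count for {element!r} "
                        f"must be a non-negative integer, got {count!r}"
                    )

    def copy(self) -> "Metabolite":
        return replace(self, formula=dict(self.formula) if self.formula else None)


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gene_rule: str | None = None
    subsystem: str | None = None
    role: str | None = None

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} exceeds "
                f"upper_bound {self.upper_bound}"
            )
        if self.role is not None and self.role not in ROLES:
            raise ModelError(f"reaction {self.id!r}: unknown role {self.role!r}")

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


class MetabolicModel:
    """An S·v = 0 universe: metabolites, bounded reactions, linear objective."""

    def __init__(
        self,
        id: str,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        objective: Mapping[str, float] | None = None,
    ) -> None:
        self.id = id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.objective: dict[str, float] = dict(objective or {})
        for met in metabolites:
            self.add_metabolite(met)
        for rxn in reactions:
            self.add_reaction(rxn)
        if objective:
            self._check_objective()

    # -- construction -----------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ParseError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ParseError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ParseError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
        if rxn.role is not None and self.reactions_by_role(rxn.role):
            raise ModelError(
                f"reaction {rxn.id!r}: role {rxn.role!r} already present in model"
            )
        self.reactions[rxn.id] = rxn

    def _check_objective(self) -> None:
        for rxn_id in self.objective:
            if rxn_id not in self.reactions:
                raise ModelError(f"objective references unknown reaction {rxn_id!r}")

    # -- queries -----------------------------------------------------------

    def reactions_by_role(self, role: str) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.role == role]

    def reaction_by_role(self, role: str) -> Reaction:
        hits = self.reactions_by_role(role)
        if not hits:
            raise ModelError(f"model {self.id!r} has no reaction with role {role!r}")
        return hits[0]

    def resolve(self, key: str) -> Reaction:
        """Resolve a reaction by id, or by ``role:NAME``."""
        if key.startswith("role:"):
            return self.reaction_by_role(key[5:])
        if key in self.reactions:
            return self.reactions[key]
        raise ModelError(f"no reaction {key!r} in model {self.id!r}")

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def stoichiometric_matrix(self):
        """Return (S, met_ids, rxn_ids) with S dense, metabolites x reactions."""
        import numpy as np

        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rxn_id in enumerate(rxn_ids):
            for met_id, coef in self.reactions[rxn_id].stoichiometry.items():
                S[met_index[met_id], j] = coef
        return S, met_ids, rxn_ids

    def validate(self) -> None:
        """Check all type invariants; raise :class:`ModelError` on violation."""
        biomass = self.reactions_by_role("BIOMASS")
        if len(biomass) > 1:
            raise ModelError("more than one reaction tagged BIOMASS")
        seen_roles: set[str] = set()
        for rxn in self.reactions.values():
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelError(f"reaction {rxn.id!r}: inverted bounds")
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )
            if rxn.role is not None:
                if rxn.role in seen_roles:
                    raise ModelError(f"role {rxn.role!r} tagged on multiple reactions")
                seen_roles.add(rxn.role)
        self._check_objective()

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            self.id,
            (m.copy() for m in self.metabolites.values()),
            (r.copy() for r in self.reactions.values()),
            dict(self.objective),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def __repr__(self) -> str:
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )

    # -- serialization (JSON dialect) --------------------------------------

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "metabolites": [
                {
                    "id": m.id,
                    "name": m.name,
                    "compartment": m.compartment,
                    "formula": m.formula,
                    "charge": m.charge,
                }
                for m in self.metabolites.values()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "stoichiometry": r.stoichiometry,
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "gene_rule": r.gene_rule,
                    "subsystem": r.subsystem,
                    "role": r.role,
                }
                for r in self.reactions.values()
            ],
            "objective": self.objective,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "MetabolicModel":
        try:
            mets = [
                Metabolite(
                    id=m["id"],
                    name=m.get("name", ""),
                    compartment=m.get("compartment", "c"),
                    formula=dict(m["formula"]) if m.get("formula") else None,
                    charge=m.get("charge"),
                )
                for m in data.get("metabolites", [])
            ]
            rxns = []
            for r in data.get("reactions", []):
                lb = r.get("lower_bound", -DEFAULT_BOUND)
                ub = r.get("upper_bound", DEFAULT_BOUND)
                if not isinstance(lb, (int, float)) or not isinstance(ub, (int, float)):
                    raise ParseError(
                        f"reaction {r.get('id')!r}: malformed numeric bound "
                        f"({lb!r}, {ub!r})"
                    )
                rxns.append(
                    Reaction(
                        id=r["id"],
                        name=r.get("name", ""),
                        stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                        lower_bound=float(lb),
                        upper_bound=float(ub),
                        gene_rule=r.get("gene_rule"),
                        subsystem=r.get("subsystem"),
                        role=r.get("role"),
                    )
                )
        except KeyError as exc:
            raise ParseError(f"missing required field {exc}") from exc
        model = cls(data.get("id", "model"), mets, rxns, data.get("objective") or {})
        model.validate()
        return model


@dataclass
class ModelEdit:
    """One strain edit: add/delete a reaction, change bounds, or set the objective.

    ``payload`` by kind:

    - ``add_reaction``: a :class:`Reaction` (plus optional ``metabolites`` list)
    - ``delete_reaction``: reaction id or ``role:NAME`` (bounds fixed to zero)
    - ``set_bounds``: ``(reaction, lower, upper)``
    - ``scale_bounds``: ``(reaction, factor)``
    - ``set_objective``: mapping reaction id -> weight
    """

    kind: str
    payload: object
    label: str = ""

    KINDS = ("add_reaction", "delete_reaction", "set_bounds", "scale_bounds", "set_objective")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise EditError(f"edit {self.label!r}: unknown kind {self.kind!r}")

    def validate(self, model: MetabolicModel) -> None:
        name = self.label or self.kind
        if self.kind == "add_reaction":
            rxn = self.payload[0] if isinstance(self.payload, tuple) else self.payload
            if not isinstance(rxn, Reaction):
                raise EditError(f"edit {name!r}: add_reaction payload must be a Reaction")
            if rxn.id in model.reactions:
                raise EditError(f"edit {name!r}: reaction {rxn.id!r} already exists")
        elif self.kind == "delete_reaction":
            model.resolve(self._key())
        elif self.kind == "set_bounds":
            key, lb, ub = self.payload
            model.resolve(key)
            if float(lb) > float(ub):
                raise EditError(f"edit {name!r}: lower bound exceeds upper bound")
        elif self.kind == "scale_bounds":
            key, factor = self.payload
            model.resolve(key)
            float(factor)
        elif self.kind == "set_objective":
            for rxn_id in dict(self.payload):
                model.resolve(rxn_id)

    def _key(self) -> str:
        return self.payload if isinstance(self.payload, str) else self.payload[0]

    def apply(self, model: MetabolicModel) -> None:
        """Apply in place (callers pass a copy; see :func:`apply_edits`)."""
        try:
            self.validate(model)
        except ModelError as exc:
            raise EditError(f"edit {self.label or self.kind!r} failed: {exc}") from exc
        if self.kind == "add_reaction":
            if isinstance(self.payload, tuple):
                rxn, new_mets = self.payload
                for met in new_mets:
                    if met.id not in model.metabolites:
                        model.add_metabolite(met)
            else:
                rxn = self.payload
            model.add_reaction(rxn.copy())
        elif self.kind == "delete_reaction":
            rxn = model.resolve(self._key())
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
        elif self.kind == "set_bounds":
            key, lb, ub = self.payload
            rxn = model.resolve(key)
            rxn.lower_bound = float(lb)
            rxn.upper_bound = float(ub)
        elif self.kind == "scale_bounds":
            key, factor = self.payload
            rxn = model.resolve(key)
            rxn.lower_bound *= float(factor)
            rxn.upper_bound *= float(factor)
        elif self.kind == "set_objective":
            model.objective = {k: float(v) for k, v in dict(self.payload).items()}


@dataclass
class MediumSpec:
    """Growth-medium constraints on exchange reactions.

    Uptake rates are stored positive (mmol/gCDW/h) and applied as equality
    bounds with the uptake-negative sign convention; ``free_exchanges`` are
    opened in both directions; every other exchange is closed to uptake
    (lower bound 0) unless listed in ``keep``.
    """

    fixed_uptakes: dict[str, float] = field(default_factory=dict)
    free_exchanges: list[str] = field(default_factory=list)
    keep: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rxn_id, rate in self.fixed_uptakes.items():
            if rate < 0:
                raise ModelError(f"uptake rate for {rxn_id!r} must be >= 0, got {rate}")


@dataclass
class BalanceReport:
    """Result of :func:`check_mass_balance`."""

    imbalanced: dict[str, dict[str, float]]
    skipped: list[str]

    @property
    def ok(self) -> bool:
        return not self.imbalanced


# ---------------------------------------------------------------------------
# formulas


def parse_formula(text: str) -> dict[str, int]:
    """Parse an elemental formula string like ``C6H12O6`` into counts."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ParseError(f"malformed formula {text!r}")
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise ParseError(f"malformed formula {text!r}")
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    order = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    return "".join(f"{e}{counts[e]}" if counts[e] != 1 else e for e in order if counts[e])


# ---------------------------------------------------------------------------
# I/O


def load_model(path, format: str = "json") -> MetabolicModel:
    """Load a model from ``path`` in the named dialect ({json, sbml})."""
    if format == "json":
        with open(path) as handle:
            try:
                data = json.load(handle)
            except json.JSONDecodeError as exc:
                raise ParseError(f"invalid JSON in {path}: {exc}") from exc
        return MetabolicModel.from_dict(data)
    if format == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown format {format!r}")


def save_model(model: MetabolicModel, path, format: str = "json") -> None:
    """Write ``model`` to ``path``; the file reloads to an equal model."""
    if format == "json":
        with open(path, "w") as handle:
            json.dump(model.to_dict(), handle, indent=1, sort_keys=False)
            handle.write("\n")
        return
    if format == "sbml":
        _save_sbml(model, path)
        return
    raise ValueError(f"unknown format {format!r}")


def _sbml_sid(prefix: str, raw: str) -> str:
    """Make an SBML SId (letter/underscore start) with the BiGG-style prefix."""
    return prefix + re.sub(r"[^A-Za-z0-9_]", "_", raw)


def _strip_sid(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _load_sbml(path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ParseError(
            f"libsbml reported errors reading {path}: "
            f"{doc.getErrorLog().toString()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ParseError(f"no model element in {path}")
    mets = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue
        fbc_sp = sp.getPlugin("fbc")
        formula = None
        charge = None
        if fbc_sp is not None:
            if fbc_sp.isSetChemicalFormula():
                formula = parse_formula(fbc_sp.getChemicalFormula())
            if fbc_sp.isSetCharge():
                charge = fbc_sp.getCharge()
        mets.append(
            Metabolite(
                id=_strip_sid(sp.getId(), "M_"),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
                formula=formula,
                charge=charge,
            )
        )
    model = MetabolicModel(sbml_model.getId() or "model")
    for met in mets:
        model.add_metabolite(met)
    fbc = sbml_model.getPlugin("fbc")
    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            key = _strip_sid(ref.getSpecies(), "M_")
            stoich[key] = stoich.get(key, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            key = _strip_sid(ref.getSpecies(), "M_")
            stoich[key] = stoich.get(key, 0.0) + ref.getStoichiometry()
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        fbc_r = sr.getPlugin("fbc")
        if fbc_r is not None and fbc_r.isSetLowerFluxBound():
            lb = sbml_model.getParameter(fbc_r.getLowerFluxBound()).getValue()
        if fbc_r is not None and fbc_r.isSetUpperFluxBound():
            ub = sbml_model.getParameter(fbc_r.getUpperFluxBound()).getValue()
        role = subsystem = gene_rule = None
        if sr.isSetNotes():
            notes = sr.getNotesString()
            role_m = re.search(r"role:\s*([A-Z_0-9]+)", notes)
            role = role_m.group(1) if role_m else None
            sub_m = re.search(r"subsystem:\s*([^<\n]+)", notes)
            subsystem = sub_m.group(1).strip() if sub_m else None
            gr_m = re.search(r"gene_rule:\s*([^<\n]+)", notes)
            gene_rule = gr_m.group(1).strip() if gr_m else None
        model.add_reaction(
            Reaction(
                id=_strip_sid(sr.getId(), "R_"),
                name=sr.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_rule=gene_rule,
                subsystem=subsystem,
                role=role,
            )
        )
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        for j in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(j)
            model.objective[_strip_sid(fo.getReaction(), "R_")] = fo.getCoefficient()
    model.validate()
    return model


def _save_sbml(model: MetabolicModel, path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    fbc = sm.getPlugin("fbc")
    fbc.setStrict(False)
    compartments = sorted({m.compartment for m in model.metabolites.values()} or {"c"})
    for comp in compartments:
        c = sm.createCompartment()
        c.setId(comp)
        c.setConstant(True)
    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(_sbml_sid("M_", met.id))
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        fbc_sp = sp.getPlugin("fbc")
        if met.formula is not None:
            fbc_sp.setChemicalFormula(format_formula(met.formula))
        if met.charge is not None:
            fbc_sp.setCharge(met.charge)
    bound_params: dict[float, str] = {}

    def bound_id(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        sr = sm.createReaction()
        sr.setId(_sbml_sid("R_", rxn.id))
        sr.setName(rxn.name)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        for met_id, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(_sbml_sid("M_", met_id))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        fbc_r = sr.getPlugin("fbc")
        fbc_r.setLowerFluxBound(bound_id(rxn.lower_bound))
        fbc_r.setUpperFluxBound(bound_id(rxn.upper_bound))
        note_lines = []
        if rxn.role:
            note_lines.append(f"role: {rxn.role}")
        if rxn.subsystem:
            note_lines.append(f"subsystem: {rxn.subsystem}")
        if rxn.gene_rule:
            note_lines.append(f"gene_rule: {rxn.gene_rule}")
        if note_lines:
            body = "".join(f"<p>{line}</p>" for line in note_lines)
            sr.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
            )
    if model.objective:
        obj = fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        for rxn_id, weight in model.objective.items():
            fo = obj.createFluxObjective()
            fo.setReaction(_sbml_sid("R_", rxn_id))
            fo.setCoefficient(weight)
        fbc.setActiveObjectiveId("obj")
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise ModelError(f"could not write SBML to {path}")


# ---------------------------------------------------------------------------
# pathway additions


#: Default id map for resolving species in foreign models.
DEFAULT_ID_MAP = {
    "glutamate": ("glu_c",),
    "co2": ("co2_c",),
    "gaba": ("4aba_c",),
    "accoa": ("accoa_c",),
    "coa": ("coa_c",),
}


def _resolve_species(model: MetabolicModel, key: str, id_map: Mapping | None) -> str:
    candidates = []
    if id_map and key in id_map:
        value = id_map[key]
        candidates = [value] if isinstance(value, str) else list(value)
    candidates += list(DEFAULT_ID_MAP.get(key, ()))
    for cand in candidates:
        if cand in model.metabolites:
            return cand
    raise ConfigurationError(
        f"cannot resolve species {key!r} in model {model.id!r}; "
        f"tried {candidates}; supply an id map"
    )


def add_gaba_pathway(model: MetabolicModel, id_map: Mapping | None = None) -> MetabolicModel:
    """Add the heterologous glutamate decarboxylase route and GABA export.

    Adds three reactions to a copy of ``model``: the reversible GAD reaction
    (glutamate -> GABA + CO2, one-step decarboxylation), a cytosol-to-medium
    GABA transport, and a GABA exchange tagged GABA_EXPORT.
    """
    if model.reactions_by_role("GAD"):
        raise ConfigurationError(f"model {model.id!r} already has a GAD reaction")
    new = model.copy()
    glu = _resolve_species(new, "glutamate", id_map)
    co2 = _resolve_species(new, "co2", id_map)
    gaba_c = "4aba_c"
    gaba_e = "4aba_e"
    if gaba_c not in new.metabolites:
        new.add_metabolite(
            Metabolite(gaba_c, "4-aminobutyrate", "c", parse_formula("C4H9NO2"))
        )
    if gaba_e not in new.metabolites:
        new.add_metabolite(
            Metabolite(gaba_e, "4-aminobutyrate (extracellular)", "e", parse_formula("C4H9NO2"))
        )
    new.add_reaction(
        Reaction(
            "GAD",
            {glu: -1.0, gaba_c: 1.0, co2: 1.0},
            name="glutamate decarboxylase (heterologous gad)",
            lower_bound=-DEFAULT_BOUND,
            upper_bound=DEFAULT_BOUND,
            role="GAD",
            subsystem="gaba",
        )
    )
    # transport and exchange are added only if the host model lacks them
    has_transport = any(
        r.stoichiometry.get(gaba_c, 0) < 0 and r.stoichiometry.get(gaba_e, 0) > 0
        for r in new.reactions.values()
    )
    if not has_transport:
        new.add_reaction(
            Reaction(
                "GABAt_out",
                {gaba_c: -1.0, gaba_e: 1.0},
                name="GABA export transport",
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
                subsystem="gaba",
            )
        )
    if not new.reactions_by_role("GABA_EXPORT"):
        new.add_reaction(
            Reaction(
                "EX_4aba_e",
                {gaba_e: -1.0},
                name="GABA exchange",
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
                role="GABA_EXPORT",
                subsystem="exchange",
            )
        )
    new.validate()
    return new


def add_butyrolactam_pathway(model: MetabolicModel, id_map: Mapping | None = None) -> MetabolicModel:
    """Add the acetyl-CoA-dependent butyrolactam branch (Act) and exchanges.

    The CoA transfer from acetyl-CoA to GABA and the subsequent spontaneous
    cyclization to butyrolactam are lumped into a single reaction (the acyl-CoA
    intermediate is not observed), so free CoA and acetate are released:
    GABA + acetyl-CoA -> butyrolactam + acetate + CoA.
    """
    if model.reactions_by_role("ACT"):
        raise ConfigurationError(f"model {model.id!r} already has an ACT reaction")
    new = model.copy()
    gaba = _resolve_species(new, "gaba", id_map)
    accoa = _resolve_species(new, "accoa", id_map)
    coa = _resolve_species(new, "coa", id_map)
    if "blm_c" not in new.metabolites:
        new.add_metabolite(
            Metabolite("blm_c", "butyrolactam (2-pyrrolidone)", "c", parse_formula("C4H7NO"))
        )
    if "ac_c" not in new.metabolites:
        new.add_metabolite(Metabolite("ac_c", "acetate", "c", parse_formula("C2H4O2")))
    new.add_reaction(
        Reaction(
            "ACT",
            {gaba: -1.0, accoa: -1.0, "blm_c": 1.0, "ac_c": 1.0, coa: 1.0},
            name="beta-alanine CoA transferase + spontaneous cyclization (lumped)",
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
            role="ACT",
            subsystem="butyrolactam",
        )
    )
    new.add_reaction(
        Reaction(
            "EX_blm_c",
            {"blm_c": -1.0},
            name="butyrolactam exchange",
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
            subsystem="exchange",
        )
    )
    if not any(
        r.is_exchange and "ac_c" in r.stoichiometry for r in new.reactions.values()
    ):
        new.add_reaction(
            Reaction(
                "EX_ac_c",
                {"ac_c": -1.0},
                name="acetate exchange",
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
                subsystem="exchange",
            )
        )
    new.validate()
    return new


# ---------------------------------------------------------------------------
# edits and medium


def apply_edits(model: MetabolicModel, edits: Iterable[ModelEdit]) -> MetabolicModel:
    """Apply an ordered edit list to a copy of ``model``; the input is untouched.

    Deletions fix bounds to (0, 0) rather than removing the reaction, so the
    reaction universe stays constant across a strain series.
    """
    new = model.copy()
    for edit in edits:
        edit.apply(new)
    new.validate()
    return new


def set_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Apply a :class:`MediumSpec` to a copy of ``model``.

    Fixed uptakes become equality bounds (-rate, -rate); free exchanges open
    to the default bounds in both directions; all remaining exchanges are
    closed to uptake (lower bound 0) unless listed in ``medium.keep``.
    """
    new = model.copy()
    known = {r.id for r in new.exchanges()}
    for rxn_id in list(medium.fixed_uptakes) + list(medium.free_exchanges) + list(medium.keep):
        if rxn_id not in known:
            raise ModelError(f"medium references unknown exchange {rxn_id!r}")
    for rxn in new.exchanges():
        if rxn.id in medium.fixed_uptakes:
            rate = medium.fixed_uptakes[rxn.id]
            rxn.lower_bound = -rate
            rxn.upper_bound = -rate
        elif rxn.id in medium.free_exchanges:
            rxn.lower_bound = -DEFAULT_BOUND
            rxn.upper_bound = DEFAULT_BOUND
        elif rxn.id in medium.keep:
            continue
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    return new


def check_mass_balance(model: MetabolicModel, tol: float = 1e-9) -> BalanceReport:
    """Report elemental imbalances of all non-exchange reactions.

    Reactions touching a metabolite without a formula are skipped and listed
    in the report (a biomass pseudo-metabolite is the usual case).
    """
    imbalanced: dict[str, dict[str, float]] = {}
    skipped: list[str] = []
    for rxn in model.reactions.values():
        if rxn.is_exchange:
            continue
        if any(model.metabolites[m].formula is None for m in rxn.stoichiometry):
            skipped.append(rxn.id)
            continue
        totals: dict[str, float] = {}
        for met_id, coef in rxn.stoichiometry.items():
            for element, count in model.metabolites[met_id].formula.items():
                totals[element] = totals.get(element, 0.0) + coef * count
        residual = {e: v for e, v in totals.items() if abs(v) > tol}
        if residual:
            imbalanced[rxn.id] = residual
    return BalanceReport(imbalanced=imbalanced, skipped=skipped)
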