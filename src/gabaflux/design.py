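"""Strain-design analytics: aconitase flux-multiplier scan, WT-vs-producer
delta maps, branch-point (node) accounting, the double-robustness surface
over growth x constrained TCA flux, and in-silico strain series.

Conventions: flux changes are normalized to the glucose uptake magnitude;
"overexpression" of a reaction is modeled as an equality constraint at a
multiple of its wild-type pFBA flux; infeasible scan or surface cells are
recorded (masked), never interpolated.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .fba import (
    REPORT_TOL,
    DegenerateConstraintError,
    FBAError,
    FluxState,
    ProductionConstraint,
    fva,
    maximize,
    pfba,
    production_fba,
)
from .metnet import MetabolicModel, Metabolite, ModelEdit, ModelError, Reaction, apply_edits
from .metnet import add_butyrolactam_pathway, add_gaba_pathway

__all__ = [
    "ScanSpec",
    "ScanResult",
    "DeltaMap",
    "RobustnessSurface",
    "StrainSpec",
    "ScanError",
    "acn_scan",
    "delta_map",
    "node_split",
    "export_share",
    "double_robustness",
    "strain_series",
    "load_strain_series",
    "packaged_strain_series",
]


class ScanError(ModelError):
    pass


@dataclass
class ScanSpec:
    """Multiplier scan specification (defaults follow the reference design)."""

    product_rxn: str
    multipliers: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0)
    biomass_fraction: float = 0.2
    reference: str = "wt_pfba"

    def __post_init__(self) -> None:
        mults = tuple(float(m) for m in self.multipliers)
        if any(m <= 0 for m in mults):
            raise ScanError("multipliers must be positive")
        if any(b >= a for a, b in zip(mults[1:], mults)):
            raise ScanError("multipliers must be strictly ascending")
        self.multipliers = mults


@dataclass
class ScanResult:
    spec: ScanSpec
    reference_state: FluxState
    states: dict[float, FluxState]
    delta_matrix: pd.DataFrame  # reactions x multipliers, uptake-normalized
    product_trace: dict[float, float | None]
    best_multiplier: float
    reference_flux: float


@dataclass
class DeltaMap:
    """Per-reaction normalized flux change with direction classification."""

    table: pd.DataFrame  # columns: wt_flux, alt_flux, delta_normalized, direction

    def direction(self, rxn_id: str) -> str:
        return str(self.table.loc[rxn_id, "direction"])


@dataclass
class RobustnessSurface:
    constrained_rxn: str
    growth_values: np.ndarray
    flux_values: np.ndarray
    objective_matrix: np.ndarray  # growth x flux; NaN where infeasible
    feasible_mask: np.ndarray
    max_value: float | None = None
    max_cell: tuple[float, float] | None = None

    @property
    def all_infeasible(self) -> bool:
        return not bool(self.feasible_mask.any())


@dataclass
class StrainSpec:
    label: str
    edits: list[ModelEdit] = field(default_factory=list)
    pathways: list[str] = field(default_factory=list)  # applied before edits
    product_rxn: str | None = None
    description: str = ""


def _uptake_rxn(model: MetabolicModel) -> str:
    return model.reaction_by_role("GLC_UPTAKE").id


def acn_scan(model: MetabolicModel, spec: ScanSpec, backend: str = "highs") -> ScanResult:
    """Scan producer behavior while fixing aconitase flux at multiples of WT.

    The reference flux v0 is the ACN flux of the wild-type pFBA solution with
    biomass as the objective, and the biomass floor is fixed once at
    biomass_fraction x mu* of the unconstrained model (the producer's
    theoretical growth maximum).  For each multiplier k, the ACN flux is fixed
    by equality at k*v0 under that floor, the product flux is maximized and
    pFBA-canonicalized, and the uptake-normalized flux changes against the
    wild type are recorded.  Infeasible cells are kept as gaps, not errors.
    """
    acn = model.reaction_by_role("ACN").id
    biomass = model.reaction_by_role("BIOMASS").id
    product = model.resolve(spec.product_rxn).id
    uptake = _uptake_rxn(model)
    wt = pfba(model, biomass, backend=backend)
    if not wt.optimal:
        raise ScanError(f"wild-type optimization is {wt.status}")
    v0 = wt.fluxes[acn]
    if abs(v0) <= REPORT_TOL:
        raise ScanError("wild-type ACN flux is zero; multiplier reference undefined")
    mu_star = wt.objective_value
    floor = spec.biomass_fraction * mu_star
    states: dict[float, FluxState] = {}
    trace: dict[float, float | None] = {}
    columns: dict[float, pd.Series] = {}
    uptake_mag = abs(wt.fluxes[uptake])
    for k in spec.multipliers:
        fixed = model.copy()
        fixed.reactions[acn].lower_bound = k * v0
        fixed.reactions[acn].upper_bound = k * v0
        fixed.reactions[biomass].lower_bound = max(
            fixed.reactions[biomass].lower_bound, floor
        )
        try:
            state = pfba(fixed, product, backend=backend)
            state.meta.update(mu_star=mu_star, biomass_floor=floor,
                              biomass_rxn=biomass, acn_multiplier=k)
        except (DegenerateConstraintError, FBAError):
            state = FluxState({}, None, "infeasible", {product: 1.0}, {})
        if not state.optimal:
            state = FluxState({}, None, state.status or "infeasible",
                              {product: 1.0}, {"acn_multiplier": k})
        states[k] = state
        if state.optimal:
            trace[k] = state.fluxes[product]
            norm = abs(state.fluxes[uptake]) or uptake_mag
            columns[k] = pd.Series(
                {r: (state.fluxes[r] - wt.fluxes[r]) / norm for r in wt.fluxes}
            )
        else:
            trace[k] = None
            columns[k] = pd.Series({r: np.nan for r in wt.fluxes})
    delta = pd.DataFrame(columns)[list(spec.multipliers)]
    feasible = [(k, v) for k, v in trace.items() if v is not None]
    if not feasible:
        raise ScanError("every scan cell is infeasible")
    best = max(feasible, key=lambda kv: (kv[1], -kv[0]))[0]
    return ScanResult(
        spec=spec,
        reference_state=wt,
        states=states,
        delta_matrix=delta,
        product_trace=trace,
        best_multiplier=best,
        reference_flux=v0,
    )


def delta_map(
    wt: FluxState,
    alt: FluxState,
    uptake_rxn: str,
    tol: float = REPORT_TOL,
) -> DeltaMap:
    """Compare two flux states reaction by reaction, normalized to uptake.

    Directions: ``reversed`` when both fluxes are nonzero with opposite signs,
    ``up``/``down`` for signed changes beyond tolerance, else ``unchanged``.
    """
    if not (wt.optimal and alt.optimal):
        raise FBAError("both states must be optimal")
    if set(wt.fluxes) != set(alt.fluxes):
        raise FBAError("flux states cover different reaction universes")
    uptake = abs(wt.fluxes[uptake_rxn])
    if uptake <= tol:
        raise FBAError(f"uptake flux of {uptake_rxn!r} is zero")
    records = []
    for rxn_id, w in wt.fluxes.items():
        a = alt.fluxes[rxn_id]
        delta = (a - w) / uptake
        if abs(w) > tol and abs(a) > tol and (w > 0) != (a > 0):
            direction = "reversed"
        elif delta > tol:
            direction = "up"
        elif delta < -tol:
            direction = "down"
        else:
            direction = "unchanged"
        records.append((rxn_id, w, a, delta, direction))
    table = pd.DataFrame.from_records(
        records,
        columns=["reaction", "wt_flux", "alt_flux", "delta_normalized", "direction"],
    ).set_index("reaction")
    return DeltaMap(table=table)


def node_split(
    state: FluxState,
    model: MetabolicModel,
    metabolite_id: str,
    tol: float = REPORT_TOL,
) -> dict[str, float]:
    """Fractions of a metabolite's total consumption carried by each reaction.

    Consumption is stoichiometry-weighted and direction-aware: a reaction
    consumes the metabolite when coefficient x flux < 0.  Fractions sum to 1.
    """
    if metabolite_id not in model.metabolites:
        raise ModelError(f"unknown metabolite {metabolite_id!r}")
    consumption: dict[str, float] = {}
    for rxn in model.reactions.values():
        coef = rxn.stoichiometry.get(metabolite_id)
        if coef is None:
            continue
        rate = coef * state.fluxes.get(rxn.id, 0.0)
        if rate < -tol:
            consumption[rxn.id] = -rate
    total = sum(consumption.values())
    if total <= tol:
        raise FBAError(
            f"metabolite {metabolite_id!r} has no consumption in this state"
        )
    return {r: v / total for r, v in consumption.items()}


def export_share(
    state: FluxState,
    model: MetabolicModel,
    metabolite_id: str,
    product_rxn: str,
    tol: float = REPORT_TOL,
) -> float:
    """Alternative node accounting: exported product flux over node turnover.

    Complements :func:`node_split` (fraction of direct node outflow) with the
    fraction of the node's total consumption that ultimately leaves as product.
    """
    total = 0.0
    for rxn in model.reactions.values():
        coef = rxn.stoichiometry.get(metabolite_id)
        if coef is None:
            continue
        rate = coef * state.fluxes.get(rxn.id, 0.0)
        if rate < -tol:
            total += -rate
    if total <= tol:
        raise FBAError(
            f"metabolite {metabolite_id!r} has no consumption in this state"
        )
    return state.fluxes[model.resolve(product_rxn).id] / total


def double_robustness(
    model: MetabolicModel,
    constrained_rxn: str,
    product_rxn: str,
    growth_values: Sequence[float] | None = None,
    flux_values: Sequence[float] | None = None,
    grid: int = 21,
    mode: str = "equality",
    backend: str = "highs",
) -> RobustnessSurface:
    """Optimal product flux over a (growth x constrained flux) grid.

    Per cell, the biomass flux and the constrained reaction flux are fixed
    (equality by default, upper bound with ``mode='bound'``) and the product
    flux is maximized.  Defaults: ``grid`` evenly spaced growth values in
    [0, mu*] and flux values in [0, FVA max at zero objective fraction].
    """
    if mode not in ("equality", "bound"):
        raise ValueError(f"unknown robustness mode {mode!r}")
    biomass = model.reaction_by_role("BIOMASS").id
    rxn = model.resolve(constrained_rxn).id
    product = model.resolve(product_rxn).id
    if growth_values is None:
        mu = maximize(model, biomass, backend=backend)
        if not mu.optimal:
            raise FBAError(f"growth optimization is {mu.status}")
        growth_values = np.linspace(0.0, mu.objective_value, grid)
    if flux_values is None:
        bracket = fva(model, [rxn], objective_fraction=0.0,
                      objective=biomass, backend=backend)
        flux_values = np.linspace(0.0, bracket[rxn][1], grid)
    growth_values = np.asarray(list(growth_values), dtype=float)
    flux_values = np.asarray(list(flux_values), dtype=float)
    if growth_values.size == 0 or flux_values.size == 0:
        raise ValueError("grids must be non-empty")
    objective = np.full((growth_values.size, flux_values.size), np.nan)
    mask = np.zeros_like(objective, dtype=bool)
    for i, mu_val in enumerate(growth_values):
        for j, f_val in enumerate(flux_values):
            cell = model.copy()
            cell.reactions[biomass].lower_bound = mu_val
            cell.reactions[biomass].upper_bound = mu_val
            lo = f_val if mode == "equality" else cell.reactions[rxn].lower_bound
            cell.reactions[rxn].lower_bound = min(lo, f_val)
            cell.reactions[rxn].upper_bound = f_val
            state = maximize(cell, product, backend=backend)
            if state.optimal:
                objective[i, j] = state.objective_value
                mask[i, j] = True
    surface = RobustnessSurface(
        constrained_rxn=rxn,
        growth_values=growth_values,
        flux_values=flux_values,
        objective_matrix=objective,
        feasible_mask=mask,
    )
    if mask.any():
        flat = np.where(mask.ravel(), objective.ravel(), -np.inf)
        idx = int(np.argmax(flat))
        i, j = divmod(idx, flux_values.size)
        surface.max_value = float(objective[i, j])
        surface.max_cell = (float(growth_values[i]), float(flux_values[j]))
    return surface


# ---------------------------------------------------------------------------
# strain series


_PATHWAY_BUILDERS = {
    "gaba": add_gaba_pathway,
    "butyrolactam": add_butyrolactam_pathway,
}


def _resolve_pseudo_edit(entry: Mapping, model: MetabolicModel, wt: FluxState) -> ModelEdit:
    """Translate a YAML pseudo-op into a concrete :class:`ModelEdit`."""
    op = entry["op"]
    key = entry.get("reaction") or (f"role:{entry['role']}" if "role" in entry else None)
    label = entry.get("label", op)
    if op == "delete":
        return ModelEdit("delete_reaction", key, label)
    if op == "close":
        return ModelEdit("set_bounds", (key, 0.0, 0.0), label)
    if op == "open":
        return ModelEdit(
            "set_bounds",
            (key, float(entry.get("lower", 0.0)), float(entry.get("upper", 1000.0))),
            label,
        )
    if op == "set_bounds":
        return ModelEdit("set_bounds", (key, float(entry["lower"]), float(entry["upper"])), label)
    if op == "scale_bounds":
        return ModelEdit("scale_bounds", (key, float(entry["factor"])), label)
    if op == "overexpress":
        factor = float(entry.get("factor", 2.0))
        rxn = model.resolve(key)
        v0 = wt.fluxes[rxn.id]
        if abs(v0) <= REPORT_TOL:
            raise ScanError(
                f"cannot overexpress {rxn.id!r}: wild-type reference flux is zero"
            )
        return ModelEdit("set_bounds", (rxn.id, factor * v0, factor * v0), label)
    raise ModelError(f"unknown strain edit op {op!r}")


def load_strain_series(source) -> list[dict]:
    """Load a YAML strain-series document (list of labeled edit scripts)."""
    if isinstance(source, str) and "\n" not in source:
        with open(source) as handle:
            data = yaml.safe_load(handle)
    elif hasattr(source, "read") or isinstance(source, str):
        data = yaml.safe_load(source)
    else:  # pathlib.Path and friends
        with open(source) as handle:
            data = yaml.safe_load(handle)
    strains = data["strains"] if isinstance(data, Mapping) else data
    labels = [s["label"] for s in strains]
    if len(labels) != len(set(labels)):
        raise ModelError("strain labels must be unique in a series")
    return strains


def packaged_strain_series() -> list[dict]:
    """The packaged GABA-1..6 / BLM-1..3 strain analogs."""
    ref = importlib.resources.files("gabaflux.data").joinpath("strains_gaba_blm.yaml")
    return load_strain_series(ref.read_text())


def strain_series(
    base_model: MetabolicModel,
    series: Iterable[Mapping | StrainSpec],
    constraint: ProductionConstraint,
    backend: str = "highs",
) -> pd.DataFrame:
    """Evaluate a strain series: growth maximum and producer product flux.

    Each strain's pathway additions and edits are applied to a fresh copy of
    ``base_model``; per-strain failures are recorded in the ``status`` column
    and the series continues.  Overexpression pseudo-ops are resolved against
    the wild-type pFBA flux of the base model.
    """
    biomass = base_model.reaction_by_role("BIOMASS").id
    wt = pfba(base_model, biomass, backend=backend)
    rows = []
    for item in series:
        if isinstance(item, StrainSpec):
            label = item.label
            pathways = list(item.pathways)
            raw_edits: list = list(item.edits)
            product = item.product_rxn or constraint.product_rxn
        else:
            label = item["label"]
            pathways = list(item.get("pathways", []))
            raw_edits = list(item.get("edits", []))
            product = item.get("product_rxn", constraint.product_rxn)
        try:
            strain = base_model
            for pathway in pathways:
                strain = _PATHWAY_BUILDERS[pathway](strain)
            edits = [
                e if isinstance(e, ModelEdit) else _resolve_pseudo_edit(e, strain, wt)
                for e in raw_edits
            ]
            strain = apply_edits(strain, edits)
            growth = maximize(strain, biomass, backend=backend)
            growth_max = growth.objective_value if growth.optimal else np.nan
            state = production_fba(
                strain,
                ProductionConstraint(product_rxn=product,
                                     biomass_fraction=constraint.biomass_fraction),
                backend=backend,
            )
            product_flux = state.fluxes[strain.resolve(product).id] if state.optimal else np.nan
            status = state.status
        except (ModelError, FBAError) as exc:
            growth_max, product_flux, status = np.nan, np.nan, f"error: {exc}"
        rows.append(
            {
                "label": label,
                "growth_max": growth_max,
                "product_flux": product_flux,
                "status": status,
            }
        )
    return pd.DataFrame(rows, columns=["label", "growth_max", "product_flux", "status"])
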