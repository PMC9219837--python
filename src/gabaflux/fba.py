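"""Flux balance analysis: plain FBA, parsimonious canonicalization, flux
variability, producer-mode optimization under a biomass floor, and derived
quantities (uptake-normalized fluxes, theoretical yields).

All reported flux distributions should come from :func:`pfba`, which minimizes
total absolute flux at the optimum and therefore does not depend on which
optimal vertex a particular solver happens to return.  :func:`maximize` is the
raw LP and is flagged non-canonical in its metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import lp as _lp
from .metnet import MetabolicModel, ModelError

__all__ = [
    "FluxState",
    "FVAResult",
    "ProductionConstraint",
    "FBAError",
    "DegenerateConstraintError",
    "NormalizationError",
    "maximize",
    "pfba",
    "production_fba",
    "fva",
    "normalize_to_uptake",
    "theoretical_max_yield",
    "FEASIBILITY_TOL",
    "REPORT_TOL",
]

#: Solver feasibility tolerance.
FEASIBILITY_TOL = 1e-9
#: Reporting / assertion tolerance.
REPORT_TOL = 1e-6


class FBAError(ModelError):
    pass


class DegenerateConstraintError(FBAError):
    """Biomass floor requested on a model whose maximum growth is zero."""


class NormalizationError(FBAError):
    """Normalization requested against a zero uptake flux."""


@dataclass
class FluxState:
    """One steady-state flux solution."""

    fluxes: dict[str, float]
    objective_value: float | None
    status: str  # optimal | infeasible | unbounded
    objective: dict[str, float]
    meta: dict = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class FVAResult:
    """Per-reaction flux ranges at a stated objective fraction."""

    ranges: dict[str, tuple[float, float]]
    objective_fraction: float
    objective_value: float

    def __getitem__(self, rxn_id: str) -> tuple[float, float]:
        return self.ranges[rxn_id]


@dataclass
class ProductionConstraint:
    """Producer formulation: growth floor as a fraction of maximal growth."""

    product_rxn: str
    biomass_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.biomass_fraction <= 1.0:
            raise FBAError(
                f"biomass_fraction must be in [0, 1], got {self.biomass_fraction}"
            )


def _objective_vector(model: MetabolicModel, objective, rxn_ids: Sequence[str]) -> tuple[np.ndarray, dict[str, float]]:
    if objective is None:
        weights = dict(model.objective)
    elif isinstance(objective, str):
        weights = {model.resolve(objective).id: 1.0}
    else:
        weights = {model.resolve(k).id: float(v) for k, v in dict(objective).items()}
    if not weights:
        raise FBAError("no objective given and model has none")
    index = {r: j for j, r in enumerate(rxn_ids)}
    c = np.zeros(len(rxn_ids))
    for rxn_id, w in weights.items():
        c[index[rxn_id]] = w
    return c, weights


def _base_problem(model: MetabolicModel):
    S, _met_ids, rxn_ids = model.stoichiometric_matrix()
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    return S, rxn_ids, lb, ub


def _make_state(model, rxn_ids, x, obj, weights, **meta) -> FluxState:
    fluxes = {r: float(v) for r, v in zip(rxn_ids, x)}
    return FluxState(
        fluxes=fluxes,
        objective_value=float(obj),
        status="optimal",
        objective=weights,
        meta={"feasibility_tol": FEASIBILITY_TOL, **meta},
    )


def maximize(model: MetabolicModel, objective=None, backend: str = "highs") -> FluxState:
    """Maximize ``c.v`` subject to S.v = 0 and the model's flux bounds.

    ``objective`` may be a reaction id, ``role:NAME``, a weight map, or None
    (use the model's own objective).  Infeasible and unbounded problems are
    reported through ``status``, never as silent zeros.
    """
    S, rxn_ids, lb, ub = _base_problem(model)
    c, weights = _objective_vector(model, objective, rxn_ids)
    status, x, obj = _lp.solve(
        _lp.LinearProgram(c=c, A_eq=S, b_eq=np.zeros(S.shape[0]), lb=lb, ub=ub),
        backend=backend,
        tol=FEASIBILITY_TOL,
    )
    if status != "optimal":
        return FluxState({}, None, status, weights, {"backend": backend})
    return _make_state(model, rxn_ids, x, obj, weights, backend=backend, canonical=False)


def pfba(
    model: MetabolicModel,
    objective=None,
    objective_fraction: float = 1.0,
    backend: str = "highs",
) -> FluxState:
    """Parsimonious FBA: minimize total absolute flux at (near-)optimality.

    Returns the flux vector minimizing sum(|v|) subject to
    c.v >= objective_fraction x (LP maximum); ``objective_value`` reports c.v.
    """
    first = maximize(model, objective, backend=backend)
    if not first.optimal:
        return first
    S, rxn_ids, lb, ub = _base_problem(model)
    c, weights = _objective_vector(model, objective, rxn_ids)
    n = len(rxn_ids)
    # variables [v, t]; minimize sum t with t >= v, t >= -v, c.v >= f*opt
    zeros = np.zeros((S.shape[0], n))
    A_eq = np.hstack([S, zeros])
    b_eq = np.zeros(S.shape[0])
    eye = np.eye(n)
    A_ub = np.vstack(
        [
            np.hstack([eye, -eye]),       # v - t <= 0
            np.hstack([-eye, -eye]),      # -v - t <= 0
            np.hstack([-c, np.zeros(n)])[None, :],  # -c.v <= -f*opt
        ]
    )
    target = objective_fraction * first.objective_value
    b_ub = np.concatenate([np.zeros(2 * n), [-target + abs(target) * 1e-12]])
    obj_vec = np.concatenate([np.zeros(n), -np.ones(n)])  # maximize -sum t
    big = np.maximum(np.abs(lb), np.abs(ub))
    lp_ext = _lp.LinearProgram(
        c=obj_vec,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        lb=np.concatenate([lb, np.zeros(n)]),
        ub=np.concatenate([ub, big]),
    )
    status, x, _ = _lp.solve(lp_ext, backend=backend, tol=FEASIBILITY_TOL)
    if status != "optimal":  # numerically possible at fraction 1.0; retry slack
        b_ub[-1] = -target + max(abs(target), 1.0) * 1e-9
        status, x, _ = _lp.solve(lp_ext, backend=backend, tol=FEASIBILITY_TOL)
    if status != "optimal":
        raise FBAError(f"pfba restriction unexpectedly {status}")
    v = x[:n]
    return _make_state(
        model,
        rxn_ids,
        v,
        float(c @ v),
        weights,
        backend=backend,
        canonical=True,
        objective_fraction=objective_fraction,
        total_flux=float(np.sum(np.abs(v))),
    )


def production_fba(
    model: MetabolicModel,
    constraint: ProductionConstraint,
    backend: str = "highs",
) -> FluxState:
    """Producer formulation: maximize product flux under a biomass floor.

    Computes the maximal growth rate mu*, imposes
    biomass >= biomass_fraction x mu* as a lower bound on the biomass
    reaction, maximizes the product flux and returns the pFBA-canonicalized
    state.  ``meta`` records mu* and the applied floor.
    """
    biomass = model.reaction_by_role("BIOMASS")
    product = model.resolve(constraint.product_rxn)
    growth = maximize(model, biomass.id, backend=backend)
    if not growth.optimal:
        return FluxState({}, None, growth.status, {product.id: 1.0}, {"backend": backend})
    mu_star = growth.objective_value
    if mu_star <= REPORT_TOL and constraint.biomass_fraction > 0:
        raise DegenerateConstraintError(
            f"maximal growth is {mu_star:.3g}; a biomass floor of "
            f"{constraint.biomass_fraction} is degenerate"
        )
    floored = model.copy()
    floor = constraint.biomass_fraction * mu_star
    floored.reactions[biomass.id].lower_bound = floor
    state = pfba(floored, product.id, backend=backend)
    state.meta.update(mu_star=mu_star, biomass_floor=floor, biomass_rxn=biomass.id)
    return state


def fva(
    model: MetabolicModel,
    reactions: Sequence[str] | None = None,
    objective_fraction: float = 1.0,
    objective=None,
    backend: str = "highs",
) -> FVAResult:
    """Flux variability analysis at a stated objective fraction.

    For each reaction, the minimal and maximal flux subject to
    c.v >= objective_fraction x optimum; brackets alternate optima.
    """
    first = maximize(model, objective, backend=backend)
    if not first.optimal:
        raise FBAError(f"FVA reference optimization is {first.status}")
    S, rxn_ids, lb, ub = _base_problem(model)
    c, _ = _objective_vector(model, objective, rxn_ids)
    target = objective_fraction * first.objective_value
    A_ub = (-c)[None, :]
    b_ub = np.array([-target + max(abs(target), 1.0) * 1e-9])
    index = {r: j for j, r in enumerate(rxn_ids)}
    which = list(rxn_ids) if reactions is None else [model.resolve(r).id for r in reactions]
    ranges: dict[str, tuple[float, float]] = {}
    for rxn_id in which:
        e = np.zeros(len(rxn_ids))
        e[index[rxn_id]] = 1.0
        lo_hi = []
        for sign in (-1.0, 1.0):
            status, x, obj = _lp.solve(
                _lp.LinearProgram(
                    c=sign * e, A_eq=S, b_eq=np.zeros(S.shape[0]),
                    A_ub=A_ub, b_ub=b_ub, lb=lb, ub=ub,
                ),
                backend=backend,
                tol=FEASIBILITY_TOL,
            )
            if status != "optimal":
                raise FBAError(f"FVA subproblem for {rxn_id!r} is {status}")
            lo_hi.append(sign * obj)
        lo, hi = min(lo_hi), max(lo_hi)
        ranges[rxn_id] = (lo, hi)
    return FVAResult(ranges=ranges, objective_fraction=objective_fraction,
                     objective_value=first.objective_value)


def normalize_to_uptake(state: FluxState, uptake_rxn: str) -> dict[str, float]:
    """Divide every flux by the magnitude of the uptake flux.

    The uptake reaction itself maps to 1.0 exactly.
    """
    if not state.optimal:
        raise FBAError("cannot normalize a non-optimal state")
    uptake = abs(state.fluxes[uptake_rxn])
    if uptake <= REPORT_TOL:
        raise NormalizationError(f"uptake flux of {uptake_rxn!r} is zero")
    out = {r: v / uptake for r, v in state.fluxes.items()}
    # the uptake rate is reported as a positive magnitude, self-normalized to 1
    out[uptake_rxn] = 1.0
    return out


def theoretical_max_yield(
    model: MetabolicModel,
    product_rxn: str,
    substrate_rxn: str,
    backend: str = "highs",
) -> float:
    """Maximal mol product per mol substrate with no growth requirement.

    The biomass lower bound (if any) is relaxed to 0 and the product flux is
    maximized; the yield is product flux / |substrate uptake flux|.
    """
    relaxed = model.copy()
    for rxn in relaxed.reactions_by_role("BIOMASS"):
        rxn.lower_bound = min(rxn.lower_bound, 0.0)
    product = relaxed.resolve(product_rxn).id
    substrate = relaxed.resolve(substrate_rxn).id
    state = maximize(relaxed, product, backend=backend)
    if not state.optimal:
        raise FBAError(f"yield optimization is {state.status}")
    uptake = abs(state.fluxes[substrate])
    if uptake <= REPORT_TOL:
        raise NormalizationError(f"substrate flux of {substrate!r} is zero")
    return state.objective_value / uptake
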