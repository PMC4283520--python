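"""Linear-programming engine: FBA, flux variability, theoretical maxima,
and the worst-case (minimum-product) inner problem of the two-step design.

All solves go through :func:`scipy.optimize.linprog` (HiGHS), wrapped so
callers work with reaction ids rather than matrix columns.  Every result
carries the dual objective reconstructed from the solver's marginals, so
strong duality can be asserted wherever a max-min value is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .errors import InfeasibleError, UnboundedError, ValidationError
from .network import Condition, MetabolicNetwork, ReactionPartition, apply_condition

__all__ = [
    "FluxRange",
    "LinearConstraintSet",
    "FBAResult",
    "fba",
    "flux_range",
    "theoretical_max",
    "worst_case_product",
]

FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-8


@dataclass(frozen=True)
class FluxRange:
    reaction_id: str
    vmin: float
    vmax: float
    constraint_tag: str = ""


@dataclass
class LinearConstraintSet:
    """Extra constraints layered on top of the network's own bounds.

    * ``fixed_fluxes``: reaction -> value (lb = ub = value);
    * ``bounds``: reaction -> (lb, ub) overriding the declared bounds;
    * ``rows``: (coefficients, sense, rhs) with sense in {"<=", ">=", "=="}.
    """

    fixed_fluxes: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    rows: list[tuple[dict[str, float], str, float]] = field(default_factory=list)

    def merged(self, other: "LinearConstraintSet | None") -> "LinearConstraintSet":
        if other is None:
            return self
        return LinearConstraintSet(
            fixed_fluxes={**self.fixed_fluxes, **other.fixed_fluxes},
            bounds={**self.bounds, **other.bounds},
            rows=[*self.rows, *other.rows],
        )


@dataclass
class FBAResult:
    status: str  # optimal | infeasible | unbounded
    objective: float | None
    fluxes: dict[str, float]
    dual_objective: float | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _effective_bounds(
    network: MetabolicNetwork, extra: LinearConstraintSet | None
) -> list[tuple[float, float]]:
    bounds = []
    for r in network.reactions:
        lb, ub = r.lb, r.ub
        if extra:
            if r.id in extra.bounds:
                lb, ub = extra.bounds[r.id]
            if r.id in extra.fixed_fluxes:
                lb = ub = extra.fixed_fluxes[r.id]
        if lb > ub + FEASIBILITY_TOL:
            raise ValidationError(f"empty flux interval for {r.id}: [{lb}, {ub}]")
        bounds.append((lb, min(ub, max(lb, ub))))
    return bounds


def _solve(
    network: MetabolicNetwork,
    c: np.ndarray,
    extra: LinearConstraintSet | None,
) -> FBAResult:
    """Minimize c.v subject to S v = 0, bounds, and extra rows."""
    S, _met_idx, rxn_idx = network.stoichiometric_matrix()
    n = len(network.reactions)
    A_eq = [S] if S.size else []
    b_eq = [np.zeros(S.shape[0])] if S.size else []
    A_ub_rows, b_ub = [], []
    if extra:
        for coeffs, sense, rhs in extra.rows:
            row = np.zeros(n)
            for rid, coef in coeffs.items():
                if rid not in rxn_idx:
                    raise ValidationError(f"constraint row references unknown {rid!r}")
                row[rxn_idx[rid]] = coef
            if sense == "==":
                A_eq.append(row[None, :])
                b_eq.append(np.array([rhs]))
            elif sense == "<=":
                A_ub_rows.append(row)
                b_ub.append(rhs)
            elif sense == ">=":
                A_ub_rows.append(-row)
                b_ub.append(-rhs)
            else:
                raise ValidationError(f"unknown constraint sense {sense!r}")
    A_eq_m = np.vstack(A_eq) if A_eq else None
    b_eq_v = np.concatenate(b_eq) if b_eq else None
    A_ub_m = np.vstack(A_ub_rows) if A_ub_rows else None
    b_ub_v = np.array(b_ub) if b_ub else None
    bounds = _effective_bounds(network, extra)

    res = linprog(
        c,
        A_ub=A_ub_m,
        b_ub=b_ub_v,
        A_eq=A_eq_m,
        b_eq=b_eq_v,
        bounds=bounds,
        method="highs",
    )
    if res.status == 2:
        return FBAResult(status="infeasible", objective=None, fluxes={})
    if res.status == 3:
        return FBAResult(status="unbounded", objective=None, fluxes={})
    if res.status != 0:  # pragma: no cover
        raise ValidationError(f"LP solver failure: {res.message}")

    fluxes = {r.id: float(res.x[rxn_idx[r.id]]) for r in network.reactions}
    dual = None
    if res.eqlin is not None:
        dual = 0.0
        if b_eq_v is not None and len(b_eq_v):
            dual += float(b_eq_v @ res.eqlin.marginals)
        if b_ub_v is not None and len(b_ub_v):
            dual += float(b_ub_v @ res.ineqlin.marginals)
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        lm = np.asarray(res.lower.marginals)
        um = np.asarray(res.upper.marginals)
        dual += float(np.sum(np.where(lm != 0.0, lo * lm, 0.0)))
        dual += float(np.sum(np.where(um != 0.0, hi * um, 0.0)))
    return FBAResult(
        status="optimal",
        objective=float(res.fun),
        fluxes=fluxes,
        dual_objective=dual,
    )


def fba(
    network: MetabolicNetwork,
    objective_id: str,
    sense: str = "max",
    extra: LinearConstraintSet | None = None,
) -> FBAResult:
    """Flux balance analysis: optimize one reaction's flux.

    The returned ``objective`` is on the caller's scale (a maximization
    reports the maximum, not its negation); ``dual_objective`` likewise.
    """
    if not network.has_reaction(objective_id):
        raise ValidationError(f"objective reaction {objective_id!r} not in network")
    if sense not in ("max", "min"):
        raise ValidationError(f"sense must be max|min, got {sense!r}")
    _, _, rxn_idx = network.stoichiometric_matrix()
    c = np.zeros(len(network.reactions))
    c[rxn_idx[objective_id]] = -1.0 if sense == "max" else 1.0
    res = _solve(network, c, extra)
    if res.optimal:
        flip = -1.0 if sense == "max" else 1.0
        res.objective = flip * res.objective
        if res.dual_objective is not None:
            res.dual_objective = flip * res.dual_objective
    return res


def flux_range(
    network: MetabolicNetwork,
    reaction_id: str,
    extra: LinearConstraintSet | None = None,
    tag: str = "",
) -> FluxRange:
    """Min and max attainable flux of one reaction (FVA primitive)."""
    lo = fba(network, reaction_id, "min", extra)
    hi = fba(network, reaction_id, "max", extra)
    for r, what in ((lo, "min"), (hi, "max")):
        if r.status == "infeasible":
            raise InfeasibleError(f"flux_range({reaction_id}, {what}): infeasible")
        if r.status == "unbounded":
            raise UnboundedError(f"flux_range({reaction_id}, {what}): unbounded")
    return FluxRange(reaction_id=reaction_id, vmin=lo.objective, vmax=hi.objective, constraint_tag=tag)


def theoretical_max(
    network: MetabolicNetwork, condition: Condition, target: str = "product"
) -> float:
    """FBA maximum of the product (or biomass) flux under condition bounds only."""
    rid = condition.product_id if target == "product" else condition.biomass_id
    if rid is None:
        raise ValidationError(f"condition does not declare a {target} reaction")
    net = apply_condition(network, condition)
    res = fba(net, rid, "max")
    if res.status == "infeasible":
        raise InfeasibleError(f"theoretical_max({target}): condition infeasible")
    if res.status == "unbounded":
        raise UnboundedError(f"theoretical_max({target}): unbounded")
    return res.objective


def worst_case_product(
    network: MetabolicNetwork,
    part: ReactionPartition,
    fixed_kinetic_fluxes: dict[str, float],
    interventions: LinearConstraintSet | None,
    condition: Condition,
    biomass_floor: float | None = None,
) -> FBAResult:
    """Minimum product flux over the stoichiometric degrees of freedom.

    The kinetic fluxes are fixed at the supplied values; intervention
    bounds and the biomass floor (default: min_biomass_fraction of the
    biomass theoretical maximum) constrain the completion.  This is the
    inner problem of the worst-case design step.
    """
    unknown = sorted(set(fixed_kinetic_fluxes) - part.kinetic_ids)
    if unknown:
        raise ValidationError(f"fixed kinetic fluxes outside J_kin: {unknown}")
    net = apply_condition(network, condition)
    extra = LinearConstraintSet(fixed_fluxes=dict(fixed_kinetic_fluxes))
    if biomass_floor is None and condition.biomass_id is not None:
        biomass_floor = condition.min_biomass_fraction * theoretical_max(
            network, condition, "biomass"
        )
    if biomass_floor is not None:
        extra.rows.append(({condition.biomass_id: 1.0}, ">=", biomass_floor))
    extra = extra.merged(interventions)
    return fba(net, condition.product_id, "min", extra)
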