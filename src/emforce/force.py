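"""Two-step FORCE intervention design over a hybrid kinetic/stoichiometric model.

Step 1 chooses up to ``kappa`` enzyme-level interventions inside the
kinetic subnetwork: for each candidate subset of MUST reactions it solves
a steady-state-constrained nonlinear program over total-enzyme multipliers
e_tot (bounded by the piecewise selection equations in
:func:`etot_bounds`), metabolite concentrations (within a configurable
fold of reference, default 5) and enzyme-state amounts, maximizing the
product flux subject to a biomass floor.  Step 2 fixes the kinetic fluxes
of the step-1 optimum and chooses flux-bound manipulations among the
stoichiometric MUST reactions, maximizing the *worst-case* product flux —
the inner minimization over the remaining stoichiometric degrees of
freedom — with strong duality verified on the reported value.

At desk scale the default solver strategy is exhaustive subset enumeration
with multistart SLSQP for the continuous inner problem; an independent
simulation-based oracle (:func:`enumerate_oracle`, dense e_tot grids
refined by direct search, steady states obtained by ODE relaxation) is
exposed to validate the optimizer on small instances and to quantify the
cost of the two-step split.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .ensemble import EnsembleModel
from .errors import EmforceError, InfeasibleError, ValidationError
from .kinetics import KineticParameterization
from .lp import LinearConstraintSet, theoretical_max, worst_case_product
from .must import MustSets
from .network import Condition

__all__ = [
    "ForceConfig",
    "KineticIntervention",
    "StoichIntervention",
    "DesignResult",
    "etot_bounds",
    "force_step1",
    "force_step2",
    "escalate",
    "enumerate_oracle",
]


@dataclass(frozen=True)
class ForceConfig:
    kappa: int = 3  # maximum intervention budget explored by escalate
    z: float = 10.0  # maximum fold-change of e_tot
    concentration_fold: float = 5.0  # allowed range of concentrations around reference
    stop_rel_improvement: float = 0.01
    solver_strategy: str = "enumerate"
    grid_points: int = 9  # oracle e_tot grid density per dimension
    multistart: int = 3  # SLSQP starts per e_tot dimension

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValidationError("kappa must be >= 0")
        if self.z <= 1:
            raise ValidationError("z must exceed 1")
        if self.concentration_fold <= 1:
            raise ValidationError("concentration_fold must exceed 1")


@dataclass(frozen=True)
class KineticIntervention:
    reaction_id: str
    direction: str  # up | down
    e_tot: float
    bounds: tuple[float, float]

    def __post_init__(self) -> None:
        lb, ub = self.bounds
        if not (lb - 1e-9 <= self.e_tot <= ub + 1e-9):
            raise ValidationError(
                f"{self.reaction_id}: e_tot {self.e_tot} outside [{lb}, {ub}]"
            )


@dataclass(frozen=True)
class StoichIntervention:
    reaction_id: str
    direction: str  # up | down
    bounds: tuple[float, float]


@dataclass
class Step1Result:
    interventions: list[KineticIntervention]
    achieved_flux: float
    kinetic_fluxes: dict[str, float]
    concentrations: dict[str, float]
    biomass_flux: float
    method: str = "slsqp-enumerate"


@dataclass
class DesignResult:
    kappa: int
    kinetic_interventions: list[KineticIntervention]
    stoich_interventions: list[StoichIntervention]
    achieved_flux: float
    worst_case_flux: float
    biomass_flux: float
    yield_mol_per_mol: float
    concentrations: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "kinetic_interventions": [
                {
                    "reaction_id": k.reaction_id,
                    "direction": k.direction,
                    "e_tot": k.e_tot,
                    "bounds": list(k.bounds),
                }
                for k in self.kinetic_interventions
            ],
            "stoich_interventions": [
                {
                    "reaction_id": s.reaction_id,
                    "direction": s.direction,
                    "bounds": list(s.bounds),
                }
                for s in self.stoich_interventions
            ],
            "achieved_flux": self.achieved_flux,
            "worst_case_flux": self.worst_case_flux,
            "biomass_flux": self.biomass_flux,
            "yield_mol_per_mol": self.yield_mol_per_mol,
        }


def etot_bounds(
    reaction_id: str, y: int, z: float, must: MustSets
) -> tuple[float, float]:
    """Bounds on the total-enzyme multiplier under selection variable y.

    lb = 1 unless the reaction is in MUST^L, where lb = 1 - y (selection
    opens the range down to removal at 0); ub = 1 unless in MUST^U, where
    ub = (z - 1) y + 1 (selection opens the range up to a z-fold
    overexpression).  A reaction in neither set cannot be selected.
    """
    if y not in (0, 1):
        raise ValidationError("y must be 0 or 1")
    if z <= 1:
        raise ValidationError("z must exceed 1")
    in_l = reaction_id in must.must_l
    in_u = reaction_id in must.must_u
    if y == 1 and not (in_l or in_u):
        raise ValidationError(
            f"{reaction_id}: selected for intervention but in neither MUST set"
        )
    lb = (1 - y) if in_l else 1.0
    ub = ((z - 1) * y + 1) if in_u else 1.0
    return (float(lb), float(ub))


def _direction(rid: str, must: MustSets) -> str:
    return "up" if rid in must.must_u else "down"


# ----------------------------------------------------------------------------
# step 1: kinetic interventions via steady-state-constrained NLP


class _Step1NLP:
    """Simultaneous NLP for one candidate subset of kinetic reactions.

    Decision variables: dynamic metabolite concentrations, all enzyme-state
    amounts of every kinetic reaction, and e_tot for the selected
    reactions.  Steady state is imposed as equality constraints on the
    mass-action right-hand side; total enzyme of each reaction must equal
    its e_tot (fixed at the reference level for unselected reactions).
    """

    def __init__(
        self,
        model: EnsembleModel,
        param: KineticParameterization,
        subset: tuple[str, ...],
        must: MustSets,
        condition: Condition,
        config: ForceConfig,
        biomass_floor: float,
    ):
        self.model = model
        self.sys = model.system
        self.param = param
        self.subset = subset
        self.condition = condition
        self.config = config
        self.biomass_floor = biomass_floor
        self.n_conc = len(self.sys.dynamic_mets)
        self.kin_ids = self.sys.kin_ids
        self.frac_slices: dict[str, slice] = {}
        pos = self.n_conc
        for rid in self.kin_ids:
            n = len(param[rid].mechanism.states)
            self.frac_slices[rid] = slice(pos, pos + n)
            pos += n
        self.etot_pos = {rid: pos + i for i, rid in enumerate(subset)}
        self.n_var = pos + len(subset)
        self.etot_bounds = {
            rid: etot_bounds(rid, 1, config.z, must) for rid in subset
        }

    # mapping between NLP variables and the simulator's state vector
    def _to_state(self, x: np.ndarray) -> np.ndarray:
        y = np.empty(self.sys.n_state)
        y[: self.n_conc] = x[: self.n_conc]
        for rid in self.kin_ids:
            y[self.sys.state_slices[rid]] = x[self.frac_slices[rid]]
        return y

    def equalities(self, x: np.ndarray) -> np.ndarray:
        y = self._to_state(x)
        dy = self.sys.rhs(0.0, y, self.param)
        eqs = [dy[: self.n_conc]]
        for rid in self.kin_ids:
            sl = self.sys.state_slices[rid]
            eqs.append(dy[sl.start + 1 : sl.stop])  # rank n-1; sum handled below
            target = (
                x[self.etot_pos[rid]]
                if rid in self.etot_pos
                else self.param[rid].e_tot
            )
            eqs.append(np.array([x[self.frac_slices[rid]].sum() - target]))
        return np.concatenate(eqs)

    def fluxes(self, x: np.ndarray) -> dict[str, float]:
        y = self._to_state(x)
        return self.sys.complete_fluxes(self.sys.net_fluxes(y, self.param))

    def product_flux(self, x: np.ndarray) -> float:
        return self.fluxes(x)[self.condition.product_id]

    def biomass_flux(self, x: np.ndarray) -> float:
        if self.condition.biomass_id is None:
            return 0.0
        return self.fluxes(x)[self.condition.biomass_id]

    def variable_bounds(self) -> list[tuple[float, float]]:
        fold = self.config.concentration_fold
        bounds: list[tuple[float, float]] = []
        for m in self.sys.dynamic_mets:
            ref = self.sys.ref_conc[m]
            bounds.append((ref / fold, ref * fold))
        for rid in self.kin_ids:
            ub = self.etot_bounds.get(rid, (1.0, self.param[rid].e_tot))[1]
            n = len(self.param[rid].mechanism.states)
            bounds.extend([(0.0, max(ub, self.param[rid].e_tot))] * n)
        for rid in self.subset:
            bounds.append(self.etot_bounds[rid])
        return bounds

    def start(self, etot_start: dict[str, float]) -> np.ndarray:
        x = np.empty(self.n_var)
        x[: self.n_conc] = [self.sys.ref_conc[m] for m in self.sys.dynamic_mets]
        for rid in self.kin_ids:
            rk = self.param[rid]
            fold = etot_start.get(rid, rk.e_tot)
            x[self.frac_slices[rid]] = [
                rk.fractions[st] * fold for st in rk.mechanism.states
            ]
        for rid in self.subset:
            x[self.etot_pos[rid]] = etot_start[rid]
        return x

    def solve(self) -> tuple[float, np.ndarray] | None:
        """Multistart SLSQP; returns (product flux, x) of the best feasible
        stationary point, or None."""
        cons = [
            {"type": "eq", "fun": self.equalities},
            {"type": "ineq", "fun": lambda x: self.biomass_flux(x) - self.biomass_floor},
        ]
        bounds = self.variable_bounds()
        best: tuple[float, np.ndarray] | None = None
        for start in self._starts():
            res = minimize(
                lambda x: -self.product_flux(x),
                self.start(start),
                method="SLSQP",
                bounds=bounds,
                constraints=cons,
                options={"maxiter": 400, "ftol": 1e-12},
            )
            # SLSQP can exit with a line-search complaint at a constrained
            # optimum; accept any returned point that is feasible (the
            # multistart sweep and ODE verification guard optimality).
            if np.abs(self.equalities(res.x)).max() > 1e-7:
                continue
            if self.biomass_flux(res.x) < self.biomass_floor - 1e-7:
                continue
            val = self.product_flux(res.x)
            if best is None or val > best[0] + 1e-12:
                best = (val, res.x)
        return best

    def _starts(self) -> list[dict[str, float]]:
        grids = []
        for rid in self.subset:
            lb, ub = self.etot_bounds[rid]
            grids.append(np.linspace(lb, ub, max(self.config.multistart, 2)))
        return [dict(zip(self.subset, combo)) for combo in itertools.product(*grids)]


def _biomass_floor(model: EnsembleModel, condition: Condition) -> float:
    if condition.biomass_id is None:
        return -math.inf
    return condition.min_biomass_fraction * theoretical_max(
        model.network, condition, "biomass"
    )


def _reference_step1(
    model: EnsembleModel, param: KineticParameterization, condition: Condition
) -> Step1Result:
    state = model.solve_steady_state(param, {})
    return Step1Result(
        interventions=[],
        achieved_flux=state.fluxes[condition.product_id],
        kinetic_fluxes={rid: state.fluxes[rid] for rid in model.system.kin_ids},
        concentrations=dict(state.concentrations),
        biomass_flux=state.fluxes.get(condition.biomass_id, 0.0),
        method="reference",
    )


def force_step1(
    model: EnsembleModel,
    param: KineticParameterization,
    must: MustSets,
    condition: Condition,
    config: ForceConfig | None = None,
    kappa: int | None = None,
) -> Step1Result:
    """Choose e_tot interventions in J_kin maximizing the product flux.

    Enumerates subsets of the kinetic MUST reactions up to size ``kappa``
    and solves the steady-state-constrained NLP for each; ties are broken
    toward fewer interventions, then lexicographic reaction order.  Every
    accepted optimum is cross-checked by ODE relaxation from the perturbed
    reference so only dynamically reachable steady states are reported.
    """
    config = config or ForceConfig()
    kappa = config.kappa if kappa is None else kappa
    if kappa == 0:
        return _reference_step1(model, param, condition)

    candidates = sorted((must.must_u | must.must_l) & set(model.system.kin_ids))
    floor = _biomass_floor(model, condition)
    best: tuple[float, int, tuple[str, ...], np.ndarray, _Step1NLP] | None = None
    ref = _reference_step1(model, param, condition)
    for size in range(0, min(kappa, len(candidates)) + 1):
        for subset in itertools.combinations(candidates, size):
            if size == 0:
                val, x, nlp = ref.achieved_flux, None, None
            else:
                nlp = _Step1NLP(model, param, subset, must, condition, config, floor)
                sol = nlp.solve()
                if sol is None:
                    continue
                val, x = sol
                if not _ode_verify(model, param, nlp, subset, x, val):
                    continue
            if best is None or val > best[0] + 1e-6 * max(1.0, abs(best[0])):
                best = (val, size, subset, x, nlp)
    if best is None:
        raise InfeasibleError("no feasible steady state under any allowed intervention")
    val, size, subset, x, nlp = best
    if size == 0:
        return ref
    interventions = [
        KineticIntervention(
            reaction_id=rid,
            direction=_direction(rid, must),
            e_tot=float(x[nlp.etot_pos[rid]]),
            bounds=nlp.etot_bounds[rid],
        )
        for rid in subset
    ]
    fluxes = nlp.fluxes(x)
    return Step1Result(
        interventions=interventions,
        achieved_flux=val,
        kinetic_fluxes={rid: fluxes[rid] for rid in model.system.kin_ids},
        concentrations={
            m: float(x[i]) for i, m in enumerate(model.system.dynamic_mets)
        },
        biomass_flux=fluxes.get(condition.biomass_id, 0.0),
    )


def _ode_verify(model, param, nlp, subset, x, val, rel_tol=1e-3) -> bool:
    """Check the NLP optimum is a relaxation-reachable steady state."""
    pert = {rid: float(x[nlp.etot_pos[rid]]) for rid in subset}
    state = model.solve_steady_state(param, pert)
    if not state.converged:
        return False
    ode_val = state.fluxes[nlp.condition.product_id]
    return abs(ode_val - val) <= rel_tol * max(abs(val), 1.0)


# ----------------------------------------------------------------------------
# step 2: stoichiometric interventions under the worst-case inner objective


def _stoich_bounds(rid: str, must: MustSets, model: EnsembleModel) -> tuple[str, tuple[float, float]]:
    ref_min, ref_max, over_min, over_max = must.ranges[rid]
    r = model.network.reaction(rid)
    if rid in must.must_u:
        return "up", (over_min, r.ub)
    return "down", (r.lb, over_max)


def force_step2(
    model: EnsembleModel,
    step1: Step1Result,
    must: MustSets,
    condition: Condition,
    config: ForceConfig | None = None,
    budget: int = 0,
) -> tuple[list[StoichIntervention], float]:
    """Choose flux-bound interventions in J_stoic maximizing the worst case.

    The kinetic fluxes are fixed at the step-1 optimum.  For each subset
    of stoichiometric MUST reactions within ``budget``, the inner LP
    minimizes the product flux over the remaining degrees of freedom
    (MUST^U members get their lower bound raised to the overproduction
    minimum, MUST^L members their upper bound lowered to the
    overproduction maximum).  Strong duality of the reported inner optimum
    is verified to 1e-6.
    """
    config = config or ForceConfig()
    candidates = sorted((must.must_u | must.must_l) & set(model.partition.stoic_ids))
    floor = _biomass_floor(model, condition)

    best: tuple[float, int, tuple[str, ...]] | None = None
    for size in range(0, min(budget, len(candidates)) + 1):
        for subset in itertools.combinations(candidates, size):
            extra = LinearConstraintSet()
            for rid in subset:
                _, b = _stoich_bounds(rid, must, model)
                extra.bounds[rid] = b
            res = worst_case_product(
                model.network,
                model.partition,
                step1.kinetic_fluxes,
                extra,
                condition,
                biomass_floor=floor,
            )
            if not res.optimal:
                continue
            val = res.objective
            if best is None or val > best[0] + 1e-6 * max(1.0, abs(best[0])):
                best = (val, size, subset)
    if best is None:
        raise InfeasibleError("step-2 inner problem infeasible for every subset")
    val, size, subset = best

    # verification re-solve of the inner LP at the chosen binaries
    extra = LinearConstraintSet()
    interventions = []
    for rid in subset:
        direction, b = _stoich_bounds(rid, must, model)
        extra.bounds[rid] = b
        interventions.append(StoichIntervention(reaction_id=rid, direction=direction, bounds=b))
    res = worst_case_product(
        model.network, model.partition, step1.kinetic_fluxes, extra, condition,
        biomass_floor=floor,
    )
    gap = abs(res.objective - res.dual_objective)
    if gap > 1e-6:
        raise EmforceError(f"step-2 duality gap {gap:.3e} exceeds 1e-6")
    return interventions, float(res.objective)


# ----------------------------------------------------------------------------


def _design_result(kappa, step1, stoich, worst, basis) -> DesignResult:
    return DesignResult(
        kappa=kappa,
        kinetic_interventions=step1.interventions,
        stoich_interventions=stoich,
        achieved_flux=step1.achieved_flux,
        worst_case_flux=min(worst, step1.achieved_flux),
        biomass_flux=step1.biomass_flux,
        yield_mol_per_mol=step1.achieved_flux / basis,
        concentrations=step1.concentrations,
    )


def run_design(
    model: EnsembleModel,
    param: KineticParameterization,
    must: MustSets,
    condition: Condition,
    config: ForceConfig,
    kappa: int,
) -> DesignResult:
    """One full step1+step2 pass at a fixed intervention budget."""
    step1 = force_step1(model, param, must, condition, config, kappa)
    remaining = kappa - len(step1.interventions)
    stoich, worst = force_step2(model, step1, must, condition, config, remaining)
    basis = model.reference.basis_uptake or 100.0
    return _design_result(kappa, step1, stoich, worst, basis)


def escalate(
    model: EnsembleModel,
    param: KineticParameterization,
    must: MustSets,
    condition: Condition,
    config: ForceConfig | None = None,
) -> list[DesignResult]:
    """Escalate the intervention budget until the product flux plateaus.

    Runs step1+step2 for kappa = 1, 2, ... up to ``config.kappa`` and
    stops once the relative improvement in achieved product flux falls
    below ``stop_rel_improvement`` (or the candidate pool is exhausted).
    Returns the per-kappa design results; empty if the reference already
    attains the theoretical maximum.
    """
    config = config or ForceConfig()
    ref = _reference_step1(model, param, condition)
    theo = theoretical_max(model.network, condition, "product")
    if ref.achieved_flux >= theo - 1e-6:
        return []
    n_candidates = len(must.must_u | must.must_l)
    results: list[DesignResult] = []
    prev = ref.achieved_flux
    for kappa in range(1, max(min(config.kappa, n_candidates), 1) + 1):
        result = run_design(model, param, must, condition, config, kappa)
        results.append(result)
        # improvement as a fraction of the new value (always < 1), so a
        # stop threshold of 1 halts after the first design
        improvement = (result.achieved_flux - prev) / max(abs(result.achieved_flux), 1e-9)
        if improvement < config.stop_rel_improvement:
            break
        prev = result.achieved_flux
    return results


# ----------------------------------------------------------------------------
# exhaustive oracle (independent route: ODE relaxation + dense grids)


def _ode_objective(model, param, condition, pert, fold, floor):
    """Product flux at the relaxed steady state, or None if infeasible."""
    state = model.solve_steady_state(param, pert)
    if not state.converged:
        return None
    for m in model.system.dynamic_mets:
        ref = model.system.ref_conc[m]
        c = state.concentrations[m]
        if not (ref / fold - 1e-9 <= c <= ref * fold + 1e-9):
            return None
    if condition.biomass_id is not None:
        if state.fluxes.get(condition.biomass_id, 0.0) < floor - 1e-7:
            return None
    return state.fluxes[condition.product_id], state


def enumerate_oracle(
    model: EnsembleModel,
    param: KineticParameterization,
    must: MustSets,
    condition: Condition,
    kappa: int,
    config: ForceConfig | None = None,
    max_subsets: int = 10_000,
) -> DesignResult:
    """Exhaustive two-step search by grid + local refinement.

    Kinetic subsets are scanned on a dense e_tot grid with steady states
    obtained by ODE relaxation, the best grid point refined by Nelder-Mead
    direct search; the stoichiometric step enumerates bound-manipulation
    subsets with single LPs.  Intended as the correctness oracle for
    :func:`force_step1` / :func:`force_step2` at desk scale.
    """
    config = config or ForceConfig()
    kin_candidates = sorted((must.must_u | must.must_l) & set(model.system.kin_ids))
    n_subsets = sum(
        math.comb(len(kin_candidates), k) for k in range(0, kappa + 1)
    )
    if n_subsets > max_subsets:
        raise ValidationError(
            f"oracle budget exceeded: {n_subsets} subsets > {max_subsets}"
        )
    floor = _biomass_floor(model, condition)
    fold = config.concentration_fold
    basis = model.reference.basis_uptake or 100.0

    ref = _reference_step1(model, param, condition)
    best_val = ref.achieved_flux
    best: tuple[tuple[str, ...], dict[str, float], object] = ((), {}, None)

    for size in range(1, min(kappa, len(kin_candidates)) + 1):
        for subset in itertools.combinations(kin_candidates, size):
            bnds = [etot_bounds(rid, 1, config.z, must) for rid in subset]
            grids = [np.linspace(lb, ub, config.grid_points) for lb, ub in bnds]
            grid_best = None
            for combo in itertools.product(*grids):
                out = _ode_objective(
                    model, param, condition, dict(zip(subset, combo)), fold, floor
                )
                if out is None:
                    continue
                if grid_best is None or out[0] > grid_best[0]:
                    grid_best = (out[0], np.array(combo))
            if grid_best is None:
                continue

            def neg(e):
                e = np.clip(e, [b[0] for b in bnds], [b[1] for b in bnds])
                out = _ode_objective(
                    model, param, condition, dict(zip(subset, e)), fold, floor
                )
                return 1e9 if out is None else -out[0]

            res = minimize(
                neg,
                grid_best[1],
                method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 400},
            )
            e_opt = np.clip(res.x, [b[0] for b in bnds], [b[1] for b in bnds])
            out = _ode_objective(
                model, param, condition, dict(zip(subset, e_opt)), fold, floor
            )
            if out is None:
                continue
            val, state = out
            if val > best_val + 1e-6 * max(1.0, abs(best_val)):
                best_val = val
                best = (subset, dict(zip(subset, e_opt)), state)

    subset, e_opts, state = best
    if state is None:
        step1 = ref
    else:
        step1 = Step1Result(
            interventions=[
                KineticIntervention(
                    reaction_id=rid,
                    direction=_direction(rid, must),
                    e_tot=e_opts[rid],
                    bounds=etot_bounds(rid, 1, config.z, must),
                )
                for rid in subset
            ],
            achieved_flux=best_val,
            kinetic_fluxes={rid: state.fluxes[rid] for rid in model.system.kin_ids},
            concentrations={
                m: state.concentrations[m] for m in model.system.dynamic_mets
            },
            biomass_flux=state.fluxes.get(condition.biomass_id, 0.0),
            method="ode-grid-oracle",
        )
    remaining = kappa - len(step1.interventions)
    stoich, worst = force_step2(model, step1, must, condition, config, remaining)
    return _design_result(kappa, step1, stoich, worst, basis)
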