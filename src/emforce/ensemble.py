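"""Ensemble sampling, steady-state simulation and GA parameter selection.

The kinetic subnetwork J_kin is simulated as a mass-action ODE system over
(i) the concentrations of *dynamic* internal metabolites — those touched
only by kinetic reactions or by fixed-flux uptake exchanges — and (ii) the
enzyme-state amounts of every kinetic reaction.  Metabolites at the
kinetic/stoichiometric interface are clamped at their reference
concentration; the carbon-source uptake flux is held at the basis value
(fluxes are normalized per 100 units of uptake, so the model cannot and
does not predict uptake changes).  Fluxes of the non-fixed stoichiometric
reactions adjacent to clamped metabolites are completed by least squares
from the kinetic net fluxes (exactly determined on the shipped fixtures).

An ensemble member is one anchored :class:`KineticParameterization`.  All
members reproduce the reference flux distribution; they differ in their
response to perturbations, and a genetic algorithm selects the member (or
recombination of per-reaction parameter blocks) that minimizes the
deviation from measured mutant fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .errors import ConvergenceError, ValidationError
from .kinetics import (
    KineticParameterization,
    MechanismTemplate,
    anchor_parameters,
    elementary_rates,
)
from .network import MetabolicNetwork, ReactionPartition, ReferenceState

__all__ = [
    "SamplingConfig",
    "GAConfig",
    "SteadyState",
    "MutantFluxDataset",
    "StrainRecord",
    "EnsembleModel",
    "GAResult",
    "sample_parameterization",
    "solve_steady_state",
    "fitness",
    "ga_fit",
]


@dataclass(frozen=True)
class SamplingConfig:
    """How reversibilities and enzyme fractions are drawn.

    Reversibilities are uniform on [r_min, r_max] (default [0.05, 0.95] to
    avoid near-singular rate constants; the full open interval is available
    by config).  Enzyme fractions are uniform on the simplex (symmetric
    Dirichlet with concentration 1).  Zero-flux reactions and regulator
    side steps draw an equilibrium exchange magnitude uniform on
    (0, zero_flux_magnitude].
    """

    r_min: float = 0.05
    r_max: float = 0.95
    zero_flux_magnitude: float = 1.0


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 50
    generations: int = 200
    crossover_prob: float = 0.9
    mutation_prob: float = 0.05  # per-reaction block resample
    seed: int = 0
    elitism: int = 1
    fitness_tol: float = 0.0  # stop early once best fitness <= tol (0 = never)
    penalty: float = 1e6  # per non-converged strain

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValidationError("population_size must be >= 2")
        for p, label in (
            (self.crossover_prob, "crossover_prob"),
            (self.mutation_prob, "mutation_prob"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{label} must lie in [0, 1]")


@dataclass
class SteadyState:
    fluxes: dict[str, float]
    concentrations: dict[str, float]
    fractions: dict[str, dict[str, float]]
    residual_norm: float
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class StrainRecord:
    name: str
    perturbations: dict[str, float]  # reaction_id -> e_tot fold (0 = knockout)
    measurements: dict[str, float]  # reaction_id -> normalized flux
    sd: dict[str, float] = field(default_factory=dict)


@dataclass
class MutantFluxDataset:
    """Per-strain perturbations and measured normalized fluxes.

    Uptake magnitude is 100 in every strain's table; knockout folds are
    exactly 0.
    """

    strains: list[StrainRecord]
    uptake_id: str | None = None
    basis_uptake: float = 100.0
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        for s in self.strains:
            if self.uptake_id and self.uptake_id in s.measurements:
                mag = abs(s.measurements[self.uptake_id])
                if abs(mag - self.basis_uptake) > 1e-6:
                    raise ValidationError(
                        f"strain {s.name}: uptake magnitude {mag} != "
                        f"{self.basis_uptake}"
                    )


# ----------------------------------------------------------------------------


class KineticSystem:
    """Compiled ODE structure for one (network, partition) pair.

    Independent of the sampled parameter values, so it is built once per
    :class:`EnsembleModel` and reused for every ensemble member.
    """

    def __init__(
        self,
        network: MetabolicNetwork,
        part: ReactionPartition,
        reference: ReferenceState,
        mechanisms: dict[str, MechanismTemplate],
    ):
        part.validate_against(network)
        missing = sorted(set(part.kinetic_ids) - set(mechanisms))
        if missing:
            raise ValidationError(f"kinetic reactions without a mechanism: {missing}")
        self.network = network
        self.partition = part
        self.reference = reference
        self.mechanisms = mechanisms
        self.kin_ids = sorted(part.kinetic_ids)

        # fixed-flux stoichiometric reactions: uptake exchanges (net import
        # at reference) are held at their reference flux during simulation.
        exch = {r.id for r in network.exchange_reactions()}
        self.fixed_ids = sorted(
            rid
            for rid in part.stoic_ids
            if rid in exch and reference.flux(rid) < 0
        )
        free_stoic = sorted(set(part.stoic_ids) - set(self.fixed_ids))
        self.free_stoic_ids = free_stoic

        internal = {m.id for m in network.internal_metabolites}
        touched_by_free = set()
        for rid in free_stoic:
            touched_by_free |= set(network.reaction(rid).stoichiometry)
        self.dynamic_mets = sorted(
            m
            for m in internal
            if m not in touched_by_free
            and any(
                m in network.reaction(rid).stoichiometry
                for rid in list(part.kinetic_ids) + self.fixed_ids
            )
        )
        self.clamped_mets = sorted(internal - set(self.dynamic_mets))
        self._met_idx = {m: i for i, m in enumerate(self.dynamic_mets)}

        # state layout: [dynamic concentrations | per-reaction state amounts]
        self.state_slices: dict[str, slice] = {}
        pos = len(self.dynamic_mets)
        for rid in self.kin_ids:
            n = len(mechanisms[rid].states)
            self.state_slices[rid] = slice(pos, pos + n)
            pos += n
        self.n_state = pos

        # constant inflow into dynamic metabolites from fixed-flux reactions
        self.fixed_inflow = np.zeros(len(self.dynamic_mets))
        for rid in self.fixed_ids:
            v = reference.flux(rid)
            for m, c in network.reaction(rid).stoichiometry.items():
                if m in self._met_idx:
                    self.fixed_inflow[self._met_idx[m]] += c * v

        # stoichiometric completion: clamped-met balances determine the
        # free stoichiometric fluxes from the kinetic net fluxes.
        rows = self.clamped_mets
        A = np.zeros((len(rows), len(free_stoic)))
        ridx = {m: i for i, m in enumerate(rows)}
        for j, rid in enumerate(free_stoic):
            for m, c in network.reaction(rid).stoichiometry.items():
                if m in ridx:
                    A[ridx[m], j] = c
        self._completion_A = A
        self._completion_rows = ridx

        self.ref_conc = {
            m.id: m.reference_concentration for m in network.metabolites
        }

    # -- evaluation --------------------------------------------------------

    def initial_state(
        self, param: KineticParameterization, perturbations: dict[str, float]
    ) -> np.ndarray:
        y0 = np.empty(self.n_state)
        for m, i in self._met_idx.items():
            y0[i] = self.ref_conc[m]
        for rid in self.kin_ids:
            rk = param[rid]
            fold = perturbations.get(rid, rk.e_tot)
            mech = rk.mechanism
            y0[self.state_slices[rid]] = [
                rk.fractions[st] * fold for st in mech.states
            ]
        return y0

    def _conc_map(self, y: np.ndarray) -> dict[str, float]:
        conc = dict(self.ref_conc)
        for m, i in self._met_idx.items():
            conc[m] = y[i]
        return conc

    def rhs(self, t: float, y: np.ndarray, param: KineticParameterization) -> np.ndarray:
        dy = np.zeros_like(y)
        dy[: len(self.dynamic_mets)] = self.fixed_inflow
        conc = self._conc_map(np.maximum(y, 0.0))
        for rid in self.kin_ids:
            rk = param[rid]
            mech = rk.mechanism
            sl = self.state_slices[rid]
            amounts = {st: max(y[sl][k], 0.0) for k, st in enumerate(mech.states)}
            e_tot = float(np.sum(np.maximum(y[sl], 0.0)))
            rates, _ = elementary_rates(rk, conc, fractions=amounts, e_tot=e_tot)
            fidx = {st: k for k, st in enumerate(mech.states)}
            for k, step in enumerate(mech.steps):
                net = rates.net[k]
                base = sl.start
                dy[base + fidx[step.state_from]] -= net
                dy[base + fidx[step.state_to]] += net
                for m in step.substrates:
                    if m in self._met_idx:
                        dy[self._met_idx[m]] -= net
                for m in step.products:
                    if m in self._met_idx:
                        dy[self._met_idx[m]] += net
        return dy

    def net_fluxes(self, y: np.ndarray, param: KineticParameterization) -> dict[str, float]:
        conc = self._conc_map(np.maximum(y, 0.0))
        fluxes: dict[str, float] = {}
        for rid in self.kin_ids:
            rk = param[rid]
            sl = self.state_slices[rid]
            amounts = {
                st: max(y[sl][k], 0.0) for k, st in enumerate(rk.mechanism.states)
            }
            e_tot = float(np.sum(np.maximum(y[sl], 0.0)))
            _, net = elementary_rates(rk, conc, fractions=amounts, e_tot=e_tot)
            fluxes[rid] = net
        return fluxes

    def complete_fluxes(self, kin_fluxes: dict[str, float]) -> dict[str, float]:
        """Extend kinetic net fluxes with fixed and completed stoic fluxes."""
        fluxes = dict(kin_fluxes)
        for rid in self.fixed_ids:
            fluxes[rid] = self.reference.flux(rid)
        if self.free_stoic_ids:
            b = np.zeros(len(self._completion_rows))
            for rid, v in fluxes.items():
                for m, c in self.network.reaction(rid).stoichiometry.items():
                    if m in self._completion_rows:
                        b[self._completion_rows[m]] -= c * v
            sol, *_ = np.linalg.lstsq(self._completion_A, b, rcond=None)
            for j, rid in enumerate(self.free_stoic_ids):
                fluxes[rid] = float(sol[j])
        return fluxes

    # -- steady-state solve ------------------------------------------------

    def solve_steady_state(
        self,
        param: KineticParameterization,
        perturbations: dict[str, float] | list | None = None,
        steady_tol: float = 1e-9,
        t_final: float = 1e3,
    ) -> SteadyState:
        """Relax the mass-action ODEs to steady state, then Newton-refine.

        Returns a non-converged :class:`SteadyState` (not an exception) on
        divergence or failure to settle by ``t_final`` in normalized time.
        """
        if perturbations is None:
            perturbations = {}
        if not isinstance(perturbations, dict):
            perturbations = dict(perturbations)
        for rid, fold in perturbations.items():
            if rid not in param.blocks:
                raise ValidationError(f"perturbation on unknown kinetic reaction {rid!r}")
            if fold < 0:
                raise ValidationError(f"perturbation fold for {rid} must be >= 0")

        y0 = self.initial_state(param, perturbations)
        y = y0.copy()
        resid = float(np.abs(self.rhs(0.0, y, param)).max())
        message = ""
        if resid > steady_tol:
            y, resid, message = self._relax(y0, param, steady_tol, t_final)
        converged = resid <= max(steady_tol, 1e-8) and np.all(y > -1e-9)
        y = np.maximum(y, 0.0)
        # exact-zero knockout semantics: integrator round-off must not leave
        # residual enzyme in a deleted reaction
        for rid, fold in perturbations.items():
            if fold == 0.0:
                y[self.state_slices[rid]] = 0.0
        kin = self.net_fluxes(y, param)
        fluxes = self.complete_fluxes(kin)
        fractions = {
            rid: {
                st: float(y[self.state_slices[rid]][k])
                for k, st in enumerate(param[rid].mechanism.states)
            }
            for rid in self.kin_ids
        }
        conc = self._conc_map(y)
        internal = {m.id for m in self.network.internal_metabolites}
        conc = {m: conc[m] for m in conc if m in internal}
        return SteadyState(
            fluxes=fluxes,
            concentrations=conc,
            fractions=fractions,
            residual_norm=resid,
            converged=bool(converged),
            message=message,
        )

    def _newton(self, y: np.ndarray, param, tol: float):
        """Refine with a root solve on a reduced state (one enzyme-state
        amount per reaction eliminated by conservation)."""
        keep = list(range(len(self.dynamic_mets)))
        elim: list[tuple[int, slice, float]] = []
        for rid in self.kin_ids:
            sl = self.state_slices[rid]
            e_tot = float(np.sum(y[sl]))
            if e_tot <= 1e-12:
                continue  # knocked out: all amounts stay 0
            keep.extend(range(sl.start + 1, sl.stop))
            elim.append((sl.start, sl, e_tot))
        keep_arr = np.array(keep, dtype=int)

        def expand(x: np.ndarray) -> np.ndarray:
            full = np.zeros(self.n_state)
            full[keep_arr] = x
            for i0, sl, e_tot in elim:
                full[i0] = e_tot - full[i0 + 1 : sl.stop].sum()
            return full

        def fun(x: np.ndarray) -> np.ndarray:
            return self.rhs(0.0, expand(x), param)[keep_arr]

        sol = root(fun, y[keep_arr], method="hybr", tol=1e-12)
        full = expand(sol.x)
        resid = float(np.abs(self.rhs(0.0, full, param)).max())
        ok = resid <= tol and np.all(full > -1e-9)
        return full, resid, ok

    def _relax(self, y0, param, steady_tol, t_final):
        y = y0
        t_reached = 0.0
        for t_stop in (50.0, t_final):
            if t_stop <= t_reached:
                continue
            sol = solve_ivp(
                self.rhs,
                (t_reached, t_stop),
                y,
                args=(param,),
                method="LSODA",
                rtol=1e-8,
                atol=1e-10,
            )
            if not sol.success:
                return y, np.inf, f"integration failure: {sol.message}"
            y = sol.y[:, -1]
            t_reached = t_stop
            if not np.all(np.isfinite(y)) or np.abs(y).max() > 1e8:
                return y, np.inf, "divergence during relaxation"
            y_ref, resid, ok = self._newton(np.maximum(y, 0.0), param, steady_tol)
            if ok:
                return y_ref, resid, ""
        resid = float(np.abs(self.rhs(0.0, y, param)).max())
        return y, resid, f"not steady by t={t_final:g} (residual {resid:.3e})"


# ----------------------------------------------------------------------------


class EnsembleModel:
    """Bundles network, partition, mechanisms and reference for sampling,
    simulation and fitting."""

    def __init__(
        self,
        network: MetabolicNetwork,
        part: ReactionPartition,
        mechanisms: dict[str, MechanismTemplate],
        reference: ReferenceState,
        sampling: SamplingConfig | None = None,
    ):
        self.system = KineticSystem(network, part, reference, mechanisms)
        self.network = network
        self.partition = part
        self.mechanisms = mechanisms
        self.reference = reference
        self.sampling = sampling or SamplingConfig()
        self._fitness_cache: dict[tuple, float] = {}
        self._state_cache: dict[tuple, SteadyState] = {}

    # -- sampling ----------------------------------------------------------

    def sample_block(self, rid: str, rng: np.random.Generator):
        mech = self.mechanisms[rid]
        cfg = self.sampling
        n_cyc = len(mech.cycle_steps)
        R = rng.uniform(cfg.r_min, cfg.r_max, size=n_cyc)
        frac = rng.dirichlet(np.ones(len(mech.states)))
        # Dirichlet can return exact zeros in edge cases; nudge off the boundary
        frac = np.maximum(frac, 1e-9)
        frac = frac / frac.sum()
        v_ref = self.reference.flux(rid)
        n_need = len(mech.steps) if v_ref == 0 else len(mech.side_steps)
        q = cfg.zero_flux_magnitude * (1.0 - rng.uniform(0.0, 1.0, size=n_need))
        return anchor_parameters(
            mech,
            R,
            frac,
            v_ref,
            ref_concs=self.system.ref_conc,
            exchange_fluxes=q,
        )

    def sample_parameterization(self, seed: int | np.random.Generator) -> KineticParameterization:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        blocks = {rid: self.sample_block(rid, rng) for rid in self.system.kin_ids}
        return KineticParameterization(blocks)

    def sample_ensemble(self, n: int, seed: int) -> list[KineticParameterization]:
        rng = np.random.default_rng(seed)
        return [self.sample_parameterization(rng) for _ in range(n)]

    # -- simulation and fitness -------------------------------------------

    def solve_steady_state(
        self, param: KineticParameterization, perturbations=None, **kw
    ) -> SteadyState:
        pert = dict(perturbations or {})
        key = (param.key(), tuple(sorted(pert.items())))
        if key not in self._state_cache:
            self._state_cache[key] = self.system.solve_steady_state(
                param, pert, **kw
            )
            if len(self._state_cache) > 20000:
                self._state_cache.clear()
        return self._state_cache[key]

    def fitness(
        self,
        param: KineticParameterization,
        dataset: MutantFluxDataset,
        penalty: float = 1e6,
    ) -> float:
        """Sum of squared scaled deviations from measured mutant fluxes.

        scale = sd if given else max(|v_meas|, one flux unit on the
        dataset's basis); a non-converged strain contributes ``penalty``.
        Simulated fluxes are converted to the dataset's uptake basis, so a
        common rescaling of measurements and basis leaves scores unchanged.
        """
        known = set(self.network.reaction_ids)
        basis_ratio = dataset.basis_uptake / (self.reference.basis_uptake or 100.0)
        total = 0.0
        for strain in dataset.strains:
            bad = sorted(set(strain.measurements) - known)
            if bad:
                raise ValidationError(
                    f"strain {strain.name}: measurements for unknown reactions {bad}"
                )
            state = self.solve_steady_state(param, strain.perturbations)
            if not state.converged:
                total += penalty
                continue
            for rid, v_meas in strain.measurements.items():
                scale = strain.sd.get(rid) or max(abs(v_meas), basis_ratio)
                v_sim = state.fluxes.get(rid, 0.0) * basis_ratio
                total += ((v_sim - v_meas) / scale) ** 2
        return total

    def _cached_fitness(self, param, dataset, penalty) -> float:
        key = (param.key(), id(dataset), penalty)
        if key not in self._fitness_cache:
            self._fitness_cache[key] = self.fitness(param, dataset, penalty)
        return self._fitness_cache[key]

    # -- genetic algorithm -------------------------------------------------

    def ga_fit(
        self,
        ensemble: list[KineticParameterization],
        dataset: MutantFluxDataset,
        config: GAConfig | None = None,
    ) -> "GAResult":
        """Generational GA over per-reaction parameter blocks.

        Crossover swaps whole reaction blocks between parents (anchoring is
        preserved because blocks are swapped whole); mutation resamples one
        reaction's block.  Elitism makes the best fitness non-increasing.
        """
        if not ensemble:
            raise ValidationError("ensemble must be nonempty")
        config = config or GAConfig()
        rng = np.random.default_rng(config.seed)
        rids = self.system.kin_ids

        pop = [p.copy() for p in ensemble[: config.population_size]]
        while len(pop) < config.population_size:
            pop.append(self.sample_parameterization(rng))

        def evaluate(population):
            return np.array(
                [self._cached_fitness(p, dataset, config.penalty) for p in population]
            )

        fits = evaluate(pop)
        if np.all(fits >= config.penalty):
            raise ConvergenceError(
                "no ensemble member converges on any strain; widen the "
                "sampling ranges or enlarge the ensemble"
            )
        order = np.argsort(fits, kind="stable")
        history = [float(fits[order[0]])]
        best, best_fit = pop[order[0]], float(fits[order[0]])

        for _gen in range(config.generations):
            if config.fitness_tol > 0 and best_fit <= config.fitness_tol:
                break
            # tournament selection (size 2), deterministic under the seed
            parents = []
            for _ in range(config.population_size):
                i, j = rng.integers(0, config.population_size, size=2)
                parents.append(pop[i] if fits[i] <= fits[j] else pop[j])
            # crossover: uniform block swap
            children: list[KineticParameterization] = []
            for a, b in zip(parents[0::2], parents[1::2]):
                ca, cb = dict(a.blocks), dict(b.blocks)
                if rng.uniform() < config.crossover_prob:
                    for rid in rids:
                        if rng.uniform() < 0.5:
                            ca[rid], cb[rid] = cb[rid], ca[rid]
                children.append(KineticParameterization(ca))
                children.append(KineticParameterization(cb))
            children = children[: config.population_size]
            # mutation: resample a reaction's whole block
            for child in children:
                for rid in rids:
                    if rng.uniform() < config.mutation_prob:
                        child.blocks[rid] = self.sample_block(rid, rng)
            # elitism
            elite_idx = np.argsort(fits, kind="stable")[: config.elitism]
            for k, ei in enumerate(elite_idx):
                children[k] = pop[ei]
            pop = children
            fits = evaluate(pop)
            gen_best = int(np.argsort(fits, kind="stable")[0])
            if fits[gen_best] < best_fit:
                best, best_fit = pop[gen_best], float(fits[gen_best])
            history.append(best_fit)

        return GAResult(best=best.copy(), best_fitness=best_fit, history=history)


@dataclass
class GAResult:
    best: KineticParameterization
    best_fitness: float
    history: list[float]


# ----------------------------------------------------------------------------
# free-function facade


def sample_parameterization(network, part, mechanisms, reference, seed, sampling=None):
    """Sample one anchored parameterization of the kinetic subnetwork."""
    model = EnsembleModel(network, part, mechanisms, reference, sampling)
    return model.sample_parameterization(seed)


def solve_steady_state(model: EnsembleModel, param, perturbations=None, **kw):
    return model.solve_steady_state(param, perturbations, **kw)


def fitness(model: EnsembleModel, param, dataset, penalty: float = 1e6) -> float:
    return model.fitness(param, dataset, penalty)


def ga_fit(model: EnsembleModel, ensemble, dataset, config=None) -> GAResult:
    return model.ga_fit(ensemble, dataset, config)
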