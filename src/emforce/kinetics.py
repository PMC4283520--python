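"""Elementary mass-action decomposition of enzymatic reactions.

Each enzymatic reaction is decomposed into a cycle of elementary steps
(substrate binding, catalysis, product release), each step exchanging
exactly one enzyme state for another so total enzyme is conserved.  The
ensemble-modeling construction parameterizes a step not by its rate
constants directly but by its *reversibility* R = v_b / v_f at the
reference steady state, together with the distribution of the enzyme over
its mechanism states (enzyme fractions e, summing to 1 in the reference
strain).  Given the reference net flux v_ref, the elementary fluxes follow
from

    v_f = v_ref / (1 - R),        v_b = R * v_ref / (1 - R),

and the rate constants are whatever values reproduce those fluxes at the
reference enzyme fractions and normalized (= 1) metabolite concentrations.
By construction every member of the sampled ensemble reproduces the
reference flux distribution exactly ("anchoring"); members differ in how
they respond to perturbations.

Substrate-level regulation is limited to competitive (dead-end) inhibition
and simple activation (an activator-bound enzyme state is required for the
catalytic cycle).  Regulator-binding steps carry zero net flux at any
steady state, so they are anchored by sampling an exchange magnitude
v_f = v_b instead of a reversibility ratio.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AnchoringError, ValidationError
from .network import Reaction

__all__ = [
    "ElementaryStep",
    "MechanismTemplate",
    "ReactionKinetics",
    "KineticParameterization",
    "StepRates",
    "build_mechanism",
    "anchor_parameters",
    "elementary_rates",
    "scale_etot",
    "MECHANISM_KINDS",
]

MECHANISM_KINDS = ("uni-uni", "bi-bi-ordered", "uni-bi", "bi-uni")

_uid_counter = itertools.count()


@dataclass(frozen=True)
class ElementaryStep:
    """One elementary event: state_from (+ substrates) <-> state_to (+ products).

    ``in_cycle`` steps carry the reaction's net flux at steady state;
    regulator-binding steps (dead-end inhibition, activator binding) are
    side equilibria with zero net rate at steady state.
    """

    kind: str  # binding | catalytic | release | inhibitor-binding | activator-binding
    state_from: str
    state_to: str
    substrates: tuple[str, ...] = ()
    products: tuple[str, ...] = ()
    in_cycle: bool = True


@dataclass(frozen=True)
class MechanismTemplate:
    reaction_id: str
    kind: str
    states: tuple[str, ...]  # free enzyme first
    steps: tuple[ElementaryStep, ...]
    regulators: tuple[tuple[str, str], ...] = ()  # (metabolite, inhibition|activation)

    @property
    def cycle_steps(self) -> list[ElementaryStep]:
        return [s for s in self.steps if s.in_cycle]

    @property
    def side_steps(self) -> list[ElementaryStep]:
        return [s for s in self.steps if not s.in_cycle]

    def validate(self) -> None:
        state_set = set(self.states)
        for s in self.steps:
            if s.state_from not in state_set or s.state_to not in state_set:
                raise ValidationError(
                    f"{self.reaction_id}: step references unknown enzyme state"
                )
        # the catalytic cycle must return to its starting state
        cyc = self.cycle_steps
        if cyc:
            if cyc[0].state_from != cyc[-1].state_to:
                raise ValidationError(
                    f"{self.reaction_id}: elementary cycle does not close"
                )
            for a, b in zip(cyc, cyc[1:]):
                if a.state_to != b.state_from:
                    raise ValidationError(
                        f"{self.reaction_id}: elementary cycle is disconnected"
                    )


def build_mechanism(
    reaction: Reaction,
    kind: str,
    regulators: list[tuple[str, str]] | tuple = (),
) -> MechanismTemplate:
    """Build the canonical ordered mechanism for ``reaction``.

    Substrates bind in sorted order; a single catalytic step converts the
    fully-bound complex, releasing the first product; remaining products
    are released one at a time.  A uni-uni reaction therefore has two
    steps, E + A <-> EA and EA <-> E + B.  Each competitive inhibitor adds
    one dead-end binding step on the free enzyme; an activator inserts a
    binding step whose bound state serves as the cycle's "free" enzyme.
    """
    if kind not in MECHANISM_KINDS:
        raise ValidationError(f"unknown mechanism kind {kind!r}")
    subs = reaction.substrates()
    prods = reaction.products()
    want_s, want_p = {
        "uni-uni": (1, 1),
        "bi-bi-ordered": (2, 2),
        "uni-bi": (1, 2),
        "bi-uni": (2, 1),
    }[kind]
    if len(subs) != want_s or len(prods) != want_p:
        raise ValidationError(
            f"{reaction.id}: mechanism {kind} needs {want_s} substrate(s) and "
            f"{want_p} product(s); reaction has {len(subs)}/{len(prods)}"
        )

    regulators = tuple(regulators)
    for met, mode in regulators:
        if mode not in ("inhibition", "activation"):
            raise ValidationError(f"{reaction.id}: unknown regulator mode {mode!r}")

    steps: list[ElementaryStep] = []
    states: list[str] = ["E"]
    free = "E"

    # activator binding precedes the cycle; the activator-bound enzyme is
    # the species that actually turns over.
    for met, mode in regulators:
        if mode == "activation":
            bound = f"E*{met}"
            steps.append(
                ElementaryStep(
                    kind="activator-binding",
                    state_from=free,
                    state_to=bound,
                    substrates=(met,),
                    in_cycle=False,
                )
            )
            states.append(bound)
            free = bound

    cycle_start = free
    current = free
    # substrate binding
    for s in subs[:-1]:
        nxt = f"{current}.{s}"
        steps.append(
            ElementaryStep(
                kind="binding", state_from=current, state_to=nxt, substrates=(s,)
            )
        )
        states.append(nxt)
        current = nxt
    last_sub = subs[-1]
    full = f"{current}.{last_sub}"
    steps.append(
        ElementaryStep(
            kind="binding", state_from=current, state_to=full, substrates=(last_sub,)
        )
    )
    states.append(full)
    current = full
    # catalytic step releases the first product; if only one product this
    # collapses catalysis + release into one step back to the free enzyme.
    remaining = list(prods[1:])
    if remaining:
        # complex still holding the remaining products
        hold = cycle_start + "".join(f":{p}" for p in remaining)
        steps.append(
            ElementaryStep(
                kind="catalytic",
                state_from=current,
                state_to=hold,
                products=(prods[0],),
            )
        )
        states.append(hold)
        current = hold
        for i, p in enumerate(remaining):
            if i == len(remaining) - 1:
                nxt = cycle_start
            else:
                nxt = cycle_start + "".join(f":{q}" for q in remaining[i + 1 :])
            steps.append(
                ElementaryStep(
                    kind="release", state_from=current, state_to=nxt, products=(p,)
                )
            )
            if nxt != cycle_start:
                states.append(nxt)
            current = nxt
    else:
        steps.append(
            ElementaryStep(
                kind="catalytic",
                state_from=current,
                state_to=cycle_start,
                products=(prods[0],),
            )
        )

    # dead-end competitive inhibitor states hang off the free enzyme
    for met, mode in regulators:
        if mode == "inhibition":
            dead = f"E-{met}"
            steps.append(
                ElementaryStep(
                    kind="inhibitor-binding",
                    state_from="E",
                    state_to=dead,
                    substrates=(met,),
                    in_cycle=False,
                )
            )
            states.append(dead)

    mech = MechanismTemplate(
        reaction_id=reaction.id,
        kind=kind,
        states=tuple(states),
        steps=tuple(steps),
        regulators=regulators,
    )
    mech.validate()
    return mech


def _flip(mech: MechanismTemplate) -> MechanismTemplate:
    """Reverse the catalytic cycle (for reactions with negative v_ref)."""
    flipped: list[ElementaryStep] = []
    for s in reversed(mech.cycle_steps):
        flipped.append(
            ElementaryStep(
                kind=s.kind,
                state_from=s.state_to,
                state_to=s.state_from,
                substrates=s.products,
                products=s.substrates,
                in_cycle=True,
            )
        )
    flipped.extend(mech.side_steps)
    return replace(mech, steps=tuple(flipped))


@dataclass(frozen=True)
class StepRates:
    forward: np.ndarray
    reverse: np.ndarray

    @property
    def net(self) -> np.ndarray:
        return self.forward - self.reverse


@dataclass(frozen=True)
class ReactionKinetics:
    """Anchored elementary kinetics of a single reaction.

    ``mechanism`` is stored in *working* orientation (net-forward at the
    reference); ``sign`` restores the network orientation on output.  Rate
    constants are per normalized concentration; the effective maximum
    activity is not stored separately — it emerges from e_tot times the
    cycle rate constants.
    """

    mechanism: MechanismTemplate
    reversibilities: np.ndarray  # per cycle step, in (0, 1) (0 allowed: irreversible)
    exchange_fluxes: np.ndarray  # per side step (and used when v_ref == 0)
    fractions: dict[str, float]  # reference enzyme fractions, sum to 1
    kf: np.ndarray
    kb: np.ndarray
    v_ref: float
    sign: float = 1.0
    e_tot: float = 1.0
    uid: int = field(default_factory=lambda: next(_uid_counter))

    def with_etot(self, fold: float) -> "ReactionKinetics":
        if fold < 0:
            raise ValidationError(
                f"{self.mechanism.reaction_id}: e_tot fold must be >= 0"
            )
        return replace(self, e_tot=float(fold), uid=self.uid)


class KineticParameterization:
    """Per-reaction anchored kinetics for the whole kinetic subnetwork."""

    def __init__(self, blocks: dict[str, ReactionKinetics]):
        self.blocks = dict(blocks)

    def __getitem__(self, rxn_id: str) -> ReactionKinetics:
        return self.blocks[rxn_id]

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in self.blocks

    @property
    def reaction_ids(self) -> list[str]:
        return sorted(self.blocks)

    def e_tot(self, rxn_id: str) -> float:
        return self.blocks[rxn_id].e_tot

    def key(self) -> tuple:
        """Hashable identity of (block, e_tot) choices — used for caching."""
        return tuple(
            (rid, self.blocks[rid].uid, self.blocks[rid].e_tot)
            for rid in sorted(self.blocks)
        )

    def copy(self) -> "KineticParameterization":
        return KineticParameterization(dict(self.blocks))

    def with_block(self, rxn_id: str, block: ReactionKinetics) -> "KineticParameterization":
        new = dict(self.blocks)
        new[rxn_id] = block
        return KineticParameterization(new)


def scale_etot(
    param: KineticParameterization, reaction_id: str, fold: float
) -> KineticParameterization:
    """Return a copy with e_tot(reaction) = fold; rate constants unchanged.

    fold = 0 is knockout semantics; fold = 1 the reference level.
    """
    if reaction_id not in param:
        raise ValidationError(f"unknown kinetic reaction {reaction_id!r}")
    return param.with_block(reaction_id, param[reaction_id].with_etot(fold))


def anchor_parameters(
    mechanism: MechanismTemplate,
    reversibilities: np.ndarray,
    fractions: dict[str, float] | np.ndarray,
    v_ref: float,
    ref_concs: dict[str, float] | None = None,
    exchange_fluxes: np.ndarray | None = None,
    zero_flux_magnitude: float = 1.0,
    residual_tol: float = 1e-9,
) -> ReactionKinetics:
    """Anchor elementary rate constants at the reference steady state.

    For each cycle step, v_f = v_ref/(1-R) and v_b = R*v_ref/(1-R); the
    rate constants are then fixed by v_f = k_f * e(state_from) * prod(c)
    and symmetrically for v_b.  Side (regulator) steps, and all steps of a
    zero-flux reaction, are anchored at equilibrium with sampled exchange
    magnitude v_f = v_b.  Negative v_ref flips the mechanism so the
    anchored net flux is positive in working coordinates; the sign is
    restored on evaluation.
    """
    mech = mechanism
    sign = 1.0
    if v_ref < 0:
        mech = _flip(mechanism)
        sign = -1.0
        v_ref = -v_ref

    cyc = mech.cycle_steps
    R = np.asarray(reversibilities, dtype=float)
    if R.shape != (len(cyc),):
        raise ValidationError(
            f"{mech.reaction_id}: need {len(cyc)} reversibilities, got {R.shape}"
        )
    if np.any(R < 0) or np.any(R >= 1):
        raise ValidationError(f"{mech.reaction_id}: reversibilities must lie in [0, 1)")

    if isinstance(fractions, np.ndarray):
        fractions = {st: float(f) for st, f in zip(mech.states, fractions)}
    frac = {st: float(fractions[st]) for st in mech.states}
    total = sum(frac.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"{mech.reaction_id}: enzyme fractions sum to {total}")
    if any(f < 0 for f in frac.values()):
        raise ValidationError(f"{mech.reaction_id}: negative enzyme fraction")

    conc = dict(ref_concs) if ref_concs else {}

    def c(met: str) -> float:
        return conc.get(met, 1.0)

    # side steps always need an exchange magnitude; for a zero-flux reaction
    # every step is at equilibrium and needs one.
    n_side = len(mech.side_steps)
    n_need = len(mech.steps) if v_ref == 0 else n_side
    if exchange_fluxes is None:
        q = np.full(n_need, zero_flux_magnitude)
    else:
        q = np.asarray(exchange_fluxes, dtype=float)
        if q.shape != (n_need,):
            raise ValidationError(
                f"{mech.reaction_id}: need {n_need} exchange fluxes, got {q.shape}"
            )
    if np.any(q <= 0):
        raise ValidationError(f"{mech.reaction_id}: exchange fluxes must be > 0")

    kf = np.zeros(len(mech.steps))
    kb = np.zeros(len(mech.steps))
    cyc_i = 0
    side_i = 0
    for i, step in enumerate(mech.steps):
        if step.in_cycle and v_ref != 0:
            vf = v_ref / (1.0 - R[cyc_i])
            vb = R[cyc_i] * v_ref / (1.0 - R[cyc_i])
            cyc_i += 1
        elif step.in_cycle:  # zero-flux reaction: anchored at equilibrium
            vf = vb = float(q[cyc_i])
            cyc_i += 1
        else:
            vf = vb = float(q[side_i] if v_ref != 0 else q[len(cyc) + side_i])
            side_i += 1
        ef = frac[step.state_from]
        eb = frac[step.state_to]
        denom_f = ef * float(np.prod([c(m) for m in step.substrates]))
        denom_b = eb * float(np.prod([c(m) for m in step.products]))
        if vf > 0 and denom_f == 0:
            raise AnchoringError(
                f"{mech.reaction_id}: enzyme state {step.state_from} has zero "
                f"fraction but carries flux (singular anchoring)"
            )
        if vb > 0 and denom_b == 0:
            raise AnchoringError(
                f"{mech.reaction_id}: enzyme state {step.state_to} has zero "
                f"fraction but carries flux (singular anchoring)"
            )
        kf[i] = vf / denom_f if denom_f > 0 else 0.0
        kb[i] = vb / denom_b if denom_b > 0 else 0.0

    rk = ReactionKinetics(
        mechanism=mech,
        reversibilities=R,
        exchange_fluxes=q,
        fractions=frac,
        kf=kf,
        kb=kb,
        v_ref=sign * v_ref,
        sign=sign,
    )
    # anchoring residual: net step rates at reference must equal v_ref
    rates, _ = elementary_rates(rk, concentrations=conc, fractions=frac, e_tot=1.0)
    net = rates.net
    target = np.array([v_ref if s.in_cycle else 0.0 for s in mech.steps])
    resid = np.abs(net - target).max()
    if resid > residual_tol:
        raise AnchoringError(
            f"{mech.reaction_id}: anchoring residual {resid:.3e} > {residual_tol:g}"
        )
    return rk


def elementary_rates(
    rk: ReactionKinetics,
    concentrations: dict[str, float],
    fractions: dict[str, float] | None = None,
    e_tot: float | None = None,
) -> tuple[StepRates, float]:
    """Mass-action rates of every elementary step and the net reaction flux.

    ``fractions`` are absolute enzyme-state amounts; if their sum differs
    from ``e_tot`` they are rescaled to it.  The net reaction flux is the
    net rate of the final cycle step (all cycle steps share it at steady
    state), signed back to network orientation.
    """
    mech = rk.mechanism
    if e_tot is None:
        e_tot = rk.e_tot
    if e_tot < 0:
        raise ValidationError(f"{mech.reaction_id}: e_tot must be >= 0")
    if fractions is None:
        fractions = rk.fractions
    for met in concentrations:
        if concentrations[met] < 0:
            raise ValidationError(f"negative concentration for {met}")
    frac = np.array([fractions.get(st, 0.0) for st in mech.states])
    tot = frac.sum()
    if e_tot == 0.0 or tot == 0.0:
        frac = np.zeros_like(frac)
    elif abs(tot - e_tot) > 1e-12:
        frac = frac * (e_tot / tot)
    fidx = {st: i for i, st in enumerate(mech.states)}

    def c(met: str) -> float:
        return concentrations.get(met, 1.0)

    vf = np.empty(len(mech.steps))
    vb = np.empty(len(mech.steps))
    for i, step in enumerate(mech.steps):
        vf[i] = rk.kf[i] * frac[fidx[step.state_from]] * float(
            np.prod([c(m) for m in step.substrates])
        )
        vb[i] = rk.kb[i] * frac[fidx[step.state_to]] * float(
            np.prod([c(m) for m in step.products])
        )
    rates = StepRates(forward=vf, reverse=vb)
    cyc_idx = [i for i, s in enumerate(mech.steps) if s.in_cycle]
    net_flux = float(rates.net[cyc_idx[-1]]) * rk.sign if cyc_idx else 0.0
    return rates, net_flux
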