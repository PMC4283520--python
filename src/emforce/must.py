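"""MUST-set identification.

A reaction belongs to MUST^U (resp. MUST^L) when its attainable flux range
in the *overproduction space* lies strictly above (below) its range in the
*reference space*: its flux must increase (decrease) to permit the target
yield.  The reference space honors kinetic uniqueness — reactions in J_kin
have a unique steady-state flux, so their reference range is the point
{V_ref}; stoichiometric reactions get an FVA range with the kinetic fluxes
pinned and the condition's uptake bounds applied.  The overproduction
space is stoichiometric FVA under the condition plus the product floor
(min_product_fraction of the theoretical maximum) and the biomass floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import InfeasibleError
from .lp import LinearConstraintSet, flux_range, theoretical_max
from .network import Condition, MetabolicNetwork, ReactionPartition, ReferenceState, apply_condition

__all__ = ["MustSets", "find_must_single", "write_must_report"]

EPSILON = 1e-6  # classification margin absorbing LP noise


@dataclass
class MustSets:
    must_u: frozenset[str]
    must_l: frozenset[str]
    # reaction -> (ref_min, ref_max, over_min, over_max)
    ranges: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert not (self.must_u & self.must_l), "MUST sets must be disjoint"

    def classify(self, rxn_id: str) -> str:
        if rxn_id in self.must_u:
            return "U"
        if rxn_id in self.must_l:
            return "L"
        return "-"


def overproduction_constraints(
    network: MetabolicNetwork, condition: Condition
) -> LinearConstraintSet:
    """Product and biomass floors as fractions of their theoretical maxima."""
    rows = []
    if condition.product_id is not None:
        pmax = theoretical_max(network, condition, "product")
        rows.append(({condition.product_id: 1.0}, ">=", condition.min_product_fraction * pmax))
    if condition.biomass_id is not None:
        bmax = theoretical_max(network, condition, "biomass")
        rows.append(({condition.biomass_id: 1.0}, ">=", condition.min_biomass_fraction * bmax))
    return LinearConstraintSet(rows=rows)


def find_must_single(
    network: MetabolicNetwork,
    part: ReactionPartition,
    reference: ReferenceState,
    condition: Condition,
    epsilon: float = EPSILON,
) -> MustSets:
    """Single-reaction MUST classification by per-reaction flux ranges.

    j in MUST^U iff over_min(j) > ref_max(j) + epsilon;
    j in MUST^L iff over_max(j) < ref_min(j) - epsilon.
    """
    part.validate_against(network)
    net = apply_condition(network, condition)

    ref_extra = LinearConstraintSet(
        fixed_fluxes={rid: reference.flux(rid) for rid in sorted(part.kinetic_ids)}
    )
    over_extra = overproduction_constraints(network, condition)

    must_u, must_l = set(), set()
    ranges: dict[str, tuple[float, float, float, float]] = {}
    try:
        over_probe = flux_range(net, condition.product_id, over_extra, tag="overproduction-space")
    except InfeasibleError as exc:
        raise InfeasibleError(
            "overproduction targets inconsistent: no flux distribution attains "
            "the product and biomass floors simultaneously"
        ) from exc
    del over_probe

    for rid in network.reaction_ids:
        if rid in part.kinetic_ids:
            v = reference.flux(rid)
            ref_min = ref_max = v
        else:
            fr = flux_range(net, rid, ref_extra, tag="reference-space")
            ref_min, ref_max = fr.vmin, fr.vmax
        fo = flux_range(net, rid, over_extra, tag="overproduction-space")
        ranges[rid] = (ref_min, ref_max, fo.vmin, fo.vmax)
        if fo.vmin > ref_max + epsilon:
            must_u.add(rid)
        elif fo.vmax < ref_min - epsilon:
            must_l.add(rid)

    return MustSets(must_u=frozenset(must_u), must_l=frozenset(must_l), ranges=ranges)


def write_must_report(must: MustSets, path: str | Path) -> None:
    """TSV report: reaction_id, set, ref_min, ref_max, over_min, over_max."""
    lines = ["reaction_id\tset\tref_min\tref_max\tover_min\tover_max"]
    for rid in sorted(must.ranges):
        a, b, c, d = must.ranges[rid]
        lines.append(f"{rid}\t{must.classify(rid)}\t{a:.6g}\t{b:.6g}\t{c:.6g}\t{d:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")
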