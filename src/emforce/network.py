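"""Metabolic network data model and I/O.

A :class:`MetabolicNetwork` is a plain stoichiometric description:
metabolites (internal or external), reactions with signed stoichiometric
coefficients and flux bounds.  Exchange reactions are written outward, so
uptake carries a negative flux (glucose uptake at the -100 mmol gDW^-1 h^-1
basis).  On top of the network sit three light value objects:

* :class:`ReactionPartition` — the split into the kinetic subnetwork J_kin
  (reactions with an elementary-step kinetic description) and the purely
  stoichiometric remainder J_stoic;
* :class:`Condition` — environmental bounds (aerobic/anaerobic uptake
  limits), boolean regulatory rules, and the product/biomass floors used
  for overproduction design;
* :class:`ReferenceState` — the wild-type steady-state flux distribution,
  normalized per 100 units of carbon-source uptake, with all metabolite
  concentrations normalized to 1.

Two on-disk formats are supported: a section-tagged TSV dialect (written
and read by this module, round-trip safe) and SBML L3/FBC via cobrapy
(read-only, for interoperability with genome-scale models).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import BalanceError, NetworkFormatError, ValidationError

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "ReactionPartition",
    "RegulatoryRule",
    "Condition",
    "ReferenceState",
    "read_network",
    "write_network",
    "partition",
    "apply_condition",
    "load_reference_state",
]

_DEFAULT_BOUND = 1000.0


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    is_external: bool = False
    reference_concentration: float = 1.0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("metabolite id must be non-empty")
        if self.reference_concentration <= 0:
            raise ValidationError(
                f"metabolite {self.id}: reference_concentration must be > 0"
            )


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed stoichiometry and flux bounds.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed).  Bounds are on the per-100-glucose flux basis.
    """

    id: str
    stoichiometry: dict[str, float]
    lb: float = 0.0
    ub: float = _DEFAULT_BOUND

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("reaction id must be non-empty")
        if not any(c != 0 for c in self.stoichiometry.values()):
            raise ValidationError(f"reaction {self.id}: no nonzero coefficient")
        if self.lb > self.ub:
            raise ValidationError(f"reaction {self.id}: lb > ub")

    @property
    def reversible(self) -> bool:
        return self.lb < 0 < self.ub

    def substrates(self) -> list[str]:
        return sorted(m for m, c in self.stoichiometry.items() if c < 0)

    def products(self) -> list[str]:
        return sorted(m for m, c in self.stoichiometry.items() if c > 0)


class MetabolicNetwork:
    """Validated collection of metabolites and reactions.

    The implied stoichiometric matrix S has one row per *internal*
    metabolite; external (boundary) metabolites are excluded from mass
    balances.
    """

    def __init__(self, metabolites: list[Metabolite], reactions: list[Reaction]):
        if not reactions:
            raise ValidationError("network has an empty reaction list")
        met_ids = [m.id for m in metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ValidationError(f"duplicate reaction ids: {dup}")
        known = set(met_ids)
        for r in reactions:
            missing = sorted(set(r.stoichiometry) - known)
            if missing:
                raise ValidationError(
                    f"reaction {r.id} references undeclared metabolite(s): "
                    + ", ".join(missing)
                )
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self._met_by_id = {m.id: m for m in self.metabolites}
        self._rxn_by_id = {r.id: r for r in self.reactions}

    # -- accessors ---------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_by_id[met_id]
        except KeyError:
            raise KeyError(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_by_id[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction {rxn_id!r}") from None

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.is_external]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_by_id

    def exchange_reactions(self) -> list[Reaction]:
        """Reactions touching at least one external metabolite."""
        return [
            r
            for r in self.reactions
            if any(self._met_by_id[m].is_external for m in r.stoichiometry)
        ]

    def stoichiometric_matrix(self) -> tuple[np.ndarray, dict[str, int], dict[str, int]]:
        """S over internal metabolites; returns (S, met_index, rxn_index)."""
        mets = self.internal_metabolites
        met_index = {m.id: i for i, m in enumerate(mets)}
        rxn_index = {r.id: j for j, r in enumerate(self.reactions)}
        S = np.zeros((len(mets), len(self.reactions)))
        for r in self.reactions:
            j = rxn_index[r.id]
            for m, c in r.stoichiometry.items():
                if m in met_index:
                    S[met_index[m], j] = c
        return S, met_index, rxn_index

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            list(self.metabolites),
            [replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"MetabolicNetwork({len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions)"
        )


@dataclass(frozen=True)
class ReactionPartition:
    """Disjoint split of reaction ids into J_kin and J_stoic."""

    kinetic_ids: frozenset[str]
    stoic_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.kinetic_ids & self.stoic_ids:
            raise ValidationError("kinetic and stoichiometric sets overlap")

    def validate_against(self, network: MetabolicNetwork) -> None:
        all_ids = set(network.reaction_ids)
        if self.kinetic_ids | self.stoic_ids != all_ids:
            raise ValidationError("partition does not cover the network")


@dataclass(frozen=True)
class RegulatoryRule:
    """Boolean transcriptional rule (e.g. ArcA/FNR) tied to a condition.

    Repression forces the targets' bounds to [0, 0] while active;
    activation opens an otherwise-silenced reaction to ``released_bounds``.
    """

    regulator: str
    mode: str  # "repression" | "activation"
    target_reaction_ids: frozenset[str]
    condition: str
    released_bounds: tuple[float, float] = (0.0, _DEFAULT_BOUND)

    def __post_init__(self) -> None:
        if self.mode not in ("repression", "activation"):
            raise ValidationError(f"unknown regulatory mode {self.mode!r}")


@dataclass(frozen=True)
class Condition:
    """Environmental condition plus overproduction targets.

    ``min_product_fraction`` / ``min_biomass_fraction`` are floors relative
    to the FBA theoretical maximum of product and biomass under this
    condition (defaults 0.9 and 0.1).
    """

    name: str
    uptake_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    rules: tuple[RegulatoryRule, ...] = ()
    product_id: str | None = None
    min_product_fraction: float = 0.9
    biomass_id: str | None = None
    min_biomass_fraction: float = 0.1

    def __post_init__(self) -> None:
        for frac, label in (
            (self.min_product_fraction, "min_product_fraction"),
            (self.min_biomass_fraction, "min_biomass_fraction"),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"{label} must lie in [0, 1], got {frac}")

    def active_rules(self) -> list[RegulatoryRule]:
        return [r for r in self.rules if r.condition in (self.name, "*")]


@dataclass(frozen=True)
class ReferenceState:
    """Wild-type steady state: fluxes per 100 uptake, concentrations = 1."""

    fluxes: dict[str, float]
    concentrations: dict[str, float]
    basis_uptake: float = 100.0
    uptake_id: str | None = None
    degenerate: bool = False

    def flux(self, rxn_id: str) -> float:
        return self.fluxes.get(rxn_id, 0.0)


# ----------------------------------------------------------------------------
# operations


def partition(network: MetabolicNetwork, kinetic_ids: set[str]) -> ReactionPartition:
    """Split the network into J_kin = ``kinetic_ids`` and its complement."""
    all_ids = set(network.reaction_ids)
    unknown = sorted(set(kinetic_ids) - all_ids)
    if unknown:
        raise ValidationError(f"kinetic_ids not in network: {unknown}")
    part = ReactionPartition(
        kinetic_ids=frozenset(kinetic_ids),
        stoic_ids=frozenset(all_ids - set(kinetic_ids)),
    )
    part.validate_against(network)
    return part


def apply_condition(network: MetabolicNetwork, condition: Condition) -> MetabolicNetwork:
    """Return a copy with condition uptake bounds and active rules applied.

    Idempotent for a fixed condition.  Repressed reactions get [0, 0];
    activated ones get the rule's released bounds.
    """
    for rid in condition.uptake_bounds:
        if not network.has_reaction(rid):
            raise ValidationError(f"uptake bound targets unknown reaction {rid!r}")
    for rule in condition.rules:
        missing = sorted(set(rule.target_reaction_ids) - set(network.reaction_ids))
        if missing:
            raise ValidationError(
                f"rule {rule.regulator} targets unknown reaction(s): {missing}"
            )
    if condition.product_id is not None and not network.has_reaction(condition.product_id):
        raise ValidationError(f"product_id {condition.product_id!r} not in network")
    if condition.biomass_id is not None and not network.has_reaction(condition.biomass_id):
        raise ValidationError(f"biomass_id {condition.biomass_id!r} not in network")

    new_bounds: dict[str, tuple[float, float]] = {}
    for rid, (lb, ub) in condition.uptake_bounds.items():
        if lb > ub:
            raise ValidationError(f"uptake bounds for {rid}: lb {lb} > ub {ub}")
        new_bounds[rid] = (lb, ub)
    for rule in condition.active_rules():
        for rid in sorted(rule.target_reaction_ids):
            if rule.mode == "repression":
                new_bounds[rid] = (0.0, 0.0)
            else:
                new_bounds[rid] = rule.released_bounds

    reactions = []
    for r in network.reactions:
        if r.id in new_bounds:
            lb, ub = new_bounds[r.id]
            reactions.append(replace(r, lb=lb, ub=ub))
        else:
            reactions.append(r)
    return MetabolicNetwork(list(network.metabolites), reactions)


def load_reference_state(
    path: str | Path,
    network: MetabolicNetwork,
    uptake_id: str | None = None,
    tol: float = 1e-6,
) -> ReferenceState:
    """Read a ``reaction_id<TAB>flux`` table and validate mass balance."""
    fluxes: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise NetworkFormatError(f"{path}:{lineno}: expected 2 columns")
        rid, raw = parts
        if not network.has_reaction(rid):
            raise ValidationError(f"{path}:{lineno}: unknown reaction {rid!r}")
        try:
            fluxes[rid] = float(raw)
        except ValueError:
            raise NetworkFormatError(f"{path}:{lineno}: bad flux {raw!r}") from None
    return reference_state_from_fluxes(network, fluxes, uptake_id=uptake_id, tol=tol)


def reference_state_from_fluxes(
    network: MetabolicNetwork,
    fluxes: dict[str, float],
    uptake_id: str | None = None,
    tol: float = 1e-6,
) -> ReferenceState:
    """Build a validated :class:`ReferenceState` from a flux map."""
    S, met_index, rxn_index = network.stoichiometric_matrix()
    v = np.zeros(len(network.reactions))
    for rid, val in fluxes.items():
        v[rxn_index[rid]] = val
    residual = S @ v
    if np.abs(residual).max() > tol:
        worst = max(met_index, key=lambda m: abs(residual[met_index[m]]))
        raise BalanceError(
            f"reference fluxes violate mass balance: worst metabolite {worst} "
            f"(residual {residual[met_index[worst]]:.6g})"
        )
    if uptake_id is None:
        exch = {r.id for r in network.exchange_reactions()}
        candidates = [(fluxes.get(rid, 0.0), rid) for rid in sorted(exch)]
        if candidates:
            uptake_id = min(candidates)[1]  # most negative = dominant uptake
    basis = abs(fluxes.get(uptake_id, 0.0)) if uptake_id else 0.0
    degenerate = math.isclose(basis, 0.0, abs_tol=1e-12)
    concentrations = {m.id: m.reference_concentration for m in network.metabolites}
    return ReferenceState(
        fluxes=dict(fluxes),
        concentrations=concentrations,
        basis_uptake=basis,
        uptake_id=uptake_id,
        degenerate=degenerate,
    )


# ----------------------------------------------------------------------------
# TSV / SBML I/O


def read_network(path: str | Path, format: str | None = None) -> MetabolicNetwork:
    """Read a network from the TSV dialect or from SBML (L3 + FBC).

    ``format`` may be "tsv" or "sbml"; by default it is inferred from the
    file suffix (.xml/.sbml -> SBML, otherwise TSV).
    """
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "tsv"
    if format == "tsv":
        return _read_tsv(path)
    if format == "sbml":
        return _read_sbml(path)
    raise NetworkFormatError(f"unknown network format {format!r}")


def _parse_stoich_string(raw: str, where: str) -> dict[str, float]:
    """Parse '-1 G + 1 M'-style stoichiometry strings."""
    stoich: dict[str, float] = {}
    # normalize "a + b" separators, keep leading sign of the first term
    terms = raw.replace("- ", "-").replace("+ ", "+").split()
    # re-tokenize: terms like '-1', 'G', '+1', 'M'
    if len(terms) % 2 != 0:
        raise NetworkFormatError(f"{where}: malformed stoichiometry {raw!r}")
    for coef_tok, met in zip(terms[0::2], terms[1::2]):
        try:
            coef = float(coef_tok.lstrip("+"))
        except ValueError:
            raise NetworkFormatError(
                f"{where}: bad coefficient {coef_tok!r} in {raw!r}"
            ) from None
        stoich[met] = stoich.get(met, 0.0) + coef
    return stoich


def _read_tsv(path: Path) -> MetabolicNetwork:
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        tag = parts[0]
        where = f"{path}:{lineno}"
        if tag == "M":
            if len(parts) != 4:
                raise NetworkFormatError(f"{where}: M lines need 4 columns")
            _, mid, name, scope = parts
            if scope not in ("internal", "external"):
                raise NetworkFormatError(f"{where}: scope must be internal|external")
            metabolites.append(
                Metabolite(id=mid, name=name, is_external=(scope == "external"))
            )
        elif tag == "R":
            if len(parts) != 5:
                raise NetworkFormatError(f"{where}: R lines need 5 columns")
            _, rid, lb, ub, stoich_raw = parts
            try:
                lbf, ubf = float(lb), float(ub)
            except ValueError:
                raise NetworkFormatError(f"{where}: bad bounds {lb!r}/{ub!r}") from None
            reactions.append(
                Reaction(
                    id=rid,
                    stoichiometry=_parse_stoich_string(stoich_raw, where),
                    lb=lbf,
                    ub=ubf,
                )
            )
        else:
            raise NetworkFormatError(f"{where}: unknown section tag {tag!r}")
    return MetabolicNetwork(metabolites, reactions)


def _format_stoich(stoich: dict[str, float]) -> str:
    parts = []
    for met in sorted(stoich):
        coef = stoich[met]
        if not parts:
            parts.append(f"{coef:g} {met}")
        else:
            sign = "+" if coef >= 0 else "-"
            parts.append(f"{sign} {abs(coef):g} {met}")
    return " ".join(parts)


def write_network(network: MetabolicNetwork, path: str | Path) -> None:
    """Write the TSV dialect; read_network round-trips the content."""
    lines = ["# emforce network TSV"]
    for m in network.metabolites:
        scope = "external" if m.is_external else "internal"
        lines.append(f"M\t{m.id}\t{m.name}\t{scope}")
    for r in network.reactions:
        lines.append(f"R\t{r.id}\t{r.lb:g}\t{r.ub:g}\t{_format_stoich(r.stoichiometry)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_sbml(path: Path) -> MetabolicNetwork:
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover
        raise NetworkFormatError("cobrapy is required for SBML import") from exc
    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:
        raise NetworkFormatError(f"SBML parse failure for {path}: {exc}") from exc
    metabolites = [
        Metabolite(id=m.id, name=m.name or "", is_external=False)
        for m in model.metabolites
    ]
    reactions = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: c for m, c in r.metabolites.items()},
            lb=r.lower_bound,
            ub=r.upper_bound,
        )
        for r in model.reactions
    ]
    return MetabolicNetwork(metabolites, reactions)
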