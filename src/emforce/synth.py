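"""Synthetic toy networks with ground-truth kinetics and mutant datasets.

The canonical fixture is a branched uptake network ("toy branch"): glucose
enters at a fixed 100-unit uptake, flows down a linear backbone, and splits
at a branch metabolite between a product route and a waste route that
stands in for biomass drain.  Reference fluxes are chosen for closed-form
checkability (backbone 100, product 20, waste 80).  The generic generator
produces random chain-and-branch networks of the same shape for
property-style tests.

All generation is reproducible from (spec, seed).  Mutant flux datasets
emulate the experimental setting: a wild type plus single-gene-deletion
strains, fluxes renormalized per 100 units of uptake, with optional
multiplicative Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .ensemble import EnsembleModel, MutantFluxDataset, StrainRecord
from .errors import ValidationError
from .kinetics import KineticParameterization, MechanismTemplate, build_mechanism
from .network import (
    Condition,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    ReactionPartition,
    ReferenceState,
    partition,
    reference_state_from_fluxes,
    write_network,
)

__all__ = [
    "ToySpec",
    "toy_branch",
    "toy_branch_mechanisms",
    "toy_branch_condition",
    "make_toy_network",
    "default_mechanisms",
    "ground_truth",
    "simulate_mutants",
    "write_fixture",
]


@dataclass(frozen=True)
class ToySpec:
    """Blueprint for a random chain-and-branch toy network.

    ``branches`` lists (backbone position, kind) pairs, kind in
    {"product", "waste"}; the chain end always exports.  The resulting
    network is connected and carbon-conserving by construction (all
    coefficients are 1).
    """

    n_chain: int = 2
    branches: tuple[tuple[int, str], ...] = ((1, "waste"),)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chain < 1:
            raise ValidationError("n_chain must be >= 1")
        for pos, kind in self.branches:
            if not 0 <= pos < self.n_chain:
                raise ValidationError(f"branch position {pos} outside the chain")
            if kind not in ("product", "waste"):
                raise ValidationError(f"unknown branch kind {kind!r}")


def toy_branch() -> tuple[MetabolicNetwork, ReactionPartition, ReferenceState]:
    """The canonical branched fixture.

    Metabolites Gx (external), G, M, P, W, Px, Wx (external); reactions
    UPT (uptake exchange, fixed -100 outward convention), kinetic chain
    R1: G->M, branch R2: M->P and R3: M->W, and stoichiometric exports
    EX_P, EX_W (the waste export doubles as the biomass proxy).  Reference
    fluxes: R1=100, R2=20, R3=80, EX_P=20, EX_W=80, UPT=-100.
    """
    metabolites = [
        Metabolite("Gx", "glucose (ext)", is_external=True),
        Metabolite("G", "glucose"),
        Metabolite("M", "branch intermediate"),
        Metabolite("P", "product"),
        Metabolite("W", "waste / biomass proxy"),
        Metabolite("Px", "product (ext)", is_external=True),
        Metabolite("Wx", "waste (ext)", is_external=True),
    ]
    reactions = [
        Reaction("UPT", {"G": -1, "Gx": 1}, lb=-1000, ub=0),
        Reaction("R1", {"G": -1, "M": 1}, lb=0, ub=1000),
        Reaction("R2", {"M": -1, "P": 1}, lb=0, ub=1000),
        Reaction("R3", {"M": -1, "W": 1}, lb=0, ub=1000),
        Reaction("EX_P", {"P": -1, "Px": 1}, lb=0, ub=1000),
        Reaction("EX_W", {"W": -1, "Wx": 1}, lb=0, ub=1000),
    ]
    network = MetabolicNetwork(metabolites, reactions)
    part = partition(network, {"R1", "R2", "R3"})
    fluxes = {"UPT": -100.0, "R1": 100.0, "R2": 20.0, "R3": 80.0, "EX_P": 20.0, "EX_W": 80.0}
    reference = reference_state_from_fluxes(network, fluxes, uptake_id="UPT")
    return network, part, reference


def toy_branch_mechanisms(
    regulators: dict[str, list[tuple[str, str]]] | None = None,
) -> dict[str, MechanismTemplate]:
    network, part, _ = toy_branch()
    regulators = regulators or {}
    return {
        rid: build_mechanism(network.reaction(rid), "uni-uni", regulators.get(rid, ()))
        for rid in sorted(part.kinetic_ids)
    }


def toy_branch_condition(
    min_product_fraction: float = 0.9, min_biomass_fraction: float = 0.1
) -> Condition:
    return Condition(
        name="aerobic-like",
        uptake_bounds={"UPT": (-100.0, -100.0)},
        product_id="EX_P",
        min_product_fraction=min_product_fraction,
        biomass_id="EX_W",
        min_biomass_fraction=min_biomass_fraction,
    )


def make_toy_network(
    spec: ToySpec,
) -> tuple[MetabolicNetwork, ReactionPartition, ReferenceState]:
    """Generate a random chain-and-branch toy with a balanced reference.

    Branch splits are drawn from a seeded Dirichlet at each branching node
    and the reference is normalized to 100 units of uptake.
    """
    rng = np.random.default_rng(spec.seed)
    metabolites = [Metabolite("Gx", is_external=True), Metabolite("C0")]
    reactions = [Reaction("UPT", {"C0": -1, "Gx": 1}, lb=-1000, ub=0)]
    kinetic: set[str] = set()
    fluxes: dict[str, float] = {"UPT": -100.0}

    branch_at: dict[int, list[int]] = {}
    for b, (pos, _kind) in enumerate(spec.branches):
        branch_at.setdefault(pos, []).append(b)

    inflow = 100.0
    for i in range(spec.n_chain):
        # split the inflow at node i among its branches and the chain
        n_out = len(branch_at.get(i, [])) + 1
        if n_out > 1:
            shares = rng.dirichlet(np.full(n_out, 2.0))
            shares = 0.05 + 0.9 * shares  # keep every route carrying flux
            shares = shares / shares.sum()
        else:
            shares = np.array([1.0])
        for k, b in enumerate(branch_at.get(i, [])):
            bm = f"B{b}"
            metabolites.append(Metabolite(bm))
            metabolites.append(Metabolite(f"{bm}x", is_external=True))
            rid = f"BR{b}"
            reactions.append(Reaction(rid, {f"C{i}": -1, bm: 1}, lb=0, ub=1000))
            kinetic.add(rid)
            ex = f"EX_B{b}"
            reactions.append(Reaction(ex, {bm: -1, f"{bm}x": 1}, lb=0, ub=1000))
            fluxes[rid] = fluxes[ex] = inflow * shares[k]
        chain_flux = inflow * shares[-1]
        if i < spec.n_chain - 1:
            metabolites.append(Metabolite(f"C{i + 1}"))
            rid = f"R{i + 1}"
            reactions.append(
                Reaction(rid, {f"C{i}": -1, f"C{i + 1}": 1}, lb=0, ub=1000)
            )
            kinetic.add(rid)
            fluxes[rid] = chain_flux
        else:
            metabolites.append(Metabolite("Endx", is_external=True))
            reactions.append(Reaction("EX_END", {f"C{i}": -1, "Endx": 1}, lb=0, ub=1000))
            fluxes["EX_END"] = chain_flux
        inflow = chain_flux

    network = MetabolicNetwork(metabolites, reactions)
    _check_connected(network)
    part = partition(network, kinetic)
    reference = reference_state_from_fluxes(network, fluxes, uptake_id="UPT", tol=1e-9)
    return network, part, reference


def _check_connected(network: MetabolicNetwork) -> None:
    g = nx.Graph()
    for r in network.reactions:
        mets = list(r.stoichiometry)
        g.add_node(r.id)
        for m in mets:
            g.add_edge(r.id, m)
    if not nx.is_connected(g):
        raise ValidationError("generated toy network is disconnected")


def default_mechanisms(
    network: MetabolicNetwork, part: ReactionPartition
) -> dict[str, MechanismTemplate]:
    """Uni-uni / bi-* templates inferred from each kinetic reaction's arity."""
    kinds = {(1, 1): "uni-uni", (2, 2): "bi-bi-ordered", (1, 2): "uni-bi", (2, 1): "bi-uni"}
    out = {}
    for rid in sorted(part.kinetic_ids):
        r = network.reaction(rid)
        arity = (len(r.substrates()), len(r.products()))
        if arity not in kinds:
            raise ValidationError(f"{rid}: no default mechanism for arity {arity}")
        out[rid] = build_mechanism(r, kinds[arity])
    return out


def ground_truth(
    network: MetabolicNetwork,
    part: ReactionPartition,
    mechanisms: dict[str, MechanismTemplate],
    reference: ReferenceState,
    seed: int = 0,
) -> KineticParameterization:
    """One anchored parameterization designated as the recovery-test truth."""
    model = EnsembleModel(network, part, mechanisms, reference)
    return model.sample_parameterization(seed)


def simulate_mutants(
    model: EnsembleModel,
    truth: KineticParameterization,
    strains: list[tuple[str, dict[str, float]]],
    noise_sd: float = 0.0,
    seed: int = 0,
    measured_ids: list[str] | None = None,
) -> MutantFluxDataset:
    """Simulate strain steady states and emit a normalized flux dataset.

    ``strains`` is a list of (name, perturbations) pairs with perturbation
    folds on e_tot (0 = knockout).  Fluxes are renormalized so the uptake
    magnitude is exactly the 100-unit basis, then multiplied by
    1 + N(0, noise_sd^2) (factors clipped to [0.01, inf) so noise never
    flips a flux sign).  Non-converged strains are excluded, with a
    warning recorded in the dataset metadata.  The default measured subset
    is all kinetic reactions plus exchanges.
    """
    rng = np.random.default_rng(seed)
    system = model.system
    uptake_id = system.fixed_ids[0] if system.fixed_ids else None
    if measured_ids is None:
        exch = [r.id for r in model.network.exchange_reactions()]
        measured_ids = sorted(set(system.kin_ids) | set(exch))
    basis = model.reference.basis_uptake or 100.0

    records: list[StrainRecord] = []
    warnings: list[str] = []
    for name, pert in strains:
        for rid, fold in pert.items():
            if fold == 0 and rid not in truth.blocks:
                raise ValidationError(f"strain {name}: knockout of unknown {rid!r}")
        state = model.solve_steady_state(truth, pert)
        if not state.converged:
            warnings.append(f"strain {name} excluded: {state.message or 'non-converged'}")
            continue
        scale = 1.0
        if uptake_id is not None and state.fluxes.get(uptake_id):
            scale = basis / abs(state.fluxes[uptake_id])
        measurements = {}
        for rid in measured_ids:
            v = state.fluxes.get(rid, 0.0) * scale
            # the uptake flux is the normalization basis and stays exact
            if noise_sd > 0 and v != 0.0 and rid != uptake_id:
                factor = max(1.0 + rng.normal(0.0, noise_sd), 0.01)
                v = v * factor
            measurements[rid] = v
        records.append(StrainRecord(name=name, perturbations=dict(pert), measurements=measurements))

    ds = MutantFluxDataset(
        strains=records,
        uptake_id=uptake_id,
        basis_uptake=basis,
        metadata={"warnings": warnings, "noise_sd": noise_sd, "seed": seed},
    )
    ds.validate()
    return ds


# ----------------------------------------------------------------------------
# fixture export (TSV formats consumed by the network / dataset loaders)


def write_fixture(outdir: str | Path) -> dict[str, Path]:
    """Write the canonical toy fixture files (network, reference,
    mechanisms, condition) into ``outdir`` and return their paths."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    network, part, reference = toy_branch()
    paths = {
        "network": outdir / "network.tsv",
        "reference": outdir / "reference.tsv",
        "mechanisms": outdir / "mechanisms.tsv",
        "condition": outdir / "condition.yaml",
    }
    write_network(network, paths["network"])
    lines = [f"{rid}\t{reference.fluxes[rid]:g}" for rid in network.reaction_ids]
    paths["reference"].write_text("\n".join(lines) + "\n")
    mech_lines = [f"{rid}\tuni-uni\t" for rid in sorted(part.kinetic_ids)]
    paths["mechanisms"].write_text("\n".join(mech_lines) + "\n")
    cond = toy_branch_condition()
    paths["condition"].write_text(
        yaml.safe_dump(
            {
                "name": cond.name,
                "uptake_bounds": {k: list(v) for k, v in cond.uptake_bounds.items()},
                "rules": [],
                "product_id": cond.product_id,
                "min_product_fraction": cond.min_product_fraction,
                "biomass_id": cond.biomass_id,
                "min_biomass_fraction": cond.min_biomass_fraction,
            }
        )
    )
    return paths


def write_dataset(dataset: MutantFluxDataset, fluxes_path, perturbations_path) -> None:
    """Write the mutant dataset as the two-TSV interchange format."""
    flux_lines = []
    pert_lines = []
    for s in dataset.strains:
        for rid in sorted(s.measurements):
            row = f"{s.name}\t{rid}\t{s.measurements[rid]:.10g}"
            if rid in s.sd:
                row += f"\t{s.sd[rid]:.10g}"
            flux_lines.append(row)
        for rid in sorted(s.perturbations):
            pert_lines.append(f"{s.name}\t{rid}\t{s.perturbations[rid]:g}")
    Path(fluxes_path).write_text("\n".join(flux_lines) + "\n")
    Path(perturbations_path).write_text("\n".join(pert_lines) + ("\n" if pert_lines else ""))


def read_dataset(fluxes_path, perturbations_path, uptake_id=None) -> MutantFluxDataset:
    """Read the two-TSV mutant dataset format back into memory."""
    meas: dict[str, dict[str, float]] = {}
    sds: dict[str, dict[str, float]] = {}
    for line in Path(fluxes_path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        strain, rid, flux = parts[0], parts[1], float(parts[2])
        meas.setdefault(strain, {})[rid] = flux
        if len(parts) > 3:
            sds.setdefault(strain, {})[rid] = float(parts[3])
    perts: dict[str, dict[str, float]] = {}
    for line in Path(perturbations_path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        strain, rid, fold = line.split("\t")
        perts.setdefault(strain, {})[rid] = float(fold)
    records = [
        StrainRecord(
            name=name,
            perturbations=perts.get(name, {}),
            measurements=meas[name],
            sd=sds.get(name, {}),
        )
        for name in meas
    ]
    return MutantFluxDataset(strains=records, uptake_id=uptake_id)
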