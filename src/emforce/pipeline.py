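"""Pipeline orchestration: config validation and the end-to-end run.

A single YAML/JSON config drives load -> ensemble sampling -> GA fit ->
MUST sets -> FORCE escalation -> reports.  One master seed fans out to
per-stage seeds by fixed offsets (truth/synthetic data +0, dataset noise
+1, ensemble +2, GA +3) so partial reruns stay reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .ensemble import EnsembleModel, GAConfig
from .errors import ConfigError, ValidationError
from .force import ForceConfig, escalate
from .kinetics import build_mechanism
from .must import find_must_single, write_must_report
from .network import (
    Condition,
    RegulatoryRule,
    load_reference_state,
    partition,
    read_network,
)
from .synth import read_dataset

SEED_OFFSET_DATA = 0
SEED_OFFSET_NOISE = 1
SEED_OFFSET_ENSEMBLE = 2
SEED_OFFSET_GA = 3
_SEED_MOD = 2**31 - 1


def stage_seed(master: int, offset: int) -> int:
    return (int(master) + offset) % _SEED_MOD


@dataclass
class PipelineConfig:
    network_path: Path
    mechanisms_path: Path
    reference_path: Path
    dataset_fluxes_path: Path
    dataset_perturbations_path: Path
    kinetic_ids: list[str]
    condition: Condition
    ga: GAConfig
    force: ForceConfig
    ensemble_size: int = 50
    seed: int = 0
    outdir: Path = Path("emforce_out")
    raw: dict = field(default_factory=dict)


_REQUIRED_KEYS = (
    "network",
    "mechanisms",
    "reference",
    "dataset_fluxes",
    "dataset_perturbations",
    "kinetic_ids",
    "condition",
)


def _parse_condition(raw: dict) -> Condition:
    for key in ("product_id", "biomass_id"):
        if key not in raw:
            raise ConfigError(f"condition is missing required key {key!r}")
    rules = tuple(
        RegulatoryRule(
            regulator=r["regulator"],
            mode=r["mode"],
            target_reaction_ids=frozenset(r["targets"]),
            condition=r.get("condition", raw.get("name", "custom")),
            released_bounds=tuple(r.get("released_bounds", (0.0, 1000.0))),
        )
        for r in raw.get("rules", [])
    )
    try:
        return Condition(
            name=raw.get("name", "custom"),
            uptake_bounds={k: tuple(v) for k, v in raw.get("uptake_bounds", {}).items()},
            rules=rules,
            product_id=raw["product_id"],
            min_product_fraction=raw.get("min_product_fraction", 0.9),
            biomass_id=raw["biomass_id"],
            min_biomass_fraction=raw.get("min_biomass_fraction", 0.1),
        )
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse, default-fill and cross-check a pipeline config file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except Exception as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")
    for key in _REQUIRED_KEYS:
        if key not in raw:
            raise ConfigError(f"config is missing required key {key!r}")

    base = path.parent

    def _path(key: str) -> Path:
        p = Path(raw[key])
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise ConfigError(f"{key}: file not found: {p}")
        return p

    condition = _parse_condition(raw["condition"])
    ga_raw = dict(raw.get("ga", {}))
    force_raw = dict(raw.get("force", {}))
    force_raw.setdefault("z", 10.0)
    force_raw.setdefault("concentration_fold", 5.0)
    try:
        ga = GAConfig(**ga_raw)
        force = ForceConfig(**force_raw)
    except (TypeError, ValidationError) as exc:
        raise ConfigError(f"invalid ga/force settings: {exc}") from exc

    return PipelineConfig(
        network_path=_path("network"),
        mechanisms_path=_path("mechanisms"),
        reference_path=_path("reference"),
        dataset_fluxes_path=_path("dataset_fluxes"),
        dataset_perturbations_path=_path("dataset_perturbations"),
        kinetic_ids=list(raw["kinetic_ids"]),
        condition=condition,
        ga=ga,
        force=force,
        ensemble_size=int(raw.get("ensemble_size", 50)),
        seed=int(raw.get("seed", 0)),
        outdir=Path(raw.get("outdir", "emforce_out")),
        raw=raw,
    )


def load_mechanisms(path: str | Path, network) -> dict:
    """Mechanism declaration TSV: reaction_id, kind, regulator:mode[,...]."""
    mechanisms = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ConfigError(f"{path}:{lineno}: need reaction_id and kind")
        rid, kind = parts[0], parts[1]
        regulators = []
        if len(parts) > 2 and parts[2].strip():
            for tok in parts[2].split(","):
                met, _, mode = tok.partition(":")
                regulators.append((met.strip(), mode.strip()))
        mechanisms[rid] = build_mechanism(network.reaction(rid), kind, regulators)
    return mechanisms


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write reports under config.outdir.

    Returns the run manifest.  Identical config + seed produce identical
    numeric outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    network = read_network(config.network_path)
    part = partition(network, set(config.kinetic_ids))
    reference = load_reference_state(config.reference_path, network)
    mechanisms = load_mechanisms(config.mechanisms_path, network)
    dataset = read_dataset(
        config.dataset_fluxes_path, config.dataset_perturbations_path
    )
    model = EnsembleModel(network, part, mechanisms, reference)

    ensemble = model.sample_ensemble(
        config.ensemble_size, stage_seed(config.seed, SEED_OFFSET_ENSEMBLE)
    )
    ga_cfg = GAConfig(
        **{
            **config.ga.__dict__,
            "seed": stage_seed(config.seed, SEED_OFFSET_GA),
        }
    )
    ga = model.ga_fit(ensemble, dataset, ga_cfg)
    (outdir / "fitness_trace.tsv").write_text(
        "generation\tbest_fitness\n"
        + "\n".join(f"{i}\t{f:.10g}" for i, f in enumerate(ga.history))
        + "\n"
    )

    must = find_must_single(network, part, reference, config.condition)
    write_must_report(must, outdir / "must_report.tsv")

    designs = escalate(model, ga.best, must, config.condition, config.force)
    design_payload = {
        "designs": [d.to_dict() for d in designs],
        "best_fitness": ga.best_fitness,
        "must_u": sorted(must.must_u),
        "must_l": sorted(must.must_l),
    }
    (outdir / "design.json").write_text(json.dumps(design_payload, indent=2) + "\n")
    summary = ["kappa\tachieved_flux\tworst_case_flux\tyield_mol_per_mol"]
    for d in designs:
        summary.append(
            f"{d.kappa}\t{d.achieved_flux:.6g}\t{d.worst_case_flux:.6g}"
            f"\t{d.yield_mol_per_mol:.6g}"
        )
    (outdir / "design_summary.tsv").write_text("\n".join(summary) + "\n")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            "ensemble": stage_seed(config.seed, SEED_OFFSET_ENSEMBLE),
            "ga": stage_seed(config.seed, SEED_OFFSET_GA),
        },
        "ensemble_size": config.ensemble_size,
        "condition": config.condition.name,
        "n_strains": len(dataset.strains),
        "best_fitness": ga.best_fitness,
        "n_designs": len(designs),
        "outputs": [
            "fitness_trace.tsv",
            "must_report.tsv",
            "design.json",
            "design_summary.tsv",
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
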