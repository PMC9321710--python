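"""Run configuration: YAML loading and model/pathway resolution.

A run config names the model (a file plus dialect, or one of the built-in
synthetic models), optional medium overrides (exchange-reaction bounds),
knock-in pathway definitions, the MOEA settings, and report options.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .gpr import parse_gpr
from .io import read_model
from .model import ModelValidationError, PathwayDefinition, StoichiometricModel
from .moea import MOEAConfig
from .toys import ToySpec, core_pathway, make_core_model, make_random_toy

__all__ = ["RunConfig", "load_run_config", "pathway_from_dict"]


def pathway_from_dict(doc: Mapping[str, Any]) -> PathwayDefinition:
    """Build a pathway from its config mapping.

    Expected keys: ``id``, ``reactions`` (list of {id, metabolites,
    lower_bound, upper_bound, gene_reaction_rule}), ``genes``,
    ``metabolites``.
    """
    reactions = []
    for rxn in doc.get("reactions", []):
        rule_text = (rxn.get("gene_reaction_rule") or "").strip()
        reactions.append(
            (
                rxn["id"],
                {k: float(v) for k, v in rxn.get("metabolites", {}).items()},
                float(rxn.get("lower_bound", 0.0)),
                float(rxn.get("upper_bound", 1000.0)),
                parse_gpr(rule_text) if rule_text else None,
            )
        )
    return PathwayDefinition(
        pathway_id=doc["id"],
        new_reactions=tuple(reactions),
        new_genes=tuple(doc.get("genes", ())),
        new_metabolites=tuple(doc.get("metabolites", ())),
    )


@dataclass
class RunConfig:
    """Everything needed to reproduce one search run."""

    model: StoichiometricModel
    moea: MOEAConfig
    pathways: dict[str, PathwayDefinition] = field(default_factory=dict)
    report_decimals: int = 6

    @property
    def loci_map(self) -> dict:
        from .loci import loci_for

        return loci_for(self.model.genes, "auto", dict(self.model.gene_chromosome))


def _resolve_model(doc: Mapping[str, Any], base_dir: Path) -> StoichiometricModel:
    spec = doc.get("model")
    if spec is None:
        raise ModelValidationError("config is missing the 'model' section")
    builtin = spec.get("builtin")
    if builtin == "core":
        return make_core_model()
    if builtin == "random-toy":
        return make_random_toy(ToySpec(rng_seed=int(spec.get("seed", 0))))
    if builtin is not None:
        raise ModelValidationError(f"unknown builtin model {builtin!r}")
    path = Path(spec["path"])
    if not path.is_absolute():
        path = base_dir / path
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    return read_model(path, spec.get("dialect", "cobra-json"))


def _apply_medium(
    model: StoichiometricModel, overrides: Mapping[str, Any]
) -> StoichiometricModel:
    lb = model.lb.copy()
    ub = model.ub.copy()
    for rid, bounds in overrides.items():
        j = model.reaction_index(rid)
        lb[j] = float(bounds[0])
        ub[j] = float(bounds[1])
    out = model.with_bounds(lb, ub)
    out.validate()
    return out


def load_run_config(path: str | Path, seed: int | None = None) -> RunConfig:
    """Load a YAML run config; ``seed`` (if given) overrides the file's seed."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text()) or {}

    model = _resolve_model(doc, path.parent)
    if doc.get("medium"):
        model = _apply_medium(model, doc["medium"])

    pathways = {}
    for pdoc in doc.get("pathways", []):
        if pdoc == "builtin-core-pathway":
            p = core_pathway()
        else:
            p = pathway_from_dict(pdoc)
        pathways[p.pathway_id] = p

    moea_doc = dict(doc.get("moea", {}))
    if seed is not None:
        moea_doc["rng_seed"] = int(seed)
    if "objectives" in moea_doc:
        moea_doc["objectives"] = tuple(moea_doc["objectives"])
    if "essential_genes" in moea_doc:
        moea_doc["essential_genes"] = frozenset(moea_doc["essential_genes"])
    if "synthetic_lethal_pairs" in moea_doc:
        moea_doc["synthetic_lethal_pairs"] = frozenset(
            frozenset(pair) for pair in moea_doc["synthetic_lethal_pairs"]
        )
    if "knockins" in moea_doc:
        moea_doc["knockins"] = frozenset(moea_doc["knockins"])
    if "cofactor_metabolites" in moea_doc:
        moea_doc["cofactor_metabolites"] = tuple(moea_doc["cofactor_metabolites"])
    moea = MOEAConfig(**moea_doc)

    unknown_knockins = moea.knockins - set(pathways)
    if unknown_knockins:
        raise ModelValidationError(
            f"config enables undefined knock-in pathway(s) {sorted(unknown_knockins)}"
        )

    report = doc.get("report", {})
    return RunConfig(
        model=model,
        moea=moea,
        pathways=pathways,
        report_decimals=int(report.get("decimals", 6)),
    )
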