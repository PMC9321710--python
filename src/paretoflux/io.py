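"""Model I/O: COBRA-style JSON (read/write) and SBML Level 3 + FBC (read).

The JSON dialect follows the community COBRA schema (top-level
``metabolites`` / ``reactions`` / ``genes`` arrays with ``metabolites``
stoichiometry maps per reaction), so public models load unchanged.  Fields
this package needs beyond the schema — the carbon-source and product
reaction roles and the gene->chromosome map — are kept under a single
``x_paretoflux`` key that foreign readers can ignore; our reader tolerates
its absence.

SBML reading is delegated to :mod:`cobra` (optional dependency).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import scipy.sparse as sp

from .gpr import parse_gpr
from .model import ModelValidationError, StoichiometricModel

__all__ = ["read_model", "write_model", "read_json_model", "read_sbml_model"]


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed; names the offending element."""


def read_model(path: str | Path, dialect: str = "cobra-json") -> StoichiometricModel:
    """Load a model from ``path``.

    Parameters
    ----------
    path : file path
    dialect : {"cobra-json", "sbml-fbc"}
    """
    if dialect == "cobra-json":
        return read_json_model(path)
    if dialect == "sbml-fbc":
        return read_sbml_model(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_json_model(path: str | Path) -> StoichiometricModel:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"{path}: not valid JSON ({exc})") from exc
    return model_from_dict(doc)


def model_from_dict(doc: dict[str, Any]) -> StoichiometricModel:
    for key in ("metabolites", "reactions", "genes"):
        if key not in doc:
            raise ModelParseError(f"missing top-level array {key!r}")

    met_ids = [m["id"] for m in doc["metabolites"]]
    met_index = {m: i for i, m in enumerate(met_ids)}
    genes = [g["id"] for g in doc["genes"]]

    rxn_ids: list[str] = []
    lb, ub, c = [], [], []
    gpr = {}
    S = sp.lil_matrix((len(met_ids), len(doc["reactions"])))
    biomass = None
    for j, rxn in enumerate(doc["reactions"]):
        rid = rxn.get("id")
        if rid is None:
            raise ModelParseError(f"reaction #{j} has no id")
        rxn_ids.append(rid)
        lb.append(float(rxn.get("lower_bound", -1000.0)))
        ub.append(float(rxn.get("upper_bound", 1000.0)))
        obj = float(rxn.get("objective_coefficient", 0.0))
        c.append(obj)
        if obj != 0.0 and biomass is None:
            biomass = rid
        for met, coeff in rxn.get("metabolites", {}).items():
            if met not in met_index:
                raise ModelParseError(
                    f"reaction {rid!r} references unknown metabolite {met!r}"
                )
            S[met_index[met], j] = float(coeff)
        rule_text = rxn.get("gene_reaction_rule", "") or ""
        if rule_text.strip():
            gpr[rid] = parse_gpr(rule_text)

    extra = doc.get("x_paretoflux", {})
    model = StoichiometricModel(
        metabolite_ids=tuple(met_ids),
        reaction_ids=tuple(rxn_ids),
        S=sp.csr_matrix(S),
        lb=np.array(lb, float),
        ub=np.array(ub, float),
        c=np.array(c, float),
        genes=tuple(genes),
        gpr=gpr,
        biomass_reaction=extra.get("biomass_reaction", biomass),
        carbon_source_exchange=extra.get("carbon_source_exchange"),
        product_reaction=extra.get("product_reaction"),
        gene_chromosome=dict(extra.get("gene_chromosome", {})),
        model_id=doc.get("id", "model"),
        applied_pathways=frozenset(extra.get("applied_pathways", ())),
    )
    try:
        model.validate()
    except ModelValidationError:
        raise
    return model


def model_to_dict(model: StoichiometricModel) -> dict[str, Any]:
    Sc = model.S.tocsc()
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        col = Sc.getcol(j).tocoo()
        stoich = {model.metabolite_ids[i]: float(v) for i, v in zip(col.row, col.data)}
        rxn: dict[str, Any] = {
            "id": rid,
            "metabolites": stoich,
            "lower_bound": float(model.lb[j]),
            "upper_bound": float(model.ub[j]),
        }
        if model.c[j] != 0.0:
            rxn["objective_coefficient"] = float(model.c[j])
        if rid in model.gpr:
            rule = repr(model.gpr[rid])
            rxn["gene_reaction_rule"] = rule[1:-1] if rule.startswith("(") else rule
        reactions.append(rxn)
    return {
        "id": model.model_id,
        "metabolites": [{"id": m} for m in model.metabolite_ids],
        "reactions": reactions,
        "genes": [{"id": g} for g in model.genes],
        "x_paretoflux": {
            "biomass_reaction": model.biomass_reaction,
            "carbon_source_exchange": model.carbon_source_exchange,
            "product_reaction": model.product_reaction,
            "gene_chromosome": dict(model.gene_chromosome),
            "applied_pathways": sorted(model.applied_pathways),
        },
    }


def write_model(model: StoichiometricModel, path: str | Path) -> None:
    """Write the model as COBRA-style JSON (lossless round trip)."""
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=True))


def read_sbml_model(path: str | Path) -> StoichiometricModel:
    """Read an SBML L3+FBC file via cobra and convert.

    Requires the optional ``cobra`` dependency.
    """
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("reading SBML requires the optional 'cobra' package") from exc

    cb = cobra.io.read_sbml_model(str(path))
    met_ids = [m.id for m in cb.metabolites]
    met_index = {m: i for i, m in enumerate(met_ids)}
    rxn_ids = [r.id for r in cb.reactions]
    S = sp.lil_matrix((len(met_ids), len(rxn_ids)))
    lb, ub, c = [], [], []
    gpr = {}
    biomass = None
    for j, rxn in enumerate(cb.reactions):
        lb.append(rxn.lower_bound)
        ub.append(rxn.upper_bound)
        c.append(rxn.objective_coefficient)
        if rxn.objective_coefficient != 0 and biomass is None:
            biomass = rxn.id
        for met, coeff in rxn.metabolites.items():
            S[met_index[met.id], j] = float(coeff)
        if rxn.gene_reaction_rule.strip():
            gpr[rxn.id] = parse_gpr(rxn.gene_reaction_rule)
    model = StoichiometricModel(
        metabolite_ids=tuple(met_ids),
        reaction_ids=tuple(rxn_ids),
        S=sp.csr_matrix(S),
        lb=np.array(lb, float),
        ub=np.array(ub, float),
        c=np.array(c, float),
        genes=tuple(g.id for g in cb.genes),
        gpr=gpr,
        biomass_reaction=biomass,
        model_id=cb.id or "model",
    )
    model.validate()
    return model
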