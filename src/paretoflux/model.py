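"""Stoichiometric model container, strain designs, knockouts and knock-ins.

The model is treated as an immutable value: every mutation-like operation
(:func:`apply_design`, :func:`add_pathway`) returns a new model, leaving the
input untouched, so candidate strains can be evaluated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .gpr import GPRRule, evaluate_gpr

__all__ = [
    "StoichiometricModel",
    "StrainDesign",
    "PathwayDefinition",
    "ModelValidationError",
    "apply_design",
    "add_pathway",
]


class ModelValidationError(ValueError):
    """Raised when a model (or a design against a model) is inconsistent."""


@dataclass(frozen=True)
class StoichiometricModel:
    """A constraint-based metabolic network.

    ``S`` is the m x n stoichiometric matrix (rows = metabolites, columns =
    reactions), ``lb``/``ub`` the per-reaction flux bounds in
    mmol gDW^-1 h^-1, and ``c`` the linear objective weights (typically an
    indicator on the biomass reaction).  ``gpr`` maps reaction ids to parsed
    Boolean gene rules; reactions without an entry are always active and are
    never knockable.
    """

    metabolite_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    S: sp.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    c: np.ndarray
    genes: tuple[str, ...]
    gpr: Mapping[str, GPRRule]
    biomass_reaction: str | None = None
    carbon_source_exchange: str | None = None
    product_reaction: str | None = None
    gene_chromosome: Mapping[str, str] = field(default_factory=dict)
    model_id: str = "model"
    applied_pathways: frozenset[str] = frozenset()

    # -- indexing helpers ---------------------------------------------------

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction {reaction_id!r}") from None

    def metabolite_index(self, metabolite_id: str) -> int:
        try:
            return self.metabolite_ids.index(metabolite_id)
        except ValueError:
            raise KeyError(f"unknown metabolite {metabolite_id!r}") from None

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def knockable_genes(self) -> tuple[str, ...]:
        """Genes that appear in at least one GPR rule (deletable targets)."""
        seen: set[str] = set()
        for rule in self.gpr.values():
            seen |= rule.genes()
        return tuple(g for g in self.genes if g in seen)

    def validate(self) -> None:
        """Check structural invariants; raise ModelValidationError on failure."""
        m, n = self.S.shape
        if m != len(self.metabolite_ids) or n != len(self.reaction_ids):
            raise ModelValidationError(
                f"S is {m}x{n} but model lists {len(self.metabolite_ids)} "
                f"metabolites and {len(self.reaction_ids)} reactions"
            )
        if m == 0 or n == 0:
            raise ModelValidationError("degenerate model: empty S")
        if m >= n:
            raise ModelValidationError(
                f"expected fewer metabolites than reactions, got m={m} >= n={n}"
            )
        if len(self.lb) != n or len(self.ub) != n or len(self.c) != n:
            raise ModelValidationError("lb/ub/c length mismatch with reactions")
        if np.any(self.lb > self.ub):
            bad = self.reaction_ids[int(np.argmax(self.lb > self.ub))]
            raise ModelValidationError(f"lb > ub for reaction {bad!r}")
        if len(set(self.reaction_ids)) != n:
            raise ModelValidationError("duplicate reaction ids")
        if len(set(self.metabolite_ids)) != m:
            raise ModelValidationError("duplicate metabolite ids")
        for attr in ("biomass_reaction", "carbon_source_exchange", "product_reaction"):
            rid = getattr(self, attr)
            if rid is not None and rid not in self.reaction_ids:
                raise ModelValidationError(f"{attr} {rid!r} is not a model reaction")
        gene_set = set(self.genes)
        for rid, rule in self.gpr.items():
            if rid not in self.reaction_ids:
                raise ModelValidationError(f"GPR attached to unknown reaction {rid!r}")
            missing = rule.genes() - gene_set
            if missing:
                raise ModelValidationError(
                    f"GPR of {rid!r} references unknown gene(s) {sorted(missing)}"
                )

    def with_bounds(self, lb: np.ndarray, ub: np.ndarray) -> "StoichiometricModel":
        return replace(self, lb=np.asarray(lb, float), ub=np.asarray(ub, float))


@dataclass(frozen=True)
class StrainDesign:
    """A candidate strain: genes switched off plus enabled knock-in pathways.

    Genes not listed in ``deletions`` are in state 1 (present).
    """

    deletions: frozenset[str] = frozenset()
    knockins: frozenset[str] = frozenset()

    @classmethod
    def from_lists(
        cls, deletions: Iterable[str] = (), knockins: Iterable[str] = ()
    ) -> "StrainDesign":
        return cls(frozenset(deletions), frozenset(knockins))

    @property
    def n_deletions(self) -> int:
        return len(self.deletions)

    def gene_states(self, genes: Sequence[str]) -> dict[str, int]:
        return {g: 0 if g in self.deletions else 1 for g in genes}

    def sort_key(self) -> tuple:
        return (tuple(sorted(self.deletions)), tuple(sorted(self.knockins)))


@dataclass(frozen=True)
class PathwayDefinition:
    """A heterologous pathway: reactions, genes and metabolites to add.

    ``new_reactions`` entries are ``(reaction_id, stoichiometry, lb, ub,
    gpr_rule_or_None)`` where the stoichiometry maps metabolite ids (existing
    or new) to coefficients.
    """

    pathway_id: str
    new_reactions: tuple[tuple[str, Mapping[str, float], float, float, GPRRule | None], ...]
    new_genes: tuple[str, ...] = ()
    new_metabolites: tuple[str, ...] = ()

    def validate_against(self, model: StoichiometricModel) -> None:
        known = set(model.metabolite_ids) | set(self.new_metabolites)
        for rid, stoich, lo, hi, _rule in self.new_reactions:
            unknown = set(stoich) - known
            if unknown:
                raise ModelValidationError(
                    f"pathway reaction {rid!r} references unknown metabolite(s) "
                    f"{sorted(unknown)}"
                )
            if lo > hi:
                raise ModelValidationError(f"pathway reaction {rid!r} has lb > ub")


def add_pathway(
    model: StoichiometricModel, pathway: PathwayDefinition
) -> StoichiometricModel:
    """Return a copy of ``model`` with the pathway's reactions spliced in.

    Idempotent per pathway id: adding a pathway the model already carries
    returns the model unchanged.  A pathway reaction whose id collides with
    an existing reaction raises ``ModelValidationError``.
    """
    if pathway.pathway_id in model.applied_pathways:
        return model
    pathway.validate_against(model)

    dup = set(r[0] for r in pathway.new_reactions) & set(model.reaction_ids)
    if dup:
        raise ModelValidationError(
            f"pathway {pathway.pathway_id!r} redefines existing reaction(s) {sorted(dup)}"
        )

    met_ids = list(model.metabolite_ids)
    for met in pathway.new_metabolites:
        if met not in met_ids:
            met_ids.append(met)
    met_index = {m: i for i, m in enumerate(met_ids)}

    rxn_ids = list(model.reaction_ids)
    lb = list(model.lb)
    ub = list(model.ub)
    c = list(model.c)
    gpr = dict(model.gpr)

    S = sp.lil_matrix((len(met_ids), len(rxn_ids) + len(pathway.new_reactions)))
    S[: model.S.shape[0], : model.S.shape[1]] = model.S

    for k, (rid, stoich, lo, hi, rule) in enumerate(pathway.new_reactions):
        col = len(rxn_ids)
        rxn_ids.append(rid)
        lb.append(float(lo))
        ub.append(float(hi))
        c.append(0.0)
        for met, coeff in stoich.items():
            S[met_index[met], col] = float(coeff)
        if rule is not None:
            gpr[rid] = rule
        del k

    genes = list(model.genes)
    for g in pathway.new_genes:
        if g not in genes:
            genes.append(g)

    new = replace(
        model,
        metabolite_ids=tuple(met_ids),
        reaction_ids=tuple(rxn_ids),
        S=sp.csr_matrix(S),
        lb=np.array(lb, float),
        ub=np.array(ub, float),
        c=np.array(c, float),
        genes=tuple(genes),
        gpr=gpr,
        applied_pathways=model.applied_pathways | {pathway.pathway_id},
    )
    new.validate()
    return new


def apply_design(
    model: StoichiometricModel,
    design: StrainDesign,
    pathways: Mapping[str, PathwayDefinition] | None = None,
) -> StoichiometricModel:
    """Simulate a strain: add its knock-in pathways, then apply knockouts.

    A gene deletion disables every reaction whose GPR rule evaluates false
    under the design's gene states; disabling is done by forcing the
    reaction's bounds to (0, 0).  Reactions without a GPR rule are never
    touched.  The input model is not modified.
    """
    unknown = design.deletions - set(model.genes) - {
        g
        for p in (pathways or {}).values()
        if p.pathway_id in design.knockins
        for g in p.new_genes
    }
    if unknown:
        raise ModelValidationError(f"design deletes unknown gene(s) {sorted(unknown)}")

    work = model
    for pid in sorted(design.knockins):
        if pathways is None or pid not in pathways:
            raise ModelValidationError(f"unknown knock-in pathway {pid!r}")
        work = add_pathway(work, pathways[pid])

    states = design.gene_states(work.genes)
    lb = work.lb.copy()
    ub = work.ub.copy()
    for rid, rule in work.gpr.items():
        if not evaluate_gpr(rule, states):
            j = work.reaction_index(rid)
            lb[j] = 0.0
            ub[j] = 0.0
    return work.with_bounds(lb, ub)
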