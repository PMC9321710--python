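"""Small synthetic metabolic models with known optima for tests and demos.

``make_core_model`` is a fixed, hand-written network whose FBA optimum is
known in closed form; ``make_random_toy`` generates seeded variants with at
most 12 knockable genes so the exhaustive front oracle stays tractable.

Core network (carbon uptake capped at 10; all internal capacities 1000
unless noted)::

    EX_glc:  A <-   (lb=-10, ub=0; uptake negative)
    T1:      A -> B            gene g_ess1              (essential)
    R_or:    B -> C            gpr "gO1 or gO2"         (isozymes)
    R_and:   C -> D + nadh     gpr "gA1 and gA2"        (subunit complex)
    T2:      D -> E            gene g_ess2              (essential)
    BIOMASS: E ->              objective, growth
    RESP:    nadh ->           gene g_resp              (main cofactor sink)
    RESP2:   nadh ->  (ub=3)   gene g_resp2             (backup sink)
    FC1:     B -> F            gene g_f1                (futile half-cycle)
    FC2:     F -> B            gene g_f2
    EX_prod: prod ->           (product exchange; nothing makes prod in WT)

The three-step knock-in pathway ("carotene") adds C -> P1 -> P2 and
P2 + nadh -> prod.  Because the product route is the only alternative nadh
sink, deleting the respiration genes growth-couples production:

* wild type (knock-in present, no deletions): growth 10, product 0;
* delete g_resp: growth 6.5, product 3.5;
* delete g_resp and g_resp2: growth 5, product 5.

These closed-form optima are asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .gpr import parse_gpr
from .model import PathwayDefinition, StoichiometricModel

__all__ = [
    "ToySpec",
    "make_core_model",
    "core_pathway",
    "CORE_WT_GROWTH",
    "CORE_ESSENTIAL_GENES",
    "make_random_toy",
]

#: Closed-form FBA optimum of the core model (chain limited by uptake).
CORE_WT_GROWTH = 10.0

#: Genes whose single deletion abolishes growth in the core model.
CORE_ESSENTIAL_GENES = frozenset({"g_ess1", "g_ess2"})


def _build(
    model_id: str,
    metabolites: list[str],
    reactions: list[tuple[str, dict[str, float], float, float, str | None]],
    genes: list[str],
    *,
    biomass: str,
    carbon: str,
    product: str | None,
    gene_chromosome: dict[str, str] | None = None,
) -> StoichiometricModel:
    met_index = {m: i for i, m in enumerate(metabolites)}
    S = sp.lil_matrix((len(metabolites), len(reactions)))
    lb, ub, c, rxn_ids, gpr = [], [], [], [], {}
    for j, (rid, stoich, lo, hi, rule) in enumerate(reactions):
        rxn_ids.append(rid)
        lb.append(lo)
        ub.append(hi)
        c.append(1.0 if rid == biomass else 0.0)
        for met, coeff in stoich.items():
            S[met_index[met], j] = coeff
        if rule:
            gpr[rid] = parse_gpr(rule)
    model = StoichiometricModel(
        metabolite_ids=tuple(metabolites),
        reaction_ids=tuple(rxn_ids),
        S=sp.csr_matrix(S),
        lb=np.array(lb, float),
        ub=np.array(ub, float),
        c=np.array(c, float),
        genes=tuple(genes),
        gpr=gpr,
        biomass_reaction=biomass,
        carbon_source_exchange=carbon,
        product_reaction=product,
        gene_chromosome=dict(gene_chromosome or {}),
        model_id=model_id,
    )
    model.validate()
    return model


def make_core_model() -> StoichiometricModel:
    """The fixed hand-written core network (see module docstring)."""
    metabolites = ["A", "B", "C", "D", "E", "nadh", "F", "prod"]
    big = 1000.0
    reactions = [
        ("EX_glc", {"A": -1.0}, -10.0, 0.0, None),
        ("T1", {"A": -1.0, "B": 1.0}, 0.0, big, "g_ess1"),
        ("R_or", {"B": -1.0, "C": 1.0}, 0.0, big, "gO1 or gO2"),
        ("R_and", {"C": -1.0, "D": 1.0, "nadh": 1.0}, 0.0, big, "gA1 and gA2"),
        ("T2", {"D": -1.0, "E": 1.0}, 0.0, big, "g_ess2"),
        ("BIOMASS", {"E": -1.0}, 0.0, big, None),
        ("RESP", {"nadh": -1.0}, 0.0, big, "g_resp"),
        ("RESP2", {"nadh": -1.0}, 0.0, 3.0, "g_resp2"),
        ("FC1", {"B": -1.0, "F": 1.0}, 0.0, big, "g_f1"),
        ("FC2", {"F": -1.0, "B": 1.0}, 0.0, big, "g_f2"),
        ("EX_prod", {"prod": -1.0}, 0.0, big, None),
    ]
    genes = [
        "g_ess1", "gO1", "gO2", "gA1", "gA2",
        "g_ess2", "g_resp", "g_resp2", "g_f1", "g_f2",
    ]
    # custom chromosome labels exercise the custom-map loci convention
    chromosomes = {
        "g_ess1": "A", "gO1": "B", "gO2": "C", "gA1": "B", "gA2": "B",
        "g_ess2": "A", "g_resp": "F", "g_resp2": "F", "g_f1": "D", "g_f2": "E",
    }
    return _build(
        "toy_core",
        metabolites,
        reactions,
        genes,
        biomass="BIOMASS",
        carbon="EX_glc",
        product="EX_prod",
        gene_chromosome=chromosomes,
    )


def core_pathway() -> PathwayDefinition:
    """Three-step heterologous product pathway for the core model."""
    return PathwayDefinition(
        pathway_id="carotene",
        new_reactions=(
            ("K1", {"C": -1.0, "P1": 1.0}, 0.0, 1000.0, parse_gpr("kin1")),
            ("K2", {"P1": -1.0, "P2": 1.0}, 0.0, 1000.0, parse_gpr("kin2")),
            ("K3", {"P2": -1.0, "nadh": -1.0, "prod": 1.0}, 0.0, 1000.0, parse_gpr("kin3")),
        ),
        new_genes=("kin1", "kin2", "kin3"),
        new_metabolites=("P1", "P2"),
    )


@dataclass(frozen=True)
class ToySpec:
    """Parameters of the random toy generator."""

    n_isozyme_reactions: int = 1
    n_subunit_reactions: int = 1
    n_sink_branches: int = 2
    uptake_limit: float = 10.0
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.n_isozyme_reactions, self.n_subunit_reactions) < 0:
            raise ValueError("reaction counts must be >= 0")
        if self.n_sink_branches < 1:
            raise ValueError("need at least one cofactor sink branch")
        if self.uptake_limit <= 0:
            raise ValueError("uptake_limit must be positive")


def _gene_name(rng: np.random.Generator, k: int) -> str:
    """Synthetic gene ids alternating Y. lipolytica / SGD naming styles."""
    if k % 2 == 0:
        letter = "ABCDEF"[int(rng.integers(0, 6))]
        return f"YALI0{letter}{10000 + int(rng.integers(0, 89999)):05d}g"
    chrom = "ABCDEFGHIJKLMNOP"[int(rng.integers(0, 16))]
    arm = "LR"[int(rng.integers(0, 2))]
    strand = "WC"[int(rng.integers(0, 2))]
    return f"Y{chrom}{arm}{int(rng.integers(1, 400)):03d}{strand}"


def make_random_toy(spec: ToySpec, max_retries: int = 20) -> StoichiometricModel:
    """Seeded random variant of the core topology.

    The linear carbon chain is kept, while isozyme/subunit gating, sink-
    branch capacities and the product pathway's cofactor stoichiometry are
    randomized.  Resamples (bounded retries) until the wild type grows,
    which the template guarantees by construction on the first try; the
    retry loop guards future template edits.

    Knockable gene count is at most 2*n_isozyme + 2*n_subunit +
    n_sink_branches + 3 and is checked against the brute-force cap of 12.
    """
    from .lp import fba  # late import to avoid a cycle at module load

    for attempt in range(max_retries):
        rng = np.random.default_rng((spec.rng_seed, attempt))
        model = _random_toy_once(spec, rng)
        state = fba(model)
        if state.optimal and state.objective_value > 1e-6:
            return model
    raise RuntimeError(f"could not generate a growing toy model for {spec!r}")


def _random_toy_once(spec: ToySpec, rng: np.random.Generator) -> StoichiometricModel:
    used: set[str] = set()

    def fresh_gene() -> str:
        while True:
            g = _gene_name(rng, len(used))
            if g not in used:
                used.add(g)
                return g

    n_chain = 2 + spec.n_isozyme_reactions + spec.n_subunit_reactions
    mets = [f"m{i}" for i in range(n_chain + 1)] + ["nadh", "prod", "pint"]
    big = 1000.0

    reactions: list[tuple[str, dict[str, float], float, float, str | None]] = [
        ("EX_glc", {"m0": -1.0}, -spec.uptake_limit, 0.0, None)
    ]
    genes: list[str] = []

    step = 0
    # carbon chain: an ungated entry step, then gated steps; the last gated
    # step also produces the cofactor that sinks must reoxidize
    kinds = (
        [None]
        + ["iso"] * spec.n_isozyme_reactions
        + ["sub"] * spec.n_subunit_reactions
        + [None]
    )
    nadh_yield = float(rng.integers(1, 3))
    for i, kind in enumerate(kinds[:-1]):
        stoich = {f"m{i}": -1.0, f"m{i + 1}": 1.0}
        if i == len(kinds) - 2:
            stoich["nadh"] = nadh_yield
        rule = None
        if kind == "iso":
            g1, g2 = fresh_gene(), fresh_gene()
            genes += [g1, g2]
            rule = f"{g1} or {g2}"
        elif kind == "sub":
            g1, g2 = fresh_gene(), fresh_gene()
            genes += [g1, g2]
            rule = f"{g1} and {g2}"
        reactions.append((f"chain{step}", stoich, 0.0, big, rule))
        step += 1
    reactions.append((f"m{n_chain - 1}_to_bio", {f"m{n_chain - 1}": -1.0, f"m{n_chain}": 1.0}, 0.0, big, None))
    reactions.append(("BIOMASS", {f"m{n_chain}": -1.0}, 0.0, big, None))

    # gated cofactor sinks with random finite capacities (the first is wide
    # open so the wild type always grows at full uptake)
    for b in range(spec.n_sink_branches):
        g = fresh_gene()
        genes.append(g)
        cap = big if b == 0 else float(rng.integers(1, 6))
        reactions.append((f"SINK{b}", {"nadh": -1.0}, 0.0, cap, g))

    # product branch: lossy drain from mid-chain, consuming the cofactor
    tap = int(rng.integers(1, n_chain - 1))
    kin = [fresh_gene(), fresh_gene(), fresh_gene()]
    genes += kin
    nadh_cost = float(rng.integers(1, int(nadh_yield) + 1))
    reactions.append((f"P1", {f"m{tap}": -1.0, "pint": 1.0}, 0.0, big, kin[0]))
    reactions.append(
        ("P2", {"pint": -1.0, "nadh": -nadh_cost, "prod": 1.0}, 0.0, big, f"{kin[1]} and {kin[2]}")
    )
    reactions.append(("EX_prod", {"prod": -1.0}, 0.0, big, None))

    model = _build(
        f"toy_random_{spec.rng_seed}",
        mets,
        reactions,
        genes,
        biomass="BIOMASS",
        carbon="EX_glc",
        product="EX_prod",
    )
    if len(model.knockable_genes()) > 12:
        raise ValueError("spec produces more than 12 knockable genes")
    return model
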