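"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import paretoflux as pf
from paretoflux.gpr import And, Literal, Or


@pytest.fixture(scope="session")
def core_model():
    return pf.make_core_model()


@pytest.fixture(scope="session")
def core_pathways():
    return {"carotene": pf.core_pathway()}


def core_config(**overrides) -> pf.MOEAConfig:
    """A small, fast MOEA config for the core fixture model."""
    base = dict(
        objectives=("growth_rate", "product_yield"),
        population_size=40,
        generations=25,
        max_deletions=3,
        growth_floor_fraction=0.40,
        essential_genes=pf.CORE_ESSENTIAL_GENES,
        knockins=frozenset({"carotene"}),
        cofactor_metabolites=("nadh",),
        rng_seed=7,
    )
    base.update(overrides)
    return pf.MOEAConfig(**base)


@pytest.fixture
def core_cfg():
    return core_config()


# -- GPR oracle --------------------------------------------------------------


def random_rule(rng: np.random.Generator, genes: list[str], depth: int = 3):
    """Random GPR expression tree over the given genes."""
    if depth == 0 or rng.random() < 0.3:
        return Literal(genes[int(rng.integers(0, len(genes)))])
    k = int(rng.integers(2, 4))
    children = tuple(random_rule(rng, genes, depth - 1) for _ in range(k))
    return And(children) if rng.random() < 0.5 else Or(children)


def rule_to_python(rule) -> str:
    """Render a rule as a Python boolean expression (independent evaluator)."""
    if isinstance(rule, Literal):
        return rule.gene
    op = " and " if isinstance(rule, And) else " or "
    return "(" + op.join(rule_to_python(c) for c in rule.children) + ")"


def truth_table_agrees(rule) -> bool:
    """Exhaustively compare evaluate_gpr with Python's own and/or semantics."""
    genes = sorted(rule.genes())
    expr = rule_to_python(rule)
    for bits in itertools.product([0, 1], repeat=len(genes)):
        states = dict(zip(genes, bits))
        expected = bool(eval(expr, {}, {g: bool(s) for g, s in states.items()}))
        if pf.evaluate_gpr(rule, states) != expected:
            return False
    return True


# -- dominance oracle --------------------------------------------------------


def pairwise_fronts(points: list[tuple], directions) -> list[list[int]]:
    """O(n^2) reference implementation of ranked non-dominated sorting."""

    def dom(a, b):
        adj = lambda p: tuple(x if d == "max" else -x for x, d in zip(p, directions))
        pa, pb = adj(a), adj(b)
        return all(x >= y for x, y in zip(pa, pb)) and any(
            x > y for x, y in zip(pa, pb)
        )

    remaining = set(range(len(points)))
    fronts = []
    while remaining:
        front = [
            i
            for i in remaining
            if not any(dom(points[j], points[i]) for j in remaining if j != i)
        ]
        fronts.append(sorted(front))
        remaining -= set(front)
    return fronts
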