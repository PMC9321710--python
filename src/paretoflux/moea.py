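"""Elitist multiobjective evolutionary search over gene-deletion vectors.

Candidate strains are binary gene vectors (plus pinned knock-in pathways).
Each candidate is scored by FBA/pFBA/FVA-derived objectives; an NSGA-II
style loop (non-dominated sorting + crowding distance, uniform crossover,
per-gene bit-flip mutation, elitist selection) evolves the population while
a Pareto archive accumulates every feasible non-dominated strain seen.

Feasibility constraints:

* growth >= growth_floor_fraction * wild-type growth;
* no essential gene deleted, no synthetic-lethal pair jointly deleted;
* optionally, each configured cofactor's production flux-sum (from pFBA)
  stays within cofactor_bound_fraction of the wild type.

Infeasible candidates are retained in the population with worst-sentinel
objectives so selection pressure still points back toward the feasible
region.  ``brute_force_front`` enumerates all deletion subsets (toy scale
only) and serves as the exact oracle for the search.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .loci import GeneLocus, loci_for, same_chromosome_score
from .lp import DEFAULT_SETTINGS, SolverSettings, fba, fva, pfba
from .metrics import (
    StrainMetrics,
    cofactor_flux_sum,
    productivity_of,
    yield_of,
)
from .model import (
    ModelValidationError,
    PathwayDefinition,
    StoichiometricModel,
    StrainDesign,
    apply_design,
)

__all__ = [
    "MOEAConfig",
    "EvaluatedStrain",
    "ParetoArchive",
    "StrainEvaluator",
    "OBJECTIVE_DIRECTIONS",
    "dominates",
    "fast_nondominated_sort",
    "crowding_distance",
    "mutate",
    "crossover",
    "run_moea",
    "brute_force_front",
    "hypervolume_2d",
]

#: Optimization direction per known objective name.
OBJECTIVE_DIRECTIONS: dict[str, str] = {
    "growth_rate": "max",
    "product_yield": "max",
    "min_productivity": "max",
    "max_productivity": "max",
    "n_knockouts": "min",
    "chromosome_score": "max",
}

WORST_SENTINEL = 1e12

DEFAULT_COFACTORS = ("atp", "gtp", "nadh", "nadph", "fadh2")


class ConfigurationError(ValueError):
    """Raised for unusable run configurations (e.g. infeasible wild type)."""


@dataclass(frozen=True)
class MOEAConfig:
    """Run configuration for the evolutionary search.

    ``mutation_rate=None`` means the conventional 1/g with g knockable
    genes.  ``cofactor_bound_fraction=None`` disables the cofactor
    flux-sum constraint; 0.10 mirrors the 10% growth bound.
    """

    objectives: tuple[str, ...] = ("growth_rate", "product_yield")
    population_size: int = 100
    generations: int = 500
    mutation_rate: float | None = None
    crossover_rate: float = 0.9
    max_deletions: int = 5
    growth_floor_fraction: float = 0.90
    cofactor_bound_fraction: float | None = None
    cofactor_metabolites: tuple[str, ...] = DEFAULT_COFACTORS
    essential_genes: frozenset[str] = frozenset()
    synthetic_lethal_pairs: frozenset[frozenset[str]] = frozenset()
    knockins: frozenset[str] = frozenset()
    fva_fraction: float = 1.0
    molar_mass_ratio: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        if not self.objectives:
            raise ConfigurationError("at least one objective is required")
        unknown = set(self.objectives) - set(OBJECTIVE_DIRECTIONS)
        if unknown:
            raise ConfigurationError(f"unknown objective(s) {sorted(unknown)}")
        if not (0.0 < self.growth_floor_fraction <= 1.0):
            raise ConfigurationError("growth_floor_fraction must be in (0, 1]")
        if self.max_deletions < 1:
            raise ConfigurationError("max_deletions must be >= 1")

    @property
    def directions(self) -> tuple[str, ...]:
        return tuple(OBJECTIVE_DIRECTIONS[o] for o in self.objectives)

    def worst_objectives(self) -> tuple[float, ...]:
        return tuple(
            -WORST_SENTINEL if d == "max" else WORST_SENTINEL for d in self.directions
        )


@dataclass(frozen=True)
class EvaluatedStrain:
    design: StrainDesign
    objectives: tuple[float, ...]
    feasible: bool
    metrics: StrainMetrics | None = None

    def sort_key(self) -> tuple:
        return self.design.sort_key()


def dominates(
    a: Sequence[float], b: Sequence[float], directions: Sequence[str]
) -> bool:
    """Pareto dominance: a is at least as good everywhere and better somewhere."""
    if len(a) != len(b) or len(a) != len(directions):
        raise ValueError("objective tuples and directions must have equal arity")
    better = False
    for x, y, d in zip(a, b, directions):
        if d == "min":
            x, y = -x, -y
        if x < y:
            return False
        if x > y:
            better = True
    return better


class ParetoArchive:
    """Mutually non-dominated set of feasible evaluated strains."""

    def __init__(self, directions: Sequence[str], wt: EvaluatedStrain | None = None):
        self.directions = tuple(directions)
        self.wt = wt
        self._members: list[EvaluatedStrain] = []
        self.n_evaluated = 0

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self):
        return iter(self.members())

    def members(self) -> list[EvaluatedStrain]:
        return sorted(self._members, key=EvaluatedStrain.sort_key)

    def objective_tuples(self, decimals: int = 9) -> set[tuple[float, ...]]:
        """Unique objective tuples, rounded for set comparison."""
        return {
            tuple(round(x, decimals) for x in s.objectives) for s in self._members
        }

    def add(self, strain: EvaluatedStrain) -> bool:
        """Insert if feasible and non-dominated; evict members it dominates."""
        if not strain.feasible:
            return False
        for member in self._members:
            if member.design == strain.design:
                return False
            if dominates(member.objectives, strain.objectives, self.directions):
                return False
        self._members = [
            m
            for m in self._members
            if not dominates(strain.objectives, m.objectives, self.directions)
        ]
        self._members.append(strain)
        return True

    def update(self, strains: Iterable[EvaluatedStrain]) -> None:
        for s in strains:
            self.add(s)

    def assert_invariants(self) -> None:
        for a, b in itertools.permutations(self._members, 2):
            if dominates(a.objectives, b.objectives, self.directions):
                raise AssertionError("archive contains a dominated member")
        if any(not m.feasible for m in self._members):
            raise AssertionError("archive contains an infeasible member")


class StrainEvaluator:
    """Memoized FBA/pFBA/FVA evaluation of strain designs.

    Holds the base model, the run configuration, available knock-in
    pathway definitions and the wild-type reference state.
    """

    def __init__(
        self,
        model: StoichiometricModel,
        config: MOEAConfig,
        pathways: Mapping[str, PathwayDefinition] | None = None,
        settings: SolverSettings = DEFAULT_SETTINGS,
    ):
        model.validate()
        self.model = model
        self.config = config
        self.pathways = dict(pathways or {})
        self.settings = settings
        self._cache: dict[tuple, EvaluatedStrain] = {}
        self.n_evaluations = 0

        base = apply_design(
            model, StrainDesign(knockins=config.knockins), self.pathways
        )
        self.base_with_knockins = base
        self.loci: dict[str, GeneLocus] = loci_for(
            base.genes, "auto", dict(base.gene_chromosome)
        )
        self.knockable: tuple[str, ...] = tuple(
            g for g in base.knockable_genes() if g not in config.essential_genes
        )
        self.cofactors = tuple(
            m for m in config.cofactor_metabolites if m in base.metabolite_ids
        )

        self.wild_type = self.evaluate(StrainDesign(knockins=config.knockins))
        if not self.wild_type.feasible or self.wild_type.metrics is None:
            raise ConfigurationError("wild-type model is not feasible under FBA")

    # -- internals ----------------------------------------------------------

    def _needs_fva(self) -> bool:
        return bool(
            {"min_productivity", "max_productivity"} & set(self.config.objectives)
        )

    def _violates_gene_rules(self, design: StrainDesign) -> bool:
        if design.deletions & self.config.essential_genes:
            return True
        for pair in self.config.synthetic_lethal_pairs:
            if pair <= design.deletions:
                return True
        return False

    def evaluate(self, design: StrainDesign) -> EvaluatedStrain:
        key = design.sort_key()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        result = self._evaluate(design)
        self._cache[key] = result
        self.n_evaluations += 1
        return result

    def _infeasible(self, design: StrainDesign, metrics=None) -> EvaluatedStrain:
        return EvaluatedStrain(
            design, self.config.worst_objectives(), False, metrics
        )

    def _evaluate(self, design: StrainDesign) -> EvaluatedStrain:
        cfg = self.config
        if self._violates_gene_rules(design):
            return self._infeasible(design)

        strain = apply_design(self.model, design, self.pathways)
        growth_state = fba(strain, self.settings)
        if not growth_state.optimal:
            return self._infeasible(design)
        growth = growth_state.objective_value

        parsimonious = pfba(strain, settings=self.settings)
        if not parsimonious.optimal:
            return self._infeasible(design)

        product = (
            parsimonious.flux(strain, strain.product_reaction)
            if strain.product_reaction is not None
            else 0.0
        )
        uptake = (
            abs(parsimonious.flux(strain, strain.carbon_source_exchange))
            if strain.carbon_source_exchange is not None
            else 0.0
        )
        try:
            yield_value = yield_of(product, uptake, cfg.molar_mass_ratio)
        except ValueError:
            return self._infeasible(design)

        cofactor_production = {
            m: cofactor_flux_sum(strain, parsimonious, m) for m in self.cofactors
        }

        prod_range = None
        if self._needs_fva() and strain.product_reaction is not None:
            ranges = fva(
                strain,
                cfg.fva_fraction,
                reactions=[strain.product_reaction],
                settings=self.settings,
            )
            p_lo, p_hi = ranges.range_of(strain, strain.product_reaction)
            vals = []
            for p in (p_lo, p_hi):
                y = 0.0 if abs(p) <= 1e-12 else yield_of(p, uptake, cfg.molar_mass_ratio)
                vals.append(productivity_of(y, growth))
            prod_range = (min(vals), max(vals))

        metrics = StrainMetrics(
            growth_rate=growth,
            product_flux=product,
            carbon_uptake=uptake,
            yield_value=yield_value,
            productivity=productivity_of(yield_value, growth),
            productivity_range=prod_range,
            cofactor_production=cofactor_production,
            n_knockouts=design.n_deletions,
        )

        feasible = self._check_feasibility(design, metrics)
        if not feasible:
            return self._infeasible(design, metrics)
        return EvaluatedStrain(design, self._objectives(design, metrics), True, metrics)

    def _check_feasibility(self, design: StrainDesign, metrics: StrainMetrics) -> bool:
        cfg = self.config
        tol = self.settings.feasibility_tol * 10
        wt_metrics = getattr(self.wild_type, "metrics", None) if hasattr(self, "wild_type") else None
        if wt_metrics is None:  # evaluating the wild type itself
            return True
        if metrics.growth_rate < cfg.growth_floor_fraction * wt_metrics.growth_rate - 1e-9:
            return False
        if cfg.cofactor_bound_fraction is not None:
            for met in self.cofactors:
                wt_sum = wt_metrics.cofactor_production.get(met, 0.0)
                delta = abs(metrics.cofactor_production.get(met, 0.0) - wt_sum)
                if delta > cfg.cofactor_bound_fraction * wt_sum + tol:
                    return False
        return True

    def _objectives(
        self, design: StrainDesign, metrics: StrainMetrics
    ) -> tuple[float, ...]:
        values = []
        for name in self.config.objectives:
            if name == "growth_rate":
                values.append(metrics.growth_rate)
            elif name == "product_yield":
                values.append(metrics.yield_value)
            elif name == "min_productivity":
                values.append(metrics.productivity_range[0])
            elif name == "max_productivity":
                values.append(metrics.productivity_range[1])
            elif name == "n_knockouts":
                values.append(float(design.n_deletions))
            elif name == "chromosome_score":
                values.append(same_chromosome_score(design, self.loci))
            else:  # pragma: no cover - guarded by MOEAConfig
                raise ConfigurationError(f"unknown objective {name!r}")
        return tuple(values)


# -- variation operators ----------------------------------------------------


def mutate(
    design: StrainDesign,
    rate: float,
    rng: np.random.Generator,
    knockable: Sequence[str],
    max_deletions: int | None = None,
) -> StrainDesign:
    """Flip each knockable gene's state independently with probability ``rate``.

    ``knockable`` must already exclude essential genes, so no essential gene
    can be switched off.  If the result exceeds ``max_deletions``, randomly
    chosen excess deletions are reverted.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("mutation rate must be in [0, 1]")
    deletions = set(design.deletions)
    flips = rng.random(len(knockable)) < rate
    for gene, flip in zip(knockable, flips):
        if flip:
            deletions.symmetric_difference_update({gene})
    return _repair(design, deletions, rng, max_deletions)


def crossover(
    parent_a: StrainDesign,
    parent_b: StrainDesign,
    rng: np.random.Generator,
    knockable: Sequence[str],
    max_deletions: int | None = None,
) -> tuple[StrainDesign, StrainDesign]:
    """Uniform crossover: each gene state drawn from one parent per child."""
    del_a, del_b = set(), set()
    for gene in knockable:
        in_a = gene in parent_a.deletions
        in_b = gene in parent_b.deletions
        if rng.random() < 0.5:
            in_a, in_b = in_b, in_a
        if in_a:
            del_a.add(gene)
        if in_b:
            del_b.add(gene)
    return (
        _repair(parent_a, del_a, rng, max_deletions),
        _repair(parent_b, del_b, rng, max_deletions),
    )


def _repair(
    template: StrainDesign,
    deletions: set[str],
    rng: np.random.Generator,
    max_deletions: int | None,
) -> StrainDesign:
    if max_deletions is not None and len(deletions) > max_deletions:
        excess = len(deletions) - max_deletions
        revert = rng.choice(sorted(deletions), size=excess, replace=False)
        deletions -= set(revert.tolist())
    return StrainDesign(frozenset(deletions), template.knockins)


# -- non-dominated sorting & selection --------------------------------------


def fast_nondominated_sort(
    population: Sequence[EvaluatedStrain], directions: Sequence[str]
) -> list[list[int]]:
    """Partition population indices into ranked non-dominated fronts."""
    n = len(population)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    domination_count = [0] * n
    fronts: list[list[int]] = [[]]
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(population[i].objectives, population[j].objectives, directions):
                dominated_by[i].append(j)
                domination_count[j] += 1
            elif dominates(population[j].objectives, population[i].objectives, directions):
                dominated_by[j].append(i)
                domination_count[i] += 1
    for i in range(n):
        if domination_count[i] == 0:
            fronts[0].append(i)
    k = 0
    while fronts[k]:
        nxt: list[int] = []
        for i in fronts[k]:
            for j in dominated_by[i]:
                domination_count[j] -= 1
                if domination_count[j] == 0:
                    nxt.append(j)
        fronts.append(nxt)
        k += 1
    return fronts[:-1]


def crowding_distance(
    population: Sequence[EvaluatedStrain], front: Sequence[int]
) -> dict[int, float]:
    """NSGA-II crowding distance within one front (objective-scale normalized)."""
    dist = {i: 0.0 for i in front}
    if len(front) <= 2:
        return {i: math.inf for i in front}
    n_obj = len(population[front[0]].objectives)
    for k in range(n_obj):
        ordered = sorted(front, key=lambda i: population[i].objectives[k])
        lo = population[ordered[0]].objectives[k]
        hi = population[ordered[-1]].objectives[k]
        dist[ordered[0]] = dist[ordered[-1]] = math.inf
        if hi - lo <= 0:
            continue
        for prev_i, i, next_i in zip(ordered, ordered[1:], ordered[2:]):
            gap = population[next_i].objectives[k] - population[prev_i].objectives[k]
            dist[i] += gap / (hi - lo)
    return dist


def _select(
    population: list[EvaluatedStrain], size: int, directions: Sequence[str]
) -> list[EvaluatedStrain]:
    """Elitist environmental selection (rank, then crowding, then design key)."""
    fronts = fast_nondominated_sort(population, directions)
    chosen: list[EvaluatedStrain] = []
    for front in fronts:
        if len(chosen) + len(front) <= size:
            chosen.extend(population[i] for i in front)
        else:
            dist = crowding_distance(population, front)
            ranked = sorted(
                front, key=lambda i: (-dist[i], population[i].sort_key())
            )
            chosen.extend(population[i] for i in ranked[: size - len(chosen)])
            break
    return chosen


def _tournament(
    population: list[EvaluatedStrain],
    ranks: dict[int, int],
    crowd: dict[int, float],
    rng: np.random.Generator,
) -> EvaluatedStrain:
    i, j = rng.integers(0, len(population), size=2)
    i, j = int(i), int(j)
    if ranks[i] != ranks[j]:
        return population[i if ranks[i] < ranks[j] else j]
    if crowd[i] != crowd[j]:
        return population[i if crowd[i] > crowd[j] else j]
    return population[min(i, j)]


def run_moea(
    model: StoichiometricModel,
    config: MOEAConfig,
    pathways: Mapping[str, PathwayDefinition] | None = None,
    settings: SolverSettings = DEFAULT_SETTINGS,
    callback: Callable[[int, list[EvaluatedStrain], ParetoArchive], None] | None = None,
) -> ParetoArchive:
    """Run the evolutionary search and return the accumulated Pareto archive.

    Fully deterministic for a given ``config.rng_seed``.  ``callback`` (if
    given) is invoked after every generation with the generation index, the
    selected population and the current archive.
    """
    rng = np.random.default_rng(config.rng_seed)
    evaluator = StrainEvaluator(model, config, pathways, settings)
    knockable = evaluator.knockable
    if not knockable:
        raise ConfigurationError("model has no knockable, non-essential genes")
    rate = config.mutation_rate if config.mutation_rate is not None else 1.0 / len(knockable)

    archive = ParetoArchive(config.directions, wt=evaluator.wild_type)
    archive.add(evaluator.wild_type)

    population = [evaluator.wild_type]
    while len(population) < config.population_size:
        k = int(rng.integers(1, config.max_deletions + 1))
        k = min(k, len(knockable))
        picked = rng.choice(knockable, size=k, replace=False)
        design = StrainDesign(frozenset(picked.tolist()), config.knockins)
        population.append(evaluator.evaluate(design))
    archive.update(population)

    for gen in range(config.generations):
        fronts = fast_nondominated_sort(population, config.directions)
        ranks = {i: r for r, front in enumerate(fronts) for i in front}
        crowd: dict[int, float] = {}
        for front in fronts:
            crowd.update(crowding_distance(population, front))

        offspring_designs: list[StrainDesign] = []
        while len(offspring_designs) < config.population_size:
            pa = _tournament(population, ranks, crowd, rng)
            pb = _tournament(population, ranks, crowd, rng)
            if rng.random() < config.crossover_rate:
                ca, cb = crossover(
                    pa.design, pb.design, rng, knockable, config.max_deletions
                )
            else:
                ca, cb = pa.design, pb.design
            ca = mutate(ca, rate, rng, knockable, config.max_deletions)
            cb = mutate(cb, rate, rng, knockable, config.max_deletions)
            offspring_designs.extend([ca, cb])
        offspring = [
            evaluator.evaluate(d)
            for d in offspring_designs[: config.population_size]
        ]
        archive.update(offspring)
        population = _select(
            population + offspring, config.population_size, config.directions
        )
        if callback is not None:
            callback(gen, population, archive)
    archive.n_evaluated = evaluator.n_evaluations
    return archive


def brute_force_front(
    model: StoichiometricModel,
    config: MOEAConfig,
    pathways: Mapping[str, PathwayDefinition] | None = None,
    max_genes: int = 12,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> ParetoArchive:
    """Exact Pareto front by enumerating all deletion subsets (test oracle).

    Evaluates every subset of knockable non-essential genes of size
    0..max_deletions; refuses more than ``max_genes`` knockable genes.
    """
    evaluator = StrainEvaluator(model, config, pathways, settings)
    knockable = evaluator.knockable
    if len(knockable) > max_genes:
        raise ConfigurationError(
            f"{len(knockable)} knockable genes exceeds the brute-force cap {max_genes}"
        )
    archive = ParetoArchive(config.directions, wt=evaluator.wild_type)
    for k in range(0, min(config.max_deletions, len(knockable)) + 1):
        for subset in itertools.combinations(knockable, k):
            design = StrainDesign(frozenset(subset), config.knockins)
            archive.add(evaluator.evaluate(design))
    archive.n_evaluated = evaluator.n_evaluations
    return archive


def hypervolume_2d(
    points: Iterable[Sequence[float]],
    reference: Sequence[float],
    directions: Sequence[str] = ("max", "max"),
) -> float:
    """Hypervolume (area) dominated by a 2-D point set w.r.t. a reference.

    Points not dominating the reference contribute nothing.
    """
    if len(tuple(reference)) != 2 or len(tuple(directions)) != 2:
        raise ValueError("hypervolume_2d handles exactly two objectives")
    # orient to maximization
    orient = lambda p: tuple(
        x if d == "max" else -x for x, d in zip(p, directions)
    )
    ref = orient(reference)
    pts = sorted(
        {
            p
            for p in map(orient, points)
            if p[0] > ref[0] and p[1] > ref[1]
        },
        key=lambda p: (-p[0], -p[1]),
    )
    area = 0.0
    prev_y = ref[1]
    for x, y in pts:
        if y > prev_y:
            area += (x - ref[0]) * (y - prev_y)
            prev_y = y
    return area
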