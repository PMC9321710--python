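import itertools
import math

import numpy as np
import pytest

import paretoflux as pf
from paretoflux.moea import (
    ConfigurationError,
    EvaluatedStrain,
    WORST_SENTINEL,
    crowding_distance,
    hypervolume_2d,
)

from conftest import core_config, pairwise_fronts


class TestDominates:
    def test_strictly_better_everywhere(self):
        assert pf.dominates((2, 2), (1, 1), ("max", "max"))

    def test_incomparable(self):
        assert not pf.dominates((2, 1), (1, 2), ("max", "max"))
        assert not pf.dominates((1, 2), (2, 1), ("max", "max"))

    def test_equal_tuples_do_not_dominate(self):
        assert not pf.dominates((1, 1), (1, 1), ("max", "max"))

    def test_minimize_direction(self):
        assert pf.dominates((1, 5), (1, 7), ("max", "min"))

    def test_arity_mismatch(self):
        with pytest.raises(ValueError):
            pf.dominates((1,), (1, 2), ("max", "max"))


class TestNondominatedSort:
    def wrap(self, points):
        return [
            EvaluatedStrain(pf.StrainDesign(frozenset([f"g{i}"])), tuple(p), True)
            for i, p in enumerate(points)
        ]

    def test_mutually_nondominated_single_front(self):
        pop = self.wrap([(1, 3), (2, 2), (3, 1)])
        fronts = pf.fast_nondominated_sort(pop, ("max", "max"))
        assert [sorted(f) for f in fronts] == [[0, 1, 2]]

    def test_strict_chain_three_fronts(self):
        pop = self.wrap([(3, 3), (2, 2), (1, 1)])
        fronts = pf.fast_nondominated_sort(pop, ("max", "max"))
        assert [sorted(f) for f in fronts] == [[0], [1], [2]]

    def test_random_points_match_pairwise_oracle(self):
        rng = np.random.default_rng(13)
        for directions in [("max", "max"), ("max", "min"), ("min", "min", "max")]:
            points = [tuple(rng.integers(0, 5, size=len(directions)).tolist()) for _ in range(20)]
            pop = self.wrap(points)
            fronts = pf.fast_nondominated_sort(pop, directions)
            assert [sorted(f) for f in fronts] == pairwise_fronts(points, directions)


class TestCrowding:
    def test_boundary_points_infinite(self):
        pop = TestNondominatedSort().wrap([(1, 4), (2, 3), (3, 2), (4, 1)])
        dist = crowding_distance(pop, [0, 1, 2, 3])
        assert dist[0] == math.inf and dist[3] == math.inf
        assert 0 < dist[1] < math.inf


class TestVariation:
    GENES = tuple(f"g{i}" for i in range(10))

    def test_mutate_rate_zero_identity(self):
        rng = np.random.default_rng(0)
        design = pf.StrainDesign(frozenset(["g1", "g2"]))
        assert pf.mutate(design, 0.0, rng, self.GENES) == design

    def test_mutate_rate_one_flips_everything(self):
        rng = np.random.default_rng(0)
        genes = ("a", "b", "c")
        design = pf.StrainDesign(frozenset(["a"]))
        out = pf.mutate(design, 1.0, rng, genes, max_deletions=3)
        assert out.deletions == frozenset(["b", "c"])

    def test_mutate_binomial_expectation(self):
        # 1e4 mutations at rate 0.01 over 100 genes: mean flips ~ 1
        rng = np.random.default_rng(42)
        genes = tuple(f"g{i}" for i in range(100))
        design = pf.StrainDesign()
        total = 0
        n_trials = 10_000
        for _ in range(n_trials):
            out = pf.mutate(design, 0.01, rng, genes)
            total += len(out.deletions)
        mean = total / n_trials
        assert mean == pytest.approx(1.0, abs=0.05)

    def test_mutate_respects_max_deletions(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            out = pf.mutate(pf.StrainDesign(), 0.8, rng, self.GENES, max_deletions=3)
            assert out.n_deletions <= 3

    def test_mutate_never_deletes_essential(self):
        # essential genes are simply excluded from the knockable universe
        rng = np.random.default_rng(2)
        knockable = tuple(g for g in self.GENES if g != "g0")
        for _ in range(50):
            out = pf.mutate(pf.StrainDesign(), 1.0, rng, knockable)
            assert "g0" not in out.deletions

    def test_mutate_bad_rate(self):
        with pytest.raises(ValueError):
            pf.mutate(pf.StrainDesign(), 1.5, np.random.default_rng(0), self.GENES)

    def test_crossover_identical_parents(self):
        rng = np.random.default_rng(3)
        p = pf.StrainDesign(frozenset(["g1", "g5"]))
        a, b = pf.crossover(p, p, rng, self.GENES)
        assert a == p and b == p

    def test_crossover_complementary_parents(self):
        rng = np.random.default_rng(4)
        pa = pf.StrainDesign(frozenset(["g0", "g1"]))
        pb = pf.StrainDesign(frozenset(["g2", "g3"]))
        union = pa.deletions | pb.deletions
        for _ in range(20):
            a, b = pf.crossover(pa, pb, rng, self.GENES)
            # every gene state comes from exactly one parent
            assert a.deletions | b.deletions == union
            assert a.deletions & b.deletions == frozenset()

    def test_crossover_closure(self):
        rng = np.random.default_rng(5)
        pa = pf.StrainDesign(frozenset(["g0", "g1", "g2"]))
        pb = pf.StrainDesign(frozenset(["g2", "g7"]))
        for _ in range(20):
            a, b = pf.crossover(pa, pb, rng, self.GENES)
            assert a.deletions <= pa.deletions | pb.deletions
            assert b.deletions <= pa.deletions | pb.deletions


class TestArchive:
    def strain(self, objs, name="x"):
        return EvaluatedStrain(pf.StrainDesign(frozenset([name])), objs, True)

    def test_dominated_rejected(self):
        arc = pf.ParetoArchive(("max", "max"))
        arc.add(self.strain((2, 2), "a"))
        assert not arc.add(self.strain((1, 1), "b"))
        assert len(arc) == 1

    def test_dominating_evicts(self):
        arc = pf.ParetoArchive(("max", "max"))
        arc.add(self.strain((1, 1), "a"))
        arc.add(self.strain((2, 2), "b"))
        assert len(arc) == 1
        assert next(iter(arc)).objectives == (2, 2)

    def test_infeasible_never_enters(self):
        arc = pf.ParetoArchive(("max", "max"))
        bad = EvaluatedStrain(pf.StrainDesign(), (5, 5), False)
        assert not arc.add(bad)
        assert len(arc) == 0

    def test_equal_tuples_coexist(self):
        arc = pf.ParetoArchive(("max", "max"))
        arc.add(self.strain((2, 2), "a"))
        arc.add(self.strain((2, 2), "b"))
        assert len(arc) == 2
        arc.assert_invariants()


class TestHypervolume:
    def test_single_point_rectangle(self):
        assert hypervolume_2d([(2, 3)], (0, 0)) == pytest.approx(6.0)

    def test_staircase_union(self):
        # [0,3]x[0,2] union [0,2]x[0,3] has area 6 + 2
        hv = hypervolume_2d([(2, 3), (3, 2)], (0, 0))
        assert hv == pytest.approx(8.0)

    def test_dominated_point_adds_nothing(self):
        base = hypervolume_2d([(3, 3)], (0, 0))
        assert hypervolume_2d([(3, 3), (1, 1)], (0, 0)) == pytest.approx(base)

    def test_min_direction(self):
        hv = hypervolume_2d([(1, 1)], (2, 2), ("min", "min"))
        assert hv == pytest.approx(1.0)


class TestEvaluator:
    def test_wild_type_objectives(self, core_model, core_pathways, core_cfg):
        ev = pf.StrainEvaluator(core_model, core_cfg, core_pathways)
        wt = ev.wild_type
        assert wt.feasible
        assert wt.objectives == pytest.approx((10.0, 0.0))

    def test_essential_deletion_infeasible(self, core_model, core_pathways, core_cfg):
        ev = pf.StrainEvaluator(core_model, core_cfg, core_pathways)
        strain = ev.evaluate(
            pf.StrainDesign(frozenset(["g_ess1"]), core_cfg.knockins)
        )
        assert not strain.feasible
        assert strain.objectives == (-WORST_SENTINEL, -WORST_SENTINEL)

    def test_lethal_knockout_fails_growth_floor(self, core_model, core_pathways):
        cfg = core_config(growth_floor_fraction=0.9)
        ev = pf.StrainEvaluator(core_model, cfg, core_pathways)
        # gA1 is not declared essential but zeroes the biomass path
        strain = ev.evaluate(pf.StrainDesign(frozenset(["gA1"]), cfg.knockins))
        assert not strain.feasible

    def test_synthetic_lethal_pair_blocked(self, core_model, core_pathways):
        pair = frozenset({"g_f1", "g_f2"})
        cfg = core_config(synthetic_lethal_pairs=frozenset({pair}))
        ev = pf.StrainEvaluator(core_model, cfg, core_pathways)
        single = ev.evaluate(pf.StrainDesign(frozenset(["g_f1"]), cfg.knockins))
        joint = ev.evaluate(pf.StrainDesign(pair, cfg.knockins))
        assert single.feasible
        assert not joint.feasible

    def test_memoization(self, core_model, core_pathways, core_cfg):
        ev = pf.StrainEvaluator(core_model, core_cfg, core_pathways)
        before = ev.n_evaluations
        d = pf.StrainDesign(frozenset(["g_resp"]), core_cfg.knockins)
        ev.evaluate(d)
        ev.evaluate(d)
        assert ev.n_evaluations == before + 1

    def test_infeasible_wild_type_is_config_error(self, core_model, core_pathways):
        cfg = core_config(knockins=frozenset())
        lb = core_model.lb.copy()
        lb[core_model.reaction_index("EX_prod")] = 1.0  # demand nothing can supply
        dead = core_model.with_bounds(lb, core_model.ub)
        with pytest.raises(ConfigurationError):
            pf.StrainEvaluator(dead, cfg)


class TestRunMOEA:
    def test_core_front_matches_brute_force(self, core_model, core_pathways, core_cfg):
        bf = pf.brute_force_front(core_model, core_cfg, core_pathways)
        arc = pf.run_moea(core_model, core_cfg, core_pathways)
        assert arc.objective_tuples() == bf.objective_tuples()

    def test_growth_floor_enforced(self, core_model, core_pathways):
        cfg = core_config(growth_floor_fraction=0.9, generations=10)
        arc = pf.run_moea(core_model, cfg, core_pathways)
        for strain in arc:
            assert strain.metrics.growth_rate >= 0.9 * 10.0 - 1e-9

    def test_no_essential_or_sl_in_archive(self, core_model, core_pathways):
        pair = frozenset({"g_resp", "g_resp2"})
        cfg = core_config(
            synthetic_lethal_pairs=frozenset({pair}), generations=15
        )
        arc = pf.run_moea(core_model, cfg, core_pathways)
        for strain in arc:
            assert not (strain.design.deletions & cfg.essential_genes)
            assert not (pair <= strain.design.deletions)

    def test_cofactor_bound_enforced(self, core_model, core_pathways):
        cfg = core_config(
            cofactor_bound_fraction=0.10, cofactor_metabolites=("nadh",), generations=15
        )
        arc = pf.run_moea(core_model, cfg, core_pathways)
        ev = pf.StrainEvaluator(core_model, cfg, core_pathways)
        wt_sum = ev.wild_type.metrics.cofactor_production["nadh"]
        assert len(arc) >= 1
        for strain in arc:
            delta = abs(strain.metrics.cofactor_production["nadh"] - wt_sum)
            assert delta <= 0.10 * wt_sum + 1e-6

    def test_determinism(self, core_model, core_pathways, core_cfg):
        a = pf.run_moea(core_model, core_cfg, core_pathways)
        b = pf.run_moea(core_model, core_cfg, core_pathways)
        assert [s.design for s in a.members()] == [s.design for s in b.members()]
        assert a.objective_tuples() == b.objective_tuples()

    def test_archive_invariants_every_generation(self, core_model, core_pathways):
        cfg = core_config(generations=8)
        seen = []

        def cb(gen, population, archive):
            archive.assert_invariants()
            seen.append(len(archive))

        pf.run_moea(core_model, cfg, core_pathways, callback=cb)
        assert len(seen) == cfg.generations

    def test_hypervolume_monotone(self, core_model, core_pathways):
        cfg = core_config(generations=12, rng_seed=3)
        hv = []

        def cb(gen, population, archive):
            hv.append(
                hypervolume_2d(
                    [s.objectives for s in archive], (-1.0, -1.0), cfg.directions
                )
            )

        pf.run_moea(core_model, cfg, core_pathways, callback=cb)
        assert all(b >= a - 1e-12 for a, b in zip(hv, hv[1:]))

    def test_moea_never_dominates_brute_force(self, core_model, core_pathways, core_cfg):
        # exhaustive search is optimal: no archived point may dominate it
        bf = pf.brute_force_front(core_model, core_cfg, core_pathways)
        arc = pf.run_moea(core_model, core_cfg, core_pathways)
        for s in arc:
            for b in bf:
                assert not pf.dominates(s.objectives, b.objectives, core_cfg.directions)

    def test_random_toy_front_matches_brute_force(self, core_pathways):
        model = pf.make_random_toy(pf.ToySpec(rng_seed=11))
        cfg = core_config(
            essential_genes=frozenset(), knockins=frozenset(), generations=30
        )
        bf = pf.brute_force_front(model, cfg)
        arc = pf.run_moea(model, cfg)
        assert arc.objective_tuples() == bf.objective_tuples()


class TestBruteForce:
    def test_two_gene_hand_enumeration(self, core_model, core_pathways):
        # restrict the universe to the two respiration genes via essentials
        others = set(pf.make_core_model().knockable_genes()) - {"g_resp", "g_resp2"}
        cfg = core_config(
            essential_genes=frozenset(others | pf.CORE_ESSENTIAL_GENES),
            max_deletions=2,
        )
        bf = pf.brute_force_front(core_model, cfg, core_pathways)
        # hand-enumerated subsets: {} -> (10, 0); {resp} -> (6.5, .35);
        # {resp2} -> (10, 0); {resp, resp2} -> (5, .5)
        assert bf.objective_tuples() == {(10.0, 0.0), (6.5, 0.35), (5.0, 0.5)}

    def test_subset_count_identity(self, core_model, core_pathways, core_cfg):
        bf = pf.brute_force_front(core_model, core_cfg, core_pathways)
        g = len(pf.StrainEvaluator(core_model, core_cfg, core_pathways).knockable)
        expected = sum(math.comb(g, k) for k in range(core_cfg.max_deletions + 1))
        assert bf.n_evaluated == expected

    def test_gene_cap_enforced(self, core_model, core_pathways, core_cfg):
        with pytest.raises(ConfigurationError, match="cap"):
            pf.brute_force_front(core_model, core_cfg, core_pathways, max_genes=3)


class TestConfig:
    def test_empty_objectives_rejected(self):
        with pytest.raises(ConfigurationError):
            pf.MOEAConfig(objectives=())

    def test_unknown_objective_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown"):
            pf.MOEAConfig(objectives=("growth_rate", "titer"))

    def test_bad_growth_floor(self):
        with pytest.raises(ConfigurationError):
            pf.MOEAConfig(growth_floor_fraction=0.0)

    def test_chromosome_score_objective(self, core_model, core_pathways):
        cfg = core_config(
            objectives=("growth_rate", "product_yield", "chromosome_score"),
            generations=10,
        )
        arc = pf.run_moea(core_model, cfg, core_pathways)
        for strain in arc:
            assert 0.0 <= strain.objectives[2] <= 1.0

    def test_min_max_productivity_objectives(self, core_model, core_pathways):
        cfg = core_config(
            objectives=("min_productivity", "max_productivity"), generations=10
        )
        arc = pf.run_moea(core_model, cfg, core_pathways)
        assert len(arc) >= 1
        for strain in arc:
            lo, hi = strain.metrics.productivity_range
            assert lo <= hi + 1e-9
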