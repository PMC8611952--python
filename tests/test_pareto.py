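"""Objectives, Pareto bookkeeping, the genetic algorithm and completion."""

import numpy as np
import pytest

from chemogenlib.config import ConfigError, PipelineConfig
from chemogenlib.pareto import (
    ParetoFront,
    LibrarySubset,
    Objectives,
    choose_final,
    complete_coverage,
    dominates,
    ga_select,
    nondominated_sort,
    subset_objectives,
)


def brute_force_fronts(triples):
    """O(n^2) oracle: peel maximal non-dominated layers."""
    remaining = list(range(len(triples)))
    fronts = []
    while remaining:
        front = [
            i
            for i in remaining
            if not any(dominates(triples[j], triples[i]) for j in remaining if j != i)
        ]
        fronts.append(front)
        remaining = [i for i in remaining if i not in front]
    return fronts


class TestObjectives:
    def test_hand_enumerated_triple(self):
        # M1 hits U1; M2 hits U1 and U2; hits per protein: U1:2, U2:1
        targets = {"M1": {"U1"}, "M2": {"U1", "U2"}}
        scaffolds = {"M1": "S1", "M2": "S2"}
        obj = subset_objectives(["M1", "M2"], targets, scaffolds, ["S1", "S2"])
        assert obj.as_tuple() == (2, 2, 1.5)

    def test_duplicate_profiles_raise_mean_hits_not_coverage(self):
        targets = {"M1": {"U1"}, "M2": {"U1"}}
        scaffolds = {"M1": "S1", "M2": "S1"}
        one = subset_objectives(["M1"], targets, scaffolds, ["S1"])
        two = subset_objectives(["M1", "M2"], targets, scaffolds, ["S1"])
        assert two.ui_coverage == one.ui_coverage
        assert two.mean_hits > one.mean_hits

    def test_empty_subset_is_the_zero_triple(self):
        assert subset_objectives([], {}, {}, []).as_tuple() == (0, 0, 0.0)

    def test_non_representative_scaffolds_do_not_count(self):
        targets = {"M1": {"U1"}}
        obj = subset_objectives(["M1"], targets, {"M1": "S1"}, ["S9"])
        assert obj.scaffold_count == 0


class TestDomination:
    def test_strict_componentwise_domination(self):
        assert dominates((2, 2, 2), (1, 1, 1))

    def test_incomparable_triples(self):
        assert not dominates((2, 1, 3), (2, 2, 2))
        assert not dominates((2, 2, 2), (2, 1, 3))

    def test_irreflexive(self):
        assert not dominates((1, 2, 3), (1, 2, 3))


class TestNonDominatedSort:
    def test_worked_three_triple_example(self):
        triples = [(2, 2, 2), (1, 1, 1), (2, 1, 3)]
        fronts = nondominated_sort(triples)
        assert sorted(fronts[0]) == [0, 2]
        assert fronts[1] == [1]

    def test_identical_triples_form_one_front(self):
        fronts = nondominated_sort([(1, 1, 1)] * 5)
        assert len(fronts) == 1 and sorted(fronts[0]) == list(range(5))

    def test_agrees_with_quadratic_oracle_on_random_triples(self):
        rng = np.random.default_rng(3)
        triples = [tuple(rng.integers(0, 6, size=3)) for _ in range(120)]
        fronts = nondominated_sort(triples)
        oracle = brute_force_fronts(triples)
        assert [sorted(f) for f in fronts] == [sorted(f) for f in oracle]
        assert sorted(i for f in fronts for i in f) == list(range(len(triples)))


def _tiny_problem(seed=0, pool_size=60, n_ui=20):
    rng = np.random.default_rng(seed)
    targets = {}
    scaffolds = {}
    pool = []
    for m in range(pool_size):
        mol = f"M{m:03d}"
        targets[mol] = {f"U{u}" for u in rng.choice(n_ui, size=rng.integers(1, 4), replace=False)}
        scaffolds[mol] = f"S{m % 15}"
        pool.append(mol)
    return pool, targets, scaffolds


class TestGA:
    def test_pool_equal_subset_size_returns_the_only_subset(self):
        pool, targets, scaffolds = _tiny_problem()
        cfg = PipelineConfig(subset_size=60, ga_population=10, ga_iterations=5, rng_seed=0)
        res = ga_select(pool, targets, scaffolds, set(scaffolds.values()), cfg)
        assert sorted(res.chosen.molecule_ids) == sorted(pool)

    def test_pool_smaller_than_subset_is_config_error(self):
        pool, targets, scaffolds = _tiny_problem()
        cfg = PipelineConfig(subset_size=100, ga_population=10, ga_iterations=5, rng_seed=0)
        with pytest.raises(ConfigError):
            ga_select(pool, targets, scaffolds, set(scaffolds.values()), cfg)

    def test_identical_seed_reproduces_identical_molecule_ids(self):
        pool, targets, scaffolds = _tiny_problem()
        cfg = PipelineConfig(subset_size=15, ga_population=16, ga_iterations=10, rng_seed=11)
        reps = set(scaffolds.values())
        a = ga_select(pool, targets, scaffolds, reps, cfg)
        b = ga_select(pool, targets, scaffolds, reps, cfg)
        assert a.chosen.molecule_ids == b.chosen.molecule_ids

    def test_best_coverage_never_decreases_across_generations(self):
        pool, targets, scaffolds = _tiny_problem(seed=5)
        cfg = PipelineConfig(subset_size=10, ga_population=16, ga_iterations=25, rng_seed=5)
        res = ga_select(pool, targets, scaffolds, set(scaffolds.values()), cfg)
        best = [h["best_O1"] for h in res.history]
        assert all(b >= a for a, b in zip(best, best[1:]))

    def test_planted_optimum_is_found(self, planted_pool):
        p = planted_pool
        cfg = PipelineConfig(subset_size=50, ga_population=40, ga_iterations=60, rng_seed=7)
        res = ga_select(
            p["pool"], p["molecule_targets"], p["molecule_scaffolds"],
            p["representative_scaffolds"], cfg,
        )
        assert res.chosen.objectives.ui_coverage == len(p["ui_ids"])

    def test_chosen_subset_beats_random_subsets_on_average(self):
        """Over 20 small runs the evolved subset's coverage weakly
        dominates a uniformly random subset of the same size."""
        wins = ties = losses = 0
        for seed in range(20):
            pool, targets, scaffolds = _tiny_problem(seed=seed)
            cfg = PipelineConfig(subset_size=10, ga_population=16, ga_iterations=15, rng_seed=seed)
            res = ga_select(pool, targets, scaffolds, set(scaffolds.values()), cfg)
            rng = np.random.default_rng(seed + 1000)
            random_subset = list(rng.choice(pool, size=10, replace=False))
            random_obj = subset_objectives(random_subset, targets, scaffolds, set(scaffolds.values()))
            if res.chosen.objectives.ui_coverage > random_obj.ui_coverage:
                wins += 1
            elif res.chosen.objectives.ui_coverage == random_obj.ui_coverage:
                ties += 1
            else:
                losses += 1
        assert losses == 0
        assert wins > ties


class TestChooseFinal:
    def _front(self, triples):
        return ParetoFront(
            1,
            [
                LibrarySubset((f"M{i}",), Objectives(*t), creation_index=i)
                for i, t in enumerate(triples)
            ],
        )

    def test_singleton_front(self):
        front = self._front([(5, 5, 5.0)])
        assert choose_final(front).molecule_ids == ("M0",)

    def test_scaffold_count_breaks_coverage_ties(self):
        front = self._front([(10, 5, 2.0), (10, 6, 1.9)])
        assert choose_final(front).creation_index == 1

    def test_coverage_dominates_the_ordering(self):
        front = self._front([(9, 9, 9.0), (10, 1, 1.0)])
        assert choose_final(front).creation_index == 1


class TestCompletion:
    TARGETS = {
        "M1": {"U1"},
        "M2": {"U2"},
        "C1": {"U3"},
        "C2": {"U3", "U4"},
    }
    SCAFFOLDS = {"M1": "S1", "M2": "S1", "C1": "Sa", "C2": "Sb"}

    def test_no_missing_protein_leaves_library_unchanged(self):
        lib, additions, unc = complete_coverage(
            ["M1", "M2"], ["M1", "M2"], ["U1", "U2"], self.TARGETS, self.SCAFFOLDS, {"S1": 2}
        )
        assert lib == ["M1", "M2"] and additions == [] and unc == []

    def test_candidate_with_better_scaffold_reach_is_added(self):
        counts = {"S1": 2, "Sa": 3, "Sb": 8}
        lib, additions, _ = complete_coverage(
            ["M1", "M2"], ["M1", "M2", "C1", "C2"], ["U1", "U2", "U3"],
            self.TARGETS, self.SCAFFOLDS, counts,
        )
        assert additions == ["C2"]  # scaffold shared by 8 > 3 molecules
        assert lib == ["M1", "M2", "C2"]

    def test_protein_without_any_candidate_reported_uncoverable(self):
        lib, additions, unc = complete_coverage(
            ["M1"], ["M1"], ["U1", "U9"], self.TARGETS, self.SCAFFOLDS, {"S1": 1}
        )
        assert unc == ["U9"] and additions == []

    def test_completion_never_reduces_coverage(self):
        before = set().union(*(self.TARGETS[m] for m in ["M1"]))
        lib, _, _ = complete_coverage(
            ["M1"], list(self.TARGETS), ["U1", "U2", "U3", "U4"],
            self.TARGETS, self.SCAFFOLDS, {"S1": 2, "Sa": 1, "Sb": 1},
        )
        after = set().union(*(self.TARGETS[m] for m in lib))
        assert before <= after
        assert after == {"U1", "U2", "U3", "U4"}
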