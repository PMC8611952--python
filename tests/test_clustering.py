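"""Jaccard distances, profile clustering and representative selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import jaccard as scipy_jaccard

from chemogenlib.clustering import (
    ScaffoldTargetMatrix,
    UndefinedDistanceError,
    build_matrix,
    hcluster,
    jaccard_distance,
    pick_representative,
)
from chemogenlib.config import ConfigError, PipelineConfig
from chemogenlib.filtering import BioactivePair
from chemogenlib.records import DataIntegrityError

CFG = PipelineConfig()


class TestJaccard:
    def test_worked_example_two_thirds(self):
        assert jaccard_distance([1, 1, 0], [1, 0, 1]) == pytest.approx(2 / 3)

    def test_identical_nonzero_profiles_are_at_distance_zero(self):
        assert jaccard_distance([1, 0, 1], [1, 0, 1]) == 0.0

    def test_disjoint_supports_are_at_distance_one(self):
        assert jaccard_distance([1, 1, 0, 0], [0, 0, 1, 1]) == 1.0

    def test_both_all_zero_is_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            jaccard_distance([0, 0], [0, 0])

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 2**20 - 1), st.integers(0, 2**20 - 1))
    def test_metric_properties_and_agreement_with_reference(self, a_bits, b_bits):
        x = np.array([(a_bits >> i) & 1 for i in range(20)], dtype=bool)
        y = np.array([(b_bits >> i) & 1 for i in range(20)], dtype=bool)
        if not (x.any() or y.any()):
            return
        d = jaccard_distance(x, y)
        assert 0.0 <= d <= 1.0
        assert d == jaccard_distance(y, x)
        assert (d == 0.0) == bool((x == y).all())
        assert d == pytest.approx(scipy_jaccard(x, y))


class TestBuildMatrix:
    def test_one_scaffold_two_targets_gives_ones_row(self):
        pairs = {BioactivePair("M1", "U1", 1.0), BioactivePair("M2", "U2", 1.0)}
        m = build_matrix(pairs, {"M1": "S1", "M2": "S1"})
        assert m.row_ids == ["S1"] and m.col_ids == ["U1", "U2"]
        assert m.values.tolist() == [[True, True]]

    def test_scaffold_without_bioactive_molecule_has_no_row(self):
        pairs = {BioactivePair("M1", "U1", 1.0)}
        m = build_matrix(pairs, {"M1": "S1", "M9": "S9"})
        assert m.row_ids == ["S1"]

    def test_matrix_equals_brute_force_pair_join(self):
        rng = np.random.default_rng(0)
        pairs = set()
        scaffolds = {}
        for i in range(40):
            mol = f"M{i}"
            scaffolds[mol] = f"S{i % 20}"
            for u in rng.choice(10, size=rng.integers(1, 4), replace=False):
                pairs.add(BioactivePair(mol, f"U{u}", 1.0))
        m = build_matrix(pairs, scaffolds)
        for i, s in enumerate(m.row_ids):
            for j, u in enumerate(m.col_ids):
                expected = any(
                    scaffolds[p.molecule_id] == s and p.ui_id == u for p in pairs
                )
                assert bool(m.values[i, j]) == expected

    def test_empty_input_is_an_error(self):
        with pytest.raises(DataIntegrityError):
            build_matrix(set(), {})

    def test_all_zero_rows_rejected_defensively(self):
        with pytest.raises(DataIntegrityError):
            ScaffoldTargetMatrix(["S1"], ["U1"], np.array([[False]]))


def _matrix(rows):
    values = np.array(rows, dtype=bool)
    return ScaffoldTargetMatrix(
        [f"S{i}" for i in range(values.shape[0])],
        [f"U{j}" for j in range(values.shape[1])],
        values,
    )


class TestHCluster:
    def test_k_equal_rows_gives_singletons(self):
        m = _matrix([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        a = hcluster(m, 3, CFG)
        assert a.n_clusters == 3
        assert sorted(a.representatives.values()) == m.row_ids

    def test_k_one_gives_single_cluster(self):
        m = _matrix([[1, 0], [0, 1], [1, 1]])
        a = hcluster(m, 1, CFG)
        assert set(a.labels.values()) == {1}

    def test_planted_blocks_recovered_exactly(self):
        # two blocks of identical profiles must separate at k=2
        m = _matrix([[1, 1, 0, 0]] * 3 + [[0, 0, 1, 1]] * 4)
        a = hcluster(m, 2, CFG)
        block1 = {a.labels[f"S{i}"] for i in range(3)}
        block2 = {a.labels[f"S{i}"] for i in range(3, 7)}
        assert len(block1) == 1 and len(block2) == 1 and block1 != block2

    def test_k_larger_than_rows_is_config_error(self):
        with pytest.raises(ConfigError):
            hcluster(_matrix([[1]]), 2, CFG)

    def test_orthogonal_rows_with_k_rows_returns_all_scaffolds(self):
        m = _matrix(np.eye(6, dtype=bool))
        a = hcluster(m, 6, CFG)
        assert sorted(a.representatives.values()) == m.row_ids


class TestRepresentative:
    def test_singleton_cluster_returns_its_scaffold(self):
        dist = np.zeros((1, 1))
        assert pick_representative(["S0"], dist, {"S0": 0}, {"S0": (1, 1)}) == "S0"

    def test_medoid_wins_on_total_distance(self):
        # hand-computed: totals are 0.4+0.0? -> distances S0:(0.2+0.2)=0.4,
        # S1:(0.2+0.5)=0.7, S2:(0.2+0.5)=0.7
        dist = np.array([[0.0, 0.2, 0.2], [0.2, 0.0, 0.5], [0.2, 0.5, 0.0]])
        index = {f"S{i}": i for i in range(3)}
        stats = {f"S{i}": (1, 1) for i in range(3)}
        assert pick_representative(["S0", "S1", "S2"], dist, index, stats) == "S0"

    def test_target_count_breaks_distance_ties(self):
        dist = np.array([[0.0, 0.5], [0.5, 0.0]])
        index = {"S0": 0, "S1": 1}
        stats = {"S0": (3, 9), "S1": (5, 1)}  # higher target count wins
        assert pick_representative(["S0", "S1"], dist, index, stats) == "S1"

    def test_molecule_count_breaks_remaining_ties(self):
        dist = np.zeros((2, 2))
        stats = {"S0": (3, 2), "S1": (3, 7)}
        assert pick_representative(["S0", "S1"], dist, {"S0": 0, "S1": 1}, stats) == "S1"

    def test_final_tie_break_is_lexicographic_and_order_invariant(self):
        dist = np.zeros((3, 3))
        index = {"Sb": 0, "Sa": 1, "Sc": 2}
        stats = {s: (1, 1) for s in index}
        for members in (["Sb", "Sa", "Sc"], ["Sc", "Sb", "Sa"], ["Sa", "Sc", "Sb"]):
            assert pick_representative(members, dist, index, stats) == "Sa"
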