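"""Hypergeometric over-representation and Bonferroni adjustment."""

import itertools
import math

import pytest

from chemogenlib.config import PipelineConfig
from chemogenlib.enrichment import (
    bonferroni,
    enrich_compound,
    enrich_library,
    hypergeom_upper_tail,
)
from chemogenlib.records import AnnotationMap

CFG = PipelineConfig()


def enumerate_tail(k, n, K, N):
    """Exhaustive oracle: fraction of size-n draws with >= k marked items."""
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total if total else 1.0


class TestUpperTail:
    def test_zero_overlap_has_probability_one(self):
        assert hypergeom_upper_tail(0, 5, 3, 10) == 1.0

    def test_exact_combinatorial_example(self):
        # C(4,2)/C(10,2) = 6/45
        assert hypergeom_upper_tail(2, 2, 4, 10) == pytest.approx(6 / 45)

    def test_monotone_non_increasing_in_overlap(self):
        values = [hypergeom_upper_tail(k, 5, 6, 15) for k in range(6)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_matches_enumeration_on_small_universes(self):
        for N in (5, 8):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        assert hypergeom_upper_tail(k, n, K, N) == pytest.approx(
                            enumerate_tail(k, n, K, N), abs=1e-12
                        )

    def test_bounds_violations_raise(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 2, 4, 10)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 2, 11, 10)


class TestBonferroni:
    def test_multiplies_and_caps(self):
        assert bonferroni([0.01, 0.5], 5) == [0.05, 1.0]

    def test_single_test_is_identity(self):
        assert bonferroni([0.3], 1) == [0.3]

    def test_family_smaller_than_list_raises(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], 1)

    def test_out_of_range_p_value_raises(self):
        with pytest.raises(ValueError):
            bonferroni([0.0], 3)


def _ann(term_id, members, namespace="GO"):
    return AnnotationMap(term_id, term_id, namespace, frozenset(members))


class TestEnrichCompound:
    UNIVERSE = [f"U{i}" for i in range(50)]

    def test_single_target_compound_yields_no_results(self):
        anns = [_ann("GO:1", {"U0", "U1"})]
        assert enrich_compound("M1", {"U0"}, anns, CFG, universe=self.UNIVERSE) == []

    def test_planted_two_of_two_term_is_first_and_significant(self):
        anns = [_ann("GO:planted", {"U0", "U1"})] + [
            _ann(f"GO:{i}", {f"U{10 + i}", f"U{20 + i}", f"U{30 + i}"}) for i in range(8)
        ]
        results = enrich_compound("M1", {"U0", "U1"}, anns, CFG, universe=self.UNIVERSE)
        assert results[0].term_id == "GO:planted"
        assert results[0].significant
        # exact tail: C(2,2)/C(50,2) = 1/1225, one tested term
        assert results[0].p_raw == pytest.approx(1 / 1225)
        assert results[0].p_adj == results[0].p_raw

    def test_single_tested_term_has_unadjusted_p(self):
        anns = [_ann("GO:1", {"U0", "U1", "U2"})]
        (res,) = enrich_compound("M1", {"U0", "U1"}, anns, CFG, universe=self.UNIVERSE)
        assert res.p_adj == res.p_raw

    def test_results_invariant_to_target_order(self):
        anns = [_ann("GO:1", {"U0", "U1", "U2"}), _ann("GO:2", {"U1", "U2", "U3"})]
        a = enrich_compound("M1", ["U0", "U1", "U2"], anns, CFG, universe=self.UNIVERSE)
        b = enrich_compound("M1", ["U2", "U0", "U1"], anns, CFG, universe=self.UNIVERSE)
        assert a == b

    def test_significance_monotone_in_cutoff(self):
        anns = [_ann(f"GO:{i}", {f"U{i}", f"U{i+1}"}) for i in range(5)]
        targets = {"U0", "U1", "U2", "U3"}
        n_sig = []
        for cutoff in (0.2, 0.1, 0.01):
            cfg = CFG.with_overrides(p_cutoff=cutoff)
            res = enrich_compound("M1", targets, anns, cfg, universe=self.UNIVERSE)
            n_sig.append(sum(r.significant for r in res))
        assert n_sig == sorted(n_sig, reverse=True)


def test_planted_terms_in_synthetic_study_are_significant(bundle):
    from chemogenlib.filtering import filter_bioactive
    from chemogenlib.records import map_targets_to_ui

    pairs = filter_bioactive(bundle.records, map_targets_to_ui(bundle.targets), CFG)
    molecule_targets = {}
    for p in pairs:
        molecule_targets.setdefault(p.molecule_id, set()).add(p.ui_id)
    results = enrich_library(molecule_targets, bundle.annotations, CFG)
    significant = {(r.molecule_id, r.term_id) for r in results if r.significant}
    for molecule, term in bundle.truth.planted_terms:
        assert (molecule, term) in significant
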